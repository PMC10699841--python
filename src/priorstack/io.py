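"""File I/O: delimited matrices, prior-effect tables, model persistence.

Matrix dialect: delimited text (comma or tab, sniffed from the header
line), first column a sample/feature identifier, header row required,
UTF-8, '.' decimal; gzip-compressed files are read transparently.  Prior
effects are matched to the feature matrix by identifier; features
without a prior get 0 (and are reported).

Models serialize to a versioned JSON document.  Floats are written with
``repr`` round-tripping, so serialize -> deserialize -> predict is
bit-exact.
"""

from __future__ import annotations

import gzip
import json
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .families import get_family
from .stacking import StackedModel
from .calibration import CalibratedPrior

__all__ = [
    "MODEL_FORMAT_VERSION",
    "read_matrix",
    "read_response",
    "read_priors",
    "write_predictions",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


def _read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_matrix(path: str):
    """Read a delimited matrix: (row ids, column names, float array)."""
    df = _read_table(path)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric matrix entries ({exc})") from None
    return list(map(str, df.index)), list(map(str, df.columns)), values


def read_response(path: str, family: str):
    """Read a response table (id + one value column); returns (ids, y).

    Binomial responses may be coded {0,1} or as two string labels; the
    lexicographically larger label maps to 1 (reported in the returned
    mapping, None for numeric input).
    """
    df = _read_table(path)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly one response column")
    col = df.iloc[:, 0]
    fam = get_family(family)
    mapping = None
    if fam.name == "binomial" and col.dtype == object:
        labels = sorted(map(str, pd.unique(col)))
        if len(labels) != 2:
            raise ValueError(f"{path}: binomial labels must have 2 levels, got {labels}")
        mapping = {labels[0]: 0.0, labels[1]: 1.0}
        y = col.astype(str).map(mapping).to_numpy(dtype=float)
    else:
        y = col.to_numpy(dtype=float)
    return list(map(str, df.index)), y, mapping


def read_priors(path: str, feature_names: Sequence[str]):
    """Read a p x m prior-effect table and align it to ``feature_names``.

    Returns (Z, source_names, missing): rows are matched by feature
    identifier, features absent from the table are imputed as 0 and
    listed in ``missing``; identifiers unknown to the feature matrix
    raise an error.
    """
    df = _read_table(path)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric prior effects ({exc})") from None
    known = set(map(str, feature_names))
    unknown = [i for i in map(str, df.index) if i not in known]
    if unknown:
        raise ValueError(
            f"{path}: prior-effect identifiers not in the feature matrix: "
            + ", ".join(unknown[:5])
            + ("..." if len(unknown) > 5 else "")
        )
    aligned = df.reindex([str(f) for f in feature_names])
    missing = [str(f) for f in feature_names if str(f) not in set(map(str, df.index))]
    Z = aligned.fillna(0.0).to_numpy(dtype=float)
    return Z, list(map(str, df.columns)), missing


def write_predictions(path: str, ids: Sequence[str], values: np.ndarray) -> None:
    pd.DataFrame({"id": list(ids), "prediction": np.asarray(values, float)}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------
def _arr(a) -> list:
    return np.asarray(a, dtype=float).tolist()


def _cal_to_dict(c: CalibratedPrior) -> dict:
    return {
        "source_index": int(c.source_index),
        "source_name": c.source_name,
        "alpha": float(c.alpha),
        "gamma": _arr(c.gamma),
        "method": c.method,
        "deviance": float(c.deviance),
        "theta": None if c.theta is None else float(c.theta),
        "tau": None if c.tau is None else float(c.tau),
        "inverted": bool(c.inverted),
        "retained": bool(c.retained),
        "filter_pvalue": float(c.filter_pvalue),
        "degenerate": bool(c.degenerate),
    }


def _cal_from_dict(d: dict) -> CalibratedPrior:
    return CalibratedPrior(
        source_index=d["source_index"],
        alpha=d["alpha"],
        gamma=np.asarray(d["gamma"], dtype=float),
        method=d["method"],
        deviance=d["deviance"],
        theta=d["theta"],
        tau=d["tau"],
        inverted=d["inverted"],
        retained=d["retained"],
        filter_pvalue=d["filter_pvalue"],
        degenerate=d.get("degenerate", False),
        source_name=d.get("source_name", ""),
    )


def model_to_dict(model: StackedModel) -> dict:
    """JSON-serializable representation of a fitted stacked model."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "package_version": _pkg_version,
        "mode": model.mode,
        "family": model.family.name,
        "feature_names": list(model.feature_names),
        "column_meta": list(model.column_meta),
        "omega0": float(model.omega0),
        "omega": _arr(model.omega),
        "beta0_star": float(model.beta0_star),
        "beta_star": _arr(model.beta_star),
        "null_model": bool(model.null_model),
        "calibrated": [_cal_to_dict(c) for c in model.calibrated],
    }
    if model.mode == "standard" and model.path is not None:
        doc["baseline"] = {
            "lambda_min": float(model.path.lambda_min),
            "lambda_1se": float(model.path.lambda_1se),
            "beta_min_intercept": float(model.path.fit_min.intercept),
            "beta_min": _arr(model.path.fit_min.slopes),
            "beta_1se_intercept": float(model.path.fit_1se.intercept),
            "beta_1se": _arr(model.path.fit_1se.slopes),
        }
    elif model.baseline is not None:
        doc["baseline"] = model.baseline
    return doc


def model_from_dict(doc: dict) -> StackedModel:
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {doc.get('format_version')!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return StackedModel(
        mode=doc["mode"],
        family=get_family(doc["family"]),
        omega0=doc["omega0"],
        omega=np.asarray(doc["omega"], dtype=float),
        beta0_star=doc["beta0_star"],
        beta_star=np.asarray(doc["beta_star"], dtype=float),
        calibrated=[_cal_from_dict(d) for d in doc["calibrated"]],
        path=None,
        feature_names=list(doc["feature_names"]),
        column_meta=list(doc["column_meta"]),
        null_model=doc.get("null_model", False),
        baseline=doc.get("baseline"),
    )


def save_model(model: StackedModel, path: str) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path: str) -> StackedModel:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt", encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))
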
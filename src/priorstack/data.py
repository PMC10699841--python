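"""Container for a supervised GLM dataset (response, features, family)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .families import Family, get_family

__all__ = ["GlmDataset"]


@dataclass
class GlmDataset:
    """A target (or source) dataset: n x p features, n responses, a family.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Feature matrix, samples in rows.
    y : ndarray of shape (n,)
        Response vector; {0, 1} for the binomial family.
    family : str or Family
        ``"gaussian"`` or ``"binomial"``.
    feature_names : sequence of str, optional
        Column identifiers; generated as ``x1..xp`` when omitted.
    """

    X: np.ndarray
    y: np.ndarray
    family: Family
    feature_names: Optional[Sequence[str]] = field(default=None)

    def __post_init__(self):
        self.family = get_family(self.family)
        X = np.ascontiguousarray(np.asarray(self.X, dtype=float))
        if X.ndim != 2:
            raise ValueError("X must be a 2-d array (samples in rows)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        y = self.family.validate_response(self.y)
        if y.shape[0] != X.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
            )
        self.X = X
        self.y = y
        if self.feature_names is None:
            self.feature_names = [f"x{j + 1}" for j in range(X.shape[1])]
        elif len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names length does not match X columns")
        else:
            self.feature_names = [str(s) for s in self.feature_names]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "GlmDataset":
        """Row subset (for cross-validation splits)."""
        return GlmDataset(
            self.X[rows], self.y[rows], self.family, self.feature_names
        )
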
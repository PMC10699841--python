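"""Cross-validated penalized paths: fold plans, lambda-min and lambda-1se.

The co-data-free base learner is an elastic-net GLM fitted along a
100-value lambda path with 10-fold cross-validation (stratified by class
for binomial responses).  Two regularization values are kept: lambda_min,
minimizing the cross-validated deviance, and lambda_1se, the largest
lambda whose loss is within one standard error of that minimum.  The
held-out linear predictors at every lambda are stored because the
stacking meta-learner consumes them.

One fold plan per analysis is drawn and shared between all
cross-validated components (calibration refits, base paths, and the
meta-learner) so that every held-out row is predicted by models that
never saw its fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .data import GlmDataset
from .glm import GlmFit, PenaltySpec, fit_penalized_path, make_lambda_sequence

__all__ = ["FoldPlan", "PenalizedPath", "make_folds", "fit_codata_free"]


@dataclass
class FoldPlan:
    """Assignment of the n samples to K cross-validation folds (1..K)."""

    fold_id: np.ndarray
    K: int
    seed: int

    def __post_init__(self):
        self.fold_id = np.asarray(self.fold_id, dtype=int)
        counts = np.bincount(self.fold_id, minlength=self.K + 1)[1:]
        if len(counts) != self.K or np.any(counts == 0):
            raise ValueError("every fold must be non-empty")

    @property
    def n(self) -> int:
        return self.fold_id.shape[0]

    def test_rows(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id == k)

    def train_rows(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id != k)


def make_folds(dataset: GlmDataset, K: int = 10, seed: int = 0) -> FoldPlan:
    """Reproducible near-equal folds, stratified by class for binomial."""
    n = dataset.n
    if not 2 <= K <= n:
        raise ValueError("need n >= K >= 2")
    fold_id = np.empty(n, dtype=int)
    if dataset.family.name == "binomial":
        _, counts = np.unique(dataset.y, return_counts=True)
        if np.min(counts) < K:
            raise ValueError(
                f"smallest binomial class ({np.min(counts)}) is below K={K}"
            )
        splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n), dataset.y)
    else:
        splitter = KFold(n_splits=K, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n))
    for k, (_, test) in enumerate(split, start=1):
        fold_id[test] = k
    return FoldPlan(fold_id=fold_id, K=K, seed=seed)


@dataclass
class PenalizedPath:
    """Full-data path plus cross-validation curves and selected lambdas."""

    fits: list  # GlmFit per lambda, full data
    lambda_seq: np.ndarray
    cv_loss: np.ndarray
    cv_se: np.ndarray
    lambda_min_index: int
    lambda_1se_index: int
    cv_predictions: np.ndarray  # n x L held-out linear predictors
    alpha: float

    @property
    def lambda_min(self) -> float:
        return float(self.lambda_seq[self.lambda_min_index])

    @property
    def lambda_1se(self) -> float:
        return float(self.lambda_seq[self.lambda_1se_index])

    @property
    def fit_min(self) -> GlmFit:
        return self.fits[self.lambda_min_index]

    @property
    def fit_1se(self) -> GlmFit:
        return self.fits[self.lambda_1se_index]


def fit_codata_free(
    dataset: GlmDataset,
    spec: PenaltySpec,
    folds: FoldPlan,
    tol: float = 1e-7,
    max_cycles: int = 100_000,
) -> PenalizedPath:
    """Penalized path with K-fold CV over a shared lambda sequence.

    The lambda sequence is constructed once from the full data and reused
    inside every fold so the cross-validation curves are comparable
    across folds.  Held-out linear predictors are retained for stacking.
    """
    if folds.n != dataset.n:
        raise ValueError("fold plan does not match the dataset")
    lambda_seq = make_lambda_sequence(dataset, spec)
    fixed = PenaltySpec(
        alpha=spec.alpha,
        lambda_seq=lambda_seq,
        penalty_factors=spec.penalty_factors,
        lower_bounds=spec.lower_bounds,
        upper_bounds=spec.upper_bounds,
        standardize=spec.standardize,
    )
    fits = fit_penalized_path(dataset, fixed, tol=tol, max_cycles=max_cycles)
    L = lambda_seq.size
    cv_pred = np.empty((dataset.n, L))
    fold_loss = np.empty((folds.K, L))
    for k in range(1, folds.K + 1):
        tr, te = folds.train_rows(k), folds.test_rows(k)
        sub = dataset.subset(tr)
        sub_fits = fit_penalized_path(sub, fixed, tol=tol, max_cycles=max_cycles)
        Xte, yte = dataset.X[te], dataset.y[te]
        for t, f in enumerate(sub_fits):
            eta = f.linear_predictor(Xte)
            cv_pred[te, t] = eta
            mu = dataset.family.inverse_link(eta)
            fold_loss[k - 1, t] = dataset.family.deviance(yte, mu)
    cv_loss = fold_loss.mean(axis=0)
    cv_se = fold_loss.std(axis=0, ddof=1) / np.sqrt(folds.K)
    min_idx = int(np.argmin(cv_loss))
    threshold = cv_loss[min_idx] + cv_se[min_idx]
    one_se_idx = int(np.flatnonzero(cv_loss <= threshold)[0])  # largest lambda
    return PenalizedPath(
        fits=fits,
        lambda_seq=lambda_seq,
        cv_loss=cv_loss,
        cv_se=cv_se,
        lambda_min_index=min_idx,
        lambda_1se_index=one_se_idx,
        cv_predictions=cv_pred,
        alpha=spec.alpha,
    )
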
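"""Stacked generalization of calibrated priors and penalized baselines.

The base layer produces, for every sample, cross-validated linear
predictors: one column per retained co-data source (the calibrated-prior
model refitted without the sample's fold, intercept contribution set to
zero) and two columns from the co-data-free penalized path (at lambda_min
and lambda_1se, intercepts included).  The meta layer then combines them:

* **standard stacking** — non-negative lasso of the target on the
  n x (m+2) predictor matrix; the fitted weights omega average the
  component models, and the combined coefficients are
  beta*_j = sum_k omega_k gamma_jk + omega_{m+1} beta_min_j
  + omega_{m+2} beta_1se_j.

* **simultaneous stacking** — a joint penalized fit of the target on the
  m meta-feature columns (unpenalized, non-negative) and the p original
  features (penalized, unconstrained), shrinking the combined
  coefficients beta*_j = sum_k omega_k gamma_jk + beta_j towards the
  weighted calibrated priors; suitable when sources are few and priors
  partially informative.

In both modes the combined intercept/coefficients reproduce the stacked
component predictions exactly, so the fitted object is an ordinary GLM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calibration import (
    DEFAULT_TAU_GRID,
    CalibratedPrior,
    PriorEffectSet,
    calibrate,
)
from .cv import FoldPlan, PenalizedPath, fit_codata_free
from .data import GlmDataset
from .families import Family
from .glm import PenaltySpec

logger = logging.getLogger(__name__)

__all__ = [
    "CvPredictorMatrix",
    "StackedModel",
    "build_cv_predictors",
    "fit_meta_standard",
    "combine_standard",
    "fit_meta_simultaneous",
    "combine_simultaneous",
    "predict",
]


@dataclass
class CvPredictorMatrix:
    """Cross-validated linear predictors from the base layer."""

    H0cv: np.ndarray  # n x m co-data columns (intercepts ignored)
    H1cv_min: np.ndarray  # n, co-data-free at lambda_min (with intercepts)
    H1cv_1se: np.ndarray  # n, co-data-free at lambda_1se
    column_meta: list  # source labels + ["lambda_min", "lambda_1se"]

    @property
    def Hcv(self) -> np.ndarray:
        return np.column_stack([self.H0cv, self.H1cv_min, self.H1cv_1se])

    @property
    def m(self) -> int:
        return self.H0cv.shape[1]


@dataclass
class StackedModel:
    """A fitted stacked transfer model, reduced to one GLM."""

    mode: str  # "standard" | "simultaneous"
    family: Family
    omega0: float  # meta intercept (standard) / 0 (simultaneous)
    omega: np.ndarray  # m+2 (standard) or m (simultaneous) weights
    beta0_star: float
    beta_star: np.ndarray
    calibrated: list  # full-data CalibratedPrior per source
    path: Optional[PenalizedPath]
    feature_names: list
    column_meta: list = field(default_factory=list)
    null_model: bool = False  # all meta-weights zero
    baseline: Optional[dict] = None  # selected baseline coefficients
    # (populated when deserialized without the full path object)

    @property
    def m(self) -> int:
        return len(self.calibrated)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.beta_star.shape[0]:
            raise ValueError(
                f"X must have {self.beta_star.shape[0]} columns in training order"
            )
        return self.beta0_star + X @ self.beta_star

    def predict(self, X: np.ndarray, kind: str = "response") -> np.ndarray:
        eta = self.linear_predictor(X)
        if kind == "link":
            return eta
        if kind == "response":
            return self.family.inverse_link(eta)
        raise ValueError("kind must be 'response' or 'link'")


def build_cv_predictors(
    dataset: GlmDataset,
    priors: PriorEffectSet,
    calibration_method: str,
    path: PenalizedPath,
    folds: FoldPlan,
    retained: Optional[np.ndarray] = None,
    allow_negative: bool = False,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
) -> CvPredictorMatrix:
    """Assemble the n x (m+2) cross-validated predictor matrix.

    Every retained source is recalibrated on each fold's included
    samples; the held-out rows receive X_test @ gamma_hat (the intercept
    is deliberately ignored so all co-data columns share a common
    anchor).  Sources with ``retained=False`` keep all-zero columns.  A
    source whose calibration fails inside a fold contributes zeros for
    that fold, with a warning.
    """
    n, m = dataset.n, priors.m
    if retained is None:
        retained = np.ones(m, dtype=bool)
    retained = np.asarray(retained, dtype=bool)
    H0 = np.zeros((n, m))
    for k in range(1, folds.K + 1):
        tr, te = folds.train_rows(k), folds.test_rows(k)
        sub = dataset.subset(tr)
        Xte = dataset.X[te]
        for j in range(m):
            if not retained[j]:
                continue
            try:
                cal = calibrate(
                    sub,
                    priors.column(j),
                    calibration_method,
                    allow_negative=allow_negative,
                    tau_grid=tau_grid,
                    source_index=j,
                    source_name=priors.source_names[j],
                )
                H0[te, j] = Xte @ cal.gamma
            except Exception as exc:  # calibration failure: zero column block
                logger.warning(
                    "calibration of source %s failed in fold %d: %s",
                    priors.source_names[j], k, exc,
                )
                H0[te, j] = 0.0
    return CvPredictorMatrix(
        H0cv=H0,
        H1cv_min=path.cv_predictions[:, path.lambda_min_index].copy(),
        H1cv_1se=path.cv_predictions[:, path.lambda_1se_index].copy(),
        column_meta=list(priors.source_names) + ["lambda_min", "lambda_1se"],
    )


def fit_meta_standard(
    dataset: GlmDataset,
    cvmat: CvPredictorMatrix,
    folds: FoldPlan,
    calibrated: Sequence[CalibratedPrior] = (),
    path: Optional[PenalizedPath] = None,
) -> StackedModel:
    """Non-negative lasso meta-learner on the stacked linear predictors.

    The meta-features are not standardized: they already share the
    linear-predictor scale, and rescaling would distort the weighted-sum
    algebra of the combined coefficients.  The meta lambda is chosen by
    cross-validation with the lambda_min rule on the shared fold plan.
    """
    H = cvmat.Hcv
    q = H.shape[1]
    spec = PenaltySpec(
        alpha=1.0,
        lower_bounds=np.zeros(q),
        upper_bounds=np.full(q, np.inf),
        standardize=False,
    )
    meta_ds = GlmDataset(H, dataset.y, dataset.family)
    meta_path = fit_codata_free(meta_ds, spec, folds)
    fit = meta_path.fit_min
    omega0 = float(fit.intercept)
    omega = np.maximum(fit.slopes, 0.0)  # exact non-negativity
    beta0_star, beta_star = combine_standard(omega0, omega, calibrated, path)
    return StackedModel(
        mode="standard",
        family=dataset.family,
        omega0=omega0,
        omega=omega,
        beta0_star=beta0_star,
        beta_star=beta_star,
        calibrated=list(calibrated),
        path=path,
        feature_names=list(dataset.feature_names),
        column_meta=list(cvmat.column_meta),
        null_model=bool(np.all(omega == 0.0)),
    )


def combine_standard(
    omega0: float,
    omega: np.ndarray,
    calibrated: Sequence[CalibratedPrior],
    path: PenalizedPath,
) -> tuple[float, np.ndarray]:
    """Weighted combination of component coefficients (standard mode).

    beta0* = omega0 + omega_{m+1} beta_min_0 + omega_{m+2} beta_1se_0 and
    beta*_j = sum_k omega_k gamma_jk + omega_{m+1} beta_min_j
    + omega_{m+2} beta_1se_j, so the single-GLM predictions equal the
    stacked component predictions.
    """
    omega = np.asarray(omega, dtype=float)
    m = len(calibrated)
    if omega.shape[0] != m + 2:
        raise ValueError(f"expected {m + 2} weights, got {omega.shape[0]}")
    fit_min, fit_1se = path.fit_min, path.fit_1se
    p = fit_min.slopes.shape[0]
    beta = omega[m] * fit_min.slopes + omega[m + 1] * fit_1se.slopes
    for k, cal in enumerate(calibrated):
        if omega[k] != 0.0:
            beta = beta + omega[k] * cal.gamma
    beta0 = float(omega0 + omega[m] * fit_min.intercept + omega[m + 1] * fit_1se.intercept)
    return beta0, beta


def fit_meta_simultaneous(
    dataset: GlmDataset,
    cvmat: CvPredictorMatrix,
    spec: PenaltySpec,
    folds: FoldPlan,
    calibrated: Sequence[CalibratedPrior] = (),
) -> StackedModel:
    """Joint fit of non-negative meta-weights and penalized deviations.

    Regresses the target on [H0cv | X]: the m meta-feature columns are
    unpenalized (penalty factor 0) with lower bound 0, the p feature
    columns carry the user's ridge/lasso penalty; lambda is selected by
    cross-validation (lambda_min rule) on the shared folds.  Only the
    co-data columns enter the meta block; the lambda_min/lambda_1se
    baseline columns are deliberately absent in this mode.
    """
    m = cvmat.m
    n, p = dataset.n, dataset.p
    if m > n / 2:
        raise ValueError(
            f"simultaneous stacking needs few sources (m={m} > n/2={n / 2:.0f}); "
            "use standard stacking"
        )
    # all-zero meta columns (filtered or degenerate sources) necessarily get
    # weight 0; dropping them keeps the zero-source case identical to the
    # plain penalized fit
    keep = np.flatnonzero(np.any(cvmat.H0cv != 0.0, axis=0))
    mk = keep.size
    D = np.column_stack([cvmat.H0cv[:, keep], dataset.X]) if mk else dataset.X
    pf = np.concatenate([np.zeros(mk), np.ones(p)])
    lo = np.concatenate([np.zeros(mk), np.full(p, -np.inf)])
    hi = np.full(mk + p, np.inf)
    joint_spec = PenaltySpec(
        alpha=spec.alpha,
        penalty_factors=pf,
        lower_bounds=lo,
        upper_bounds=hi,
        nlambda=spec.nlambda,
        lambda_min_ratio=spec.lambda_min_ratio,
        standardize=spec.standardize,
    )
    joint_ds = GlmDataset(D, dataset.y, dataset.family)
    joint_path = fit_codata_free(joint_ds, joint_spec, folds)
    fit = joint_path.fit_min
    omega = np.zeros(m)
    omega[keep] = np.maximum(fit.slopes[:mk], 0.0)
    beta_hat = fit.slopes[mk:]
    beta0_star, beta_star = combine_simultaneous(
        float(fit.intercept), omega, beta_hat, calibrated
    )
    return StackedModel(
        mode="simultaneous",
        family=dataset.family,
        omega0=0.0,
        omega=omega,
        beta0_star=beta0_star,
        beta_star=beta_star,
        calibrated=list(calibrated),
        path=joint_path,
        feature_names=list(dataset.feature_names),
        column_meta=list(cvmat.column_meta[:m]),
        null_model=bool(np.all(omega == 0.0) and np.all(beta_hat == 0.0)),
    )


def combine_simultaneous(
    beta0_hat: float,
    omega: np.ndarray,
    beta_hat: np.ndarray,
    calibrated: Sequence[CalibratedPrior],
) -> tuple[float, np.ndarray]:
    """beta0* = beta0_hat; beta*_j = sum_k omega_k gamma_jk + beta_hat_j."""
    omega = np.asarray(omega, dtype=float)
    if omega.shape[0] != len(calibrated):
        raise ValueError("one weight per calibrated source required")
    beta = np.asarray(beta_hat, dtype=float).copy()
    for k, cal in enumerate(calibrated):
        if omega[k] != 0.0:
            beta = beta + omega[k] * cal.gamma
    return float(beta0_hat), beta


def predict(model: StackedModel, Xnew: np.ndarray, kind: str = "response") -> np.ndarray:
    """Predictions of a stacked model on new samples (module-level alias)."""
    return model.predict(Xnew, kind=kind)
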
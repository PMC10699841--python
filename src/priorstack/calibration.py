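"""Calibration of external prior effects to a target dataset.

Each co-data source supplies one prior effect per feature (z_j, e.g. a
penalized-regression coefficient or a signed log10 p-value from an external
study), assumed positively correlated with the target's true coefficients.
Calibration re-maps these onto the target data's scale and shape:

* **exponential** — gamma_j = theta * sign(z_j) * |z_j|^tau with theta,
  tau >= 0: a power law that can rescale (theta) and reshape (tau) the
  priors, fitted by profiling theta over a grid of tau values;
* **isotonic** — any map that preserves the signs and the order of the
  priors, fitted as sign-constrained maximum likelihood on a
  cumulative-sum reparametrization of the ordered features.

Both methods are invariant under multiplication of the priors by a
positive scalar, which is why priors only need rescaling (never
recentering).  After calibration, a source can be pre-filtered by testing
whether its residuals are smaller than those of the intercept-only model
(paired one-sided Wilcoxon signed-rank test at the 5% level).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data import GlmDataset
from .glm import GlmFit, PenaltySpec, fit_penalized, fit_sign_constrained_ml

__all__ = [
    "DEFAULT_TAU_GRID",
    "PriorEffectSet",
    "CalibratedPrior",
    "CumulativeDesign",
    "rescale_priors",
    "exponential_calibrate",
    "build_cumulative_design",
    "recover_gamma",
    "isotonic_calibrate",
    "calibrate",
    "filter_codata",
]

#: tau grid for exponential calibration: 0, 0.25, ..., 3.0
DEFAULT_TAU_GRID = np.round(np.arange(0.0, 3.0 + 1e-9, 0.25), 2)

_RIDGE_EPS = 1e-8


# ---------------------------------------------------------------------------
# prior effects container
# ---------------------------------------------------------------------------
@dataclass
class PriorEffectSet:
    """p x m matrix of prior effects, one column per external source."""

    effects: np.ndarray
    source_names: list[str]
    rescaled: bool = False
    degenerate: np.ndarray = field(default=None)

    def __post_init__(self):
        Z = np.asarray(self.effects, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.ndim != 2:
            raise ValueError("effects must be a p x m matrix")
        self.effects = Z
        if self.degenerate is None:
            self.degenerate = np.all(Z == 0.0, axis=0)
        self.source_names = [str(s) for s in self.source_names]
        if len(self.source_names) != Z.shape[1]:
            raise ValueError("source_names length must match effect columns")

    @property
    def p(self) -> int:
        return self.effects.shape[0]

    @property
    def m(self) -> int:
        return self.effects.shape[1]

    def column(self, k: int) -> np.ndarray:
        return self.effects[:, k]


def rescale_priors(raw: np.ndarray, source_names: Optional[Sequence[str]] = None) -> PriorEffectSet:
    """Divide each column by its maximum absolute value (never recenter).

    Zero columns pass through unchanged and are flagged degenerate.
    """
    Z = np.asarray(raw, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]  # a single source given as a flat vector
    if Z.ndim != 2:
        raise ValueError("prior effects must form a p x m matrix")
    if not np.all(np.isfinite(Z)):
        raise ValueError("prior effects contain non-finite values")
    if source_names is None:
        source_names = [f"source{k + 1}" for k in range(Z.shape[1])]
    scales = np.max(np.abs(Z), axis=0)
    degenerate = scales == 0.0
    out = Z / np.where(degenerate, 1.0, scales)
    return PriorEffectSet(out, list(source_names), rescaled=True, degenerate=degenerate)


# ---------------------------------------------------------------------------
# calibrated prior
# ---------------------------------------------------------------------------
@dataclass
class CalibratedPrior:
    """One source's calibration result: intercept alpha and effects gamma."""

    source_index: int
    alpha: float
    gamma: np.ndarray
    method: str  # "exponential" | "isotonic"
    deviance: float
    theta: Optional[float] = None
    tau: Optional[float] = None
    inverted: bool = False
    retained: bool = True
    filter_pvalue: float = float("nan")
    degenerate: bool = False
    converged: bool = True
    source_name: str = ""

    def linear_predictor(self, X: np.ndarray, include_intercept: bool = True) -> np.ndarray:
        eta = np.asarray(X, float) @ self.gamma
        return eta + self.alpha if include_intercept else eta


def _signed_power(z: np.ndarray, tau: float) -> np.ndarray:
    """sign(z) |z|^tau with the convention 0^0 = 0."""
    out = np.zeros_like(z)
    nz = z != 0.0
    out[nz] = np.sign(z[nz]) * np.abs(z[nz]) ** tau
    return out


def _fit_single_covariate(dataset: GlmDataset, v: np.ndarray, non_negative: bool) -> GlmFit:
    """Intercept + one slope, optionally constrained non-negative."""
    sub = GlmDataset(v[:, None], dataset.y, dataset.family)
    if non_negative:
        return fit_sign_constrained_ml(sub, [1])
    return fit_penalized(
        sub, PenaltySpec(alpha=0.0), lam=_RIDGE_EPS, tol=1e-9
    )


def _null_fit(dataset: GlmDataset) -> tuple[float, float]:
    """Intercept and deviance of the intercept-only model."""
    alpha = dataset.family.null_intercept(dataset.y)
    mu = np.full(dataset.n, dataset.family.null_mean(dataset.y))
    return alpha, dataset.family.deviance(dataset.y, mu)


def exponential_calibrate(
    dataset: GlmDataset,
    z: np.ndarray,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    allow_negative: bool = False,
    source_index: int = 0,
    source_name: str = "",
) -> CalibratedPrior:
    """Exponential (power-law) calibration of one source.

    For each tau in the grid, the single covariate
    v_i = sum_j sign(z_j)|z_j|^tau x_ij is regressed on the target
    (intercept free, slope theta >= 0 unless ``allow_negative``); the tau
    with the smallest in-sample deviance wins and the calibrated effects
    are gamma_j = theta_hat * sign(z_j)|z_j|^tau_hat.
    """
    z = np.asarray(z, dtype=float).ravel()
    if z.shape[0] != dataset.p:
        raise ValueError("prior effect length must equal the number of features")
    tau_grid = np.asarray(tau_grid, dtype=float).ravel()
    if tau_grid.size == 0 or np.any(tau_grid < 0):
        raise ValueError("tau_grid must be non-empty and non-negative")
    if np.all(z == 0.0):
        alpha, dev = _null_fit(dataset)
        return CalibratedPrior(
            source_index, alpha, np.zeros_like(z), "exponential", dev,
            theta=0.0, tau=float(tau_grid[0]), degenerate=True,
            source_name=source_name,
        )
    best = None
    for tau in tau_grid:
        s = _signed_power(z, float(tau))
        v = dataset.X @ s
        fit = _fit_single_covariate(dataset, v, non_negative=not allow_negative)
        if best is None or fit.deviance < best[0] - 1e-15:
            best = (fit.deviance, float(tau), fit, s)
    dev, tau_hat, fit, s = best
    theta_hat = float(fit.slopes[0])
    gamma = theta_hat * s
    return CalibratedPrior(
        source_index, float(fit.intercept), gamma, "exponential", dev,
        theta=theta_hat, tau=tau_hat, inverted=theta_hat < 0,
        converged=fit.converged, source_name=source_name,
    )


# ---------------------------------------------------------------------------
# isotonic calibration via the cumulative-sum design
# ---------------------------------------------------------------------------
@dataclass
class CumulativeDesign:
    """Cumulative-sum reparametrization of features ordered by the priors.

    Features with equal priors are merged into one group (their columns
    summed) so that equal priors receive equal calibrated effects; zero
    priors are excluded entirely (their effects are fixed at zero).  With
    groups ordered by ascending prior value and q of them negative, the
    design column for group a is the cumulative sum of group columns
    1..a for a <= q and a..G for a > q; the effects of the design columns
    are sign-constrained (non-positive on the first q, non-negative
    after), which reproduces exactly the sign- and order-constraints on
    the original effects.
    """

    W: np.ndarray  # n x G
    signs: np.ndarray  # G entries in {-1, +1}
    q: int  # number of negative groups
    groups: list  # original feature indices per ordered group
    group_z: np.ndarray  # the (distinct) prior value of each group
    p: int  # original feature count

    @property
    def n_groups(self) -> int:
        return self.W.shape[1]


def build_cumulative_design(X: np.ndarray, z: np.ndarray) -> CumulativeDesign:
    """Order features by the priors, merge ties, build cumulative sums."""
    X = np.asarray(X, dtype=float)
    z = np.asarray(z, dtype=float).ravel()
    if not np.all(np.isfinite(z)):
        raise ValueError("prior effects contain non-finite values")
    if X.ndim != 2 or X.shape[1] != z.shape[0]:
        raise ValueError("X columns must match prior effect length")
    nonzero = np.flatnonzero(z != 0.0)
    values = np.unique(z[nonzero])  # ascending distinct nonzero priors
    groups = [nonzero[z[nonzero] == v] for v in values]
    q = int(np.sum(values < 0))
    G = len(groups)
    n = X.shape[0]
    comp = np.empty((n, G))
    for a, idx in enumerate(groups):
        comp[:, a] = X[:, idx].sum(axis=1)
    W = np.empty((n, G))
    if q > 0:
        W[:, :q] = np.cumsum(comp[:, :q], axis=1)
    if G > q:
        W[:, q:] = np.cumsum(comp[:, q:][:, ::-1], axis=1)[:, ::-1]
    signs = np.concatenate([np.full(q, -1, dtype=int), np.full(G - q, 1, dtype=int)])
    return CumulativeDesign(W=W, signs=signs, q=q, groups=groups, group_z=values, p=z.shape[0])


def recover_gamma(delta: np.ndarray, design: CumulativeDesign, tol: float = 1e-8) -> np.ndarray:
    """Map design-column effects delta back to per-feature effects gamma.

    In the ordered groups, gamma_(a) is the tail sum of delta over a..q
    for the negative block and the head sum over q+1..a for the
    non-negative block; members of a group share its value and zero-prior
    features stay at zero.
    """
    delta = np.asarray(delta, dtype=float).ravel()
    G = design.n_groups
    if delta.shape[0] != G:
        raise ValueError("delta length must equal the number of design columns")
    q = design.q
    if np.any(delta[:q] > tol) or np.any(delta[q:] < -tol):
        raise ValueError("delta violates the design's sign constraints")
    d = delta.copy()
    d[:q] = np.minimum(d[:q], 0.0)
    d[q:] = np.maximum(d[q:], 0.0)
    g_group = np.empty(G)
    if q > 0:
        g_group[:q] = np.cumsum(d[:q][::-1])[::-1]  # tail sums
    if G > q:
        g_group[q:] = np.cumsum(d[q:])  # head sums
    gamma = np.zeros(design.p)
    for a, idx in enumerate(design.groups):
        gamma[idx] = g_group[a]
    return gamma


def _isotonic_fit(dataset: GlmDataset, z: np.ndarray) -> tuple[GlmFit, np.ndarray]:
    design = build_cumulative_design(dataset.X, z)
    if design.n_groups == 0:
        alpha, dev = _null_fit(dataset)
        return GlmFit(alpha, np.zeros(0), 0.0, True, dev), np.zeros(dataset.p)
    sub = GlmDataset(design.W, dataset.y, dataset.family)
    fit = fit_sign_constrained_ml(sub, design.signs)
    gamma = recover_gamma(fit.slopes, design, tol=np.inf)
    return fit, gamma


def isotonic_calibrate(
    dataset: GlmDataset,
    z: np.ndarray,
    allow_negative: bool = False,
    source_index: int = 0,
    source_name: str = "",
) -> CalibratedPrior:
    """Isotonic calibration: sign- and order-preserving effects.

    Fits the sign-constrained model on the cumulative-sum design and
    recovers per-feature effects.  With ``allow_negative`` the inverted
    constraints (priors negated) are also fitted and the lower-deviance
    model wins, flagged ``inverted``.
    """
    z = np.asarray(z, dtype=float).ravel()
    if z.shape[0] != dataset.p:
        raise ValueError("prior effect length must equal the number of features")
    if np.all(z == 0.0):
        alpha, dev = _null_fit(dataset)
        return CalibratedPrior(
            source_index, alpha, np.zeros_like(z), "isotonic", dev,
            degenerate=True, source_name=source_name,
        )
    fit, gamma = _isotonic_fit(dataset, z)
    inverted = False
    if allow_negative:
        fit_inv, gamma_inv = _isotonic_fit(dataset, -z)
        if fit_inv.deviance < fit.deviance:
            fit, gamma, inverted = fit_inv, gamma_inv, True
    return CalibratedPrior(
        source_index, float(fit.intercept), gamma, "isotonic", fit.deviance,
        inverted=inverted, converged=fit.converged, source_name=source_name,
    )


def calibrate(
    dataset: GlmDataset,
    z: np.ndarray,
    method: str,
    allow_negative: bool = False,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    source_index: int = 0,
    source_name: str = "",
) -> CalibratedPrior:
    """Dispatch to exponential or isotonic calibration."""
    if method == "exponential":
        return exponential_calibrate(
            dataset, z, tau_grid=tau_grid, allow_negative=allow_negative,
            source_index=source_index, source_name=source_name,
        )
    if method == "isotonic":
        return isotonic_calibrate(
            dataset, z, allow_negative=allow_negative,
            source_index=source_index, source_name=source_name,
        )
    raise ValueError(f"unknown calibration method {method!r}")


# ---------------------------------------------------------------------------
# co-data filter
# ---------------------------------------------------------------------------
def _residual_magnitudes(dataset: GlmDataset, mu: np.ndarray) -> np.ndarray:
    """Gaussian: |raw residuals|; binomial: |deviance residuals|."""
    if dataset.family.name == "gaussian":
        return np.abs(dataset.y - mu)
    return np.sqrt(dataset.family.unit_deviance(dataset.y, mu))


def filter_codata(
    dataset: GlmDataset,
    calibrated: CalibratedPrior,
    level: float = 0.05,
) -> CalibratedPrior:
    """Retain a source only if calibration beats the intercept-only model.

    Pairs per-sample residual magnitudes of the calibrated model with
    those of the intercept-only model and applies the one-sided Wilcoxon
    signed-rank test (zeros dropped; exact null for <= 25 informative
    pairs without ties, else normal approximation with continuity
    correction).  ``retained`` is set when p <= level.
    """
    mu_cal = dataset.family.inverse_link(calibrated.linear_predictor(dataset.X))
    mu_null = np.full(dataset.n, dataset.family.null_mean(dataset.y))
    r_cal = _residual_magnitudes(dataset, mu_cal)
    r_null = _residual_magnitudes(dataset, mu_null)
    d = r_null - r_cal  # positive: calibration fits better
    d = d[d != 0.0]
    if d.size == 0:
        pval = 1.0
    else:
        exact = d.size <= 25 and np.unique(np.abs(d)).size == d.size
        res = stats.wilcoxon(
            d,
            alternative="greater",
            zero_method="wilcox",
            correction=True,
            method="exact" if exact else "approx",
        )
        pval = float(res.pvalue)
    return dataclasses.replace(
        calibrated, retained=bool(pval <= level), filter_pvalue=pval
    )
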
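"""Benchmark simulation designs for transfer learning with prior effects.

Two generators are provided, each producing a target dataset (train +
held-out test), several source datasets, and the true coefficient
vectors:

* the **external design**: AR(0.5)-correlated features, equal effect
  sizes (0.5) on the first s features of the target, and source
  coefficients displaced by +-h/p (transferable) or +-2h/p with causal
  positions scrambled (non-transferable);
* the **internal design**: AR(rho_x)-correlated features and Gaussian
  coefficients that are thinned to a fraction pi of nonzeros and
  correlated across datasets (rho_beta among the target and two
  transferable sources; the remaining source independent), with the two
  transferable coefficient sets passed through square / square-root
  distortions so calibration has real work to do; targets carry a fixed
  signal fraction w of the variance.

Prior effects are then derived exactly as a practitioner would: each
source is fitted with cross-validated penalized regression and its
lambda_min coefficients become one prior-effect column.  Predictive
performance is reported as the percent-of-null metric: test MSE
(gaussian) or mean logistic deviance (binomial) relative to predicting
the training mean, times 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import PriorEffectSet
from .cv import make_folds, fit_codata_free
from .data import GlmDataset
from .families import get_family
from .glm import PenaltySpec

__all__ = [
    "ExternalScenario",
    "InternalScenario",
    "SimulatedStudy",
    "simulate_external",
    "simulate_internal",
    "derive_priors",
    "percent_of_null",
    "run_study",
    "summarize_study",
]


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------
@dataclass
class ExternalScenario:
    """External benchmark design (AR(0.5) features, shifted coefficients)."""

    family: str = "gaussian"
    h_shift: float = 5.0
    K: int = 5  # number of source datasets
    Ka: int = 5  # transferable sources (the first Ka of K)
    n_target: int = 100
    n_source: int = 150
    s: int = 50  # nonzero target coefficients
    p: int = 1000
    n_test: int = 10_000

    def __post_init__(self):
        if not 0 <= self.Ka <= self.K:
            raise ValueError("need 0 <= Ka <= K")
        if 3 * self.s > self.p:
            raise ValueError("non-transferable construction needs 3s <= p")


@dataclass
class InternalScenario:
    """Internal benchmark design (AR(rho_x) features, correlated effects)."""

    family: str = "gaussian"
    rho_x: float = 0.95
    rho_beta: float = 0.99
    pi: float = 0.2  # nonzero probability (0.2 dense / 0.05 sparse)
    w: float = 0.8  # signal weight: Var(signal)/Var(response)
    n_target: int = 100
    n_source: int = 150
    n_sources: int = 3
    p: int = 500
    n_test: int = 10_000
    beta3_transform: str = "sqrt"  # "sqrt" | "identity"

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if not 0.0 < self.rho_x < 1.0:
            raise ValueError("rho_x must lie in (0, 1)")
        if self.beta3_transform not in ("sqrt", "identity"):
            raise ValueError("beta3_transform must be 'sqrt' or 'identity'")


@dataclass
class SimulatedStudy:
    """One simulated replicate: target train/test, sources, true effects."""

    target_train: GlmDataset
    target_test: GlmDataset
    sources: list
    true_beta_target: np.ndarray
    true_beta_sources: list
    derived_priors: Optional[PriorEffectSet] = None


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------
def _ar_cholesky(p: int, rho: float) -> np.ndarray:
    """Upper-triangular R with R'R the AR(rho) correlation matrix."""
    idx = np.arange(p)
    sigma = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(sigma).T


def _gaussian_features(rng: np.random.Generator, n: int, R: np.ndarray) -> np.ndarray:
    return rng.standard_normal((n, R.shape[0])) @ R


def simulate_external(
    scenario: ExternalScenario, seed: int | np.random.Generator = 0
) -> SimulatedStudy:
    """Generate one replicate of the external design."""
    rng = np.random.default_rng(seed)
    fam = get_family(scenario.family)
    p, s, h = scenario.p, scenario.s, scenario.h_shift
    R = _ar_cholesky(p, 0.5)

    beta0 = np.zeros(p)
    beta0[:s] = 0.5
    betas = []
    for k in range(scenario.K):
        flip = np.where(rng.binomial(1, 0.5, size=p) == 1, -1.0, 1.0)
        if k < scenario.Ka:  # transferable: small displacement of the target
            bk = beta0 + flip * h / p
        else:  # non-transferable: double displacement, causal slots scrambled
            bk = flip * 2.0 * h / p
            bk[s : 2 * s] += 0.5
            tail = np.zeros(p - 2 * s)
            tail[:s] = 0.5  # s causal slots among the remaining positions
            rng.shuffle(tail)
            bk[2 * s :] += tail
        betas.append(bk)

    def make_target(n: int) -> GlmDataset:
        X = _gaussian_features(rng, n, R)
        eta = X @ beta0
        if fam.name == "gaussian":
            y = eta + rng.standard_normal(n)
        else:
            y = rng.binomial(1, fam.inverse_link(eta)).astype(float)
        return GlmDataset(X, y, fam)

    target_train = make_target(scenario.n_target)
    target_test = make_target(scenario.n_test)

    sources = []
    for bk in betas:
        Xk = _gaussian_features(rng, scenario.n_source, R)
        eta = 0.5 + Xk @ bk
        if fam.name == "gaussian":
            yk = eta + rng.standard_normal(scenario.n_source)
        else:
            yk = rng.binomial(1, fam.inverse_link(eta)).astype(float)
        sources.append(GlmDataset(Xk, yk, fam))

    return SimulatedStudy(target_train, target_test, sources, beta0, betas)


def internal_coefficients(
    scenario: InternalScenario, rng: np.random.Generator
) -> tuple[np.ndarray, list]:
    """Draw the four correlated coefficient vectors of the internal design.

    Returns (target beta, [source betas]) after thinning and the
    transferable-source transforms.
    """
    m = scenario.n_sources + 1  # datasets 0 (target), 1..3 (sources)
    C = np.full((m, m), scenario.rho_beta)
    C[1, :] = 0.0
    C[:, 1] = 0.0
    np.fill_diagonal(C, 1.0)
    L = np.linalg.cholesky(C)
    B1 = rng.standard_normal((scenario.p, m)) @ L.T
    B2 = rng.standard_normal((scenario.p, m)) @ L.T
    cut = stats.norm.ppf(1.0 - scenario.pi)
    B = B1 * (B2 > cut)
    beta0 = B[:, 0]
    b1, b2, b3 = B[:, 1], B[:, 2], B[:, 3]
    b2 = np.sign(b2) * np.abs(b2) ** 2
    if scenario.beta3_transform == "sqrt":
        b3 = np.sign(b3) * np.sqrt(np.abs(b3))
    return beta0, [b1, b2, b3]


def simulate_internal(
    scenario: InternalScenario, seed: int | np.random.Generator = 0
) -> SimulatedStudy:
    """Generate one replicate of the internal design."""
    rng = np.random.default_rng(seed)
    fam = get_family(scenario.family)
    R = _ar_cholesky(scenario.p, scenario.rho_x)
    beta0, source_betas = internal_coefficients(scenario, rng)

    def make_dataset(n: int, beta: np.ndarray) -> GlmDataset:
        X = _gaussian_features(rng, n, R)
        z = X @ beta
        sd = z.std()
        zs = (z - z.mean()) / (sd if sd > 0 else 1.0)
        eta = np.sqrt(scenario.w) * zs + np.sqrt(1.0 - scenario.w) * rng.standard_normal(n)
        if fam.name == "gaussian":
            y = eta
        else:
            y = (fam.inverse_link(eta) >= 0.5).astype(float)  # rounded classes
        return GlmDataset(X, y, fam)

    # the target's train and test samples form one dataset: simulate the
    # linear predictor jointly so both share the same standardization
    n_all = scenario.n_target + scenario.n_test
    target_all = make_dataset(n_all, beta0)
    tr = np.arange(scenario.n_target)
    te = np.arange(scenario.n_target, n_all)
    target_train = target_all.subset(tr)
    target_test = target_all.subset(te)
    sources = [make_dataset(scenario.n_source, b) for b in source_betas]
    return SimulatedStudy(target_train, target_test, sources, beta0, source_betas)


# ---------------------------------------------------------------------------
# prior derivation and evaluation
# ---------------------------------------------------------------------------
def derive_priors(
    sources: Sequence[GlmDataset],
    alpha_source: float = 0.0,
    n_folds: int = 10,
    seed: int = 0,
) -> PriorEffectSet:
    """Per-source lambda_min coefficients from cross-validated fits.

    Dense settings use ridge (alpha=0); sparse settings use lasso-like
    elastic net (alpha=0.95) to keep the prior information stable.
    """
    cols = []
    for k, src in enumerate(sources):
        folds = make_folds(src, K=n_folds, seed=seed + k)
        path = fit_codata_free(src, PenaltySpec(alpha=alpha_source), folds)
        cols.append(path.fit_min.slopes)
    Z = np.column_stack(cols)
    return PriorEffectSet(Z, [f"source{k + 1}" for k in range(len(sources))])


def percent_of_null(
    test: GlmDataset, mu_pred: np.ndarray, train_mean: float
) -> float:
    """100 x metric(model) / metric(predicting the training mean).

    Gaussian: test MSE; binomial: mean logistic deviance; the null model
    predicts the training mean (prevalence).
    """
    fam = test.family
    num = fam.deviance(test.y, np.asarray(mu_pred, dtype=float))
    den = fam.deviance(test.y, np.full(test.n, float(train_mean)))
    if den == 0.0:
        raise ValueError("degenerate null model: zero-variance response")
    return 100.0 * num / den


def null_auc_quantile(
    n_controls: int,
    n_cases: int,
    prob: float = 0.95,
    n_sim: Optional[int] = None,
    seed: int = 0,
) -> float:
    """Quantile of the AUC of a random classifier (Mann-Whitney null).

    By default uses the exact null moments of the Mann-Whitney U
    statistic under random ranking — mean 1/2 and variance
    (n0 + n1 + 1) / (12 n0 n1) on the AUC scale — with a normal
    approximation for the quantile.  With ``n_sim`` the quantile is
    instead estimated by Monte-Carlo permutation of ranks.
    """
    n0, n1 = int(n_controls), int(n_cases)
    if n0 < 1 or n1 < 1:
        raise ValueError("need at least one control and one case")
    if n_sim is None:
        sd = np.sqrt((n0 + n1 + 1) / (12.0 * n0 * n1))
        return float(0.5 + stats.norm.ppf(prob) * sd)
    rng = np.random.default_rng(seed)
    n = n0 + n1
    aucs = np.empty(n_sim)
    block = max(1, int(2e7) // n)
    done = 0
    while done < n_sim:
        b = min(block, n_sim - done)
        scores = rng.random((b, n))
        ranks = scores.argsort(axis=1).argsort(axis=1) + 1.0
        u = ranks[:, n0:].sum(axis=1) - n1 * (n1 + 1) / 2.0
        aucs[done : done + b] = u / (n0 * n1)
        done += b
    return float(np.quantile(aucs, prob))


# ---------------------------------------------------------------------------
# study driver
# ---------------------------------------------------------------------------
_STACKED_METHODS = {
    "exp.sta": ("exponential", "standard"),
    "exp.sim": ("exponential", "simultaneous"),
    "iso.sta": ("isotonic", "standard"),
    "iso.sim": ("isotonic", "simultaneous"),
}


def _simulate(scenario, seed):
    if isinstance(scenario, ExternalScenario):
        return simulate_external(scenario, seed)
    if isinstance(scenario, InternalScenario):
        return simulate_internal(scenario, seed)
    raise TypeError(f"unknown scenario type {type(scenario).__name__}")


def run_study(
    scenario,
    methods: Sequence[str],
    n_reps: int = 10,
    seed: int = 0,
    alpha_target: float = 0.0,
    alpha_source: float = 0.0,
    n_folds: int = 10,
    force_exclude_sources: bool = False,
) -> pd.DataFrame:
    """Replicated benchmark: percent-of-null metric per method per rep.

    Methods: ``ridge`` / ``lasso`` (co-data-free baselines), the four
    stacked variants ``{exp,iso}.{sta,sim}``, and ``naive`` (a simple
    regression on the prior-weighted feature sum).  Data generation uses
    sub-streams spawned from the root seed, one per replicate, so adding
    methods never perturbs the simulated datasets.
    """
    from .estimators import PenalizedGlmCV, StackedTransferGlm  # cycle guard

    for name in methods:
        if name not in ("ridge", "lasso", "naive") and name not in _STACKED_METHODS:
            raise ValueError(f"unknown method {name!r}")
    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(n_reps)
    rows = []
    for rep, ss in enumerate(rep_seeds):
        data_ss, prior_ss, fit_ss = ss.spawn(3)
        study = _simulate(scenario, np.random.default_rng(data_ss))
        fold_seed = int(fit_ss.generate_state(1)[0] % (2**31 - 1))
        prior_seed = int(prior_ss.generate_state(1)[0] % (2**31 - 1))
        needs_priors = any(m in _STACKED_METHODS or m == "naive" for m in methods)
        if needs_priors:
            study.derived_priors = derive_priors(
                study.sources, alpha_source=alpha_source,
                n_folds=n_folds, seed=prior_seed,
            )
        train, test = study.target_train, study.target_test
        train_mean = train.family.null_mean(train.y)
        for name in methods:
            if name in ("ridge", "lasso"):
                est = PenalizedGlmCV(
                    family=train.family.name,
                    alpha=0.0 if name == "ridge" else 1.0,
                    n_folds=n_folds,
                    random_state=fold_seed,
                )
                est.fit(train.X, train.y)
                mu = est.predict_mean(test.X)
            elif name == "naive":
                mu = _naive_transfer(train, test, study.derived_priors)
            else:
                calib, stack = _STACKED_METHODS[name]
                Z = study.derived_priors.effects
                if force_exclude_sources:
                    Z = np.zeros_like(Z)
                est = StackedTransferGlm(
                    family=train.family.name,
                    calibration=calib,
                    stacking=stack,
                    alpha=alpha_target,
                    n_folds=n_folds,
                    random_state=fold_seed,
                )
                est.fit(train.X, train.y, priors=Z)
                mu = est.predict_mean(test.X)
            metric = percent_of_null(test, mu, train_mean)
            rows.append(
                {"method": name, "rep": rep, "metric_percent": metric}
            )
    return pd.DataFrame(rows)


def _naive_transfer(train: GlmDataset, test: GlmDataset, priors: PriorEffectSet):
    """Simple regression on the prior-weighted feature sum (cheap anchor)."""
    z = priors.effects.mean(axis=1)
    v_train = train.X @ z
    v_test = test.X @ z
    from .glm import fit_penalized

    sub = GlmDataset(v_train[:, None], train.y, train.family)
    fit = fit_penalized(sub, PenaltySpec(alpha=0.0), lam=1e-8, tol=1e-9)
    return train.family.inverse_link(fit.intercept + fit.slopes[0] * v_test)


def summarize_study(
    results: pd.DataFrame, baseline: Optional[str] = None
) -> pd.DataFrame:
    """Mean +- SD per method; paired one-sided Wilcoxon versus a baseline."""
    out = []
    base = None
    if baseline is not None:
        base = results[results["method"] == baseline].sort_values("rep")[
            "metric_percent"
        ].to_numpy()
    for name, grp in results.groupby("method", sort=False):
        vals = grp.sort_values("rep")["metric_percent"].to_numpy()
        row = {
            "method": name,
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan"),
            "n_reps": int(vals.size),
        }
        if base is not None and name != baseline and vals.size == base.size:
            d = base - vals
            if np.all(d == 0):
                row["p_better"] = 1.0
            else:
                row["p_better"] = float(
                    stats.wilcoxon(d, alternative="greater").pvalue
                )
        out.append(row)
    return pd.DataFrame(out)
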
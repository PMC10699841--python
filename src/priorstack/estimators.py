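"""Scikit-learn style estimators.

:class:`PenalizedGlmCV` is the co-data-free base learner: an elastic-net
GLM with 10-fold cross-validation over a 100-value lambda path, exposing
the lambda_min (default) or lambda_1se fit.

:class:`StackedTransferGlm` is the full two-step transfer learner: it
rescales the supplied prior-effect matrix, calibrates each source to the
training data (exponentially or isotonically), optionally pre-filters
sources with the Wilcoxon residual test, fits the co-data-free penalized
path, and combines everything by standard or simultaneous stacking.  The
fitted model is a single GLM (``intercept_``, ``coef_``) whose
predictions reproduce the stacked components exactly.

Both classes follow the scikit-learn estimator contract (``get_params``
/ ``set_params``, fitted attributes with trailing underscores, input
validation in ``fit``) and compose with sklearn model selection.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .calibration import (
    DEFAULT_TAU_GRID,
    calibrate,
    filter_codata,
    rescale_priors,
)
from .cv import fit_codata_free, make_folds
from .data import GlmDataset
from .families import get_family
from .glm import PenaltySpec
from .stacking import (
    build_cv_predictors,
    fit_meta_simultaneous,
    fit_meta_standard,
)

__all__ = ["PenalizedGlmCV", "StackedTransferGlm"]


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have inconsistent numbers of samples")
    return X, y


class PenalizedGlmCV(BaseEstimator, RegressorMixin):
    """Cross-validated elastic-net GLM (the co-data-free baseline).

    Parameters
    ----------
    family : str, default "gaussian"
        "gaussian" or "binomial" (responses in {0, 1}).
    alpha : float, default 0.0
        Elastic-net mixing; 0 is ridge, 1 is lasso.
    n_folds : int, default 10
        Cross-validation folds (stratified for binomial).
    rule : str, default "lambda_min"
        Which fit ``predict`` uses: "lambda_min" or "lambda_1se".
    standardize : bool, default True
        Standardize features internally before penalized fitting.
    random_state : int, default 0
        Seed for the fold assignment.

    Attributes
    ----------
    coef_, intercept_ : fitted coefficients at the selected rule.
    lambda_min_, lambda_1se_ : selected regularization values.
    path_ : the full :class:`~priorstack.cv.PenalizedPath`.
    """

    def __init__(
        self,
        family: str = "gaussian",
        alpha: float = 0.0,
        n_folds: int = 10,
        rule: str = "lambda_min",
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.family = family
        self.alpha = alpha
        self.n_folds = n_folds
        self.rule = rule
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        if self.rule not in ("lambda_min", "lambda_1se"):
            raise ValueError("rule must be 'lambda_min' or 'lambda_1se'")
        X, y = _check_Xy(X, y)
        dataset = GlmDataset(X, y, self.family)
        folds = make_folds(dataset, K=self.n_folds, seed=self.random_state)
        spec = PenaltySpec(alpha=self.alpha, standardize=self.standardize)
        self.path_ = fit_codata_free(dataset, spec, folds)
        fit = (
            self.path_.fit_min
            if self.rule == "lambda_min"
            else self.path_.fit_1se
        )
        self.coef_ = fit.slopes.copy()
        self.intercept_ = float(fit.intercept)
        self.lambda_min_ = self.path_.lambda_min
        self.lambda_1se_ = self.path_.lambda_1se
        self.n_features_in_ = X.shape[1]
        self.family_ = get_family(self.family)
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of features than at fit")
        return self.intercept_ + X @ self.coef_

    def predict_mean(self, X):
        """Predictions on the mean scale (value or probability)."""
        return self.family_.inverse_link(self.decision_function(X))

    def predict(self, X):
        mu = self.predict_mean(X)
        if self.family_.name == "binomial":
            return (mu >= 0.5).astype(float)
        return mu

    def predict_proba(self, X):
        if self.family_.name != "binomial":
            raise AttributeError("predict_proba requires the binomial family")
        p = self.predict_mean(X)
        return np.column_stack([1.0 - p, p])


class StackedTransferGlm(BaseEstimator, RegressorMixin):
    """Two-step transfer learning: calibrate prior effects, then stack.

    Parameters
    ----------
    family : str, default "gaussian"
    calibration : str, default "isotonic"
        "exponential" (power-law) or "isotonic" (sign/order preserving).
    stacking : str, default "standard"
        "standard" (non-negative lasso on stacked linear predictors) or
        "simultaneous" (joint fit shrinking towards the weighted priors).
    alpha : float, default 0.0
        Elastic-net mixing for the co-data-free path (and the penalized
        feature block in simultaneous mode).
    n_folds : int, default 10
        Shared cross-validation folds for all components.
    filter_sources : bool, default True
        Apply the Wilcoxon residual pre-filter to each calibrated source.
    allow_negative : bool, default False
        Permit negatively correlated priors (inverted calibration).
    tau_grid : sequence of float, optional
        Exponent grid for exponential calibration (default 0..3 by 0.25).
    random_state : int, default 0

    Attributes
    ----------
    coef_, intercept_ : combined GLM coefficients (dense in general).
    omega_ : non-negative meta-weights.
    calibrated_ : per-source calibration results (alpha, gamma, theta,
        tau, retained flag, filter p-value).
    retained_ : boolean mask of sources that passed the filter.
    model_ : the underlying :class:`~priorstack.stacking.StackedModel`.
    path_ : the co-data-free :class:`~priorstack.cv.PenalizedPath`.
    """

    def __init__(
        self,
        family: str = "gaussian",
        calibration: str = "isotonic",
        stacking: str = "standard",
        alpha: float = 0.0,
        n_folds: int = 10,
        filter_sources: bool = True,
        allow_negative: bool = False,
        tau_grid: Optional[Sequence[float]] = None,
        random_state: int = 0,
    ):
        self.family = family
        self.calibration = calibration
        self.stacking = stacking
        self.alpha = alpha
        self.n_folds = n_folds
        self.filter_sources = filter_sources
        self.allow_negative = allow_negative
        self.tau_grid = tau_grid
        self.random_state = random_state

    def fit(self, X, y, priors=None, source_names=None):
        """Fit on the target data with a p x m prior-effect matrix.

        ``priors`` may be raw (any positive scale per column): columns
        are rescaled internally by their maximum absolute value.
        """
        if self.calibration not in ("exponential", "isotonic"):
            raise ValueError("calibration must be 'exponential' or 'isotonic'")
        if self.stacking not in ("standard", "simultaneous"):
            raise ValueError("stacking must be 'standard' or 'simultaneous'")
        X, y = _check_Xy(X, y)
        if priors is None:
            priors = np.zeros((X.shape[1], 0))
        dataset = GlmDataset(X, y, self.family)
        prior_set = rescale_priors(priors, source_names)
        if prior_set.p != dataset.p:
            raise ValueError(
                f"priors have {prior_set.p} rows but X has {dataset.p} columns"
            )
        tau_grid = DEFAULT_TAU_GRID if self.tau_grid is None else np.asarray(
            self.tau_grid, dtype=float
        )
        folds = make_folds(dataset, K=self.n_folds, seed=self.random_state)
        spec = PenaltySpec(alpha=self.alpha)
        path = fit_codata_free(dataset, spec, folds)

        calibrated = []
        for k in range(prior_set.m):
            cal = calibrate(
                dataset,
                prior_set.column(k),
                self.calibration,
                allow_negative=self.allow_negative,
                tau_grid=tau_grid,
                source_index=k,
                source_name=prior_set.source_names[k],
            )
            if self.filter_sources:
                cal = filter_codata(dataset, cal)
            calibrated.append(cal)
        retained = np.array([c.retained for c in calibrated], dtype=bool)

        cvmat = build_cv_predictors(
            dataset,
            prior_set,
            self.calibration,
            path,
            folds,
            retained=retained,
            allow_negative=self.allow_negative,
            tau_grid=tau_grid,
        )
        if self.stacking == "standard":
            model = fit_meta_standard(
                dataset, cvmat, folds, calibrated=calibrated, path=path
            )
        else:
            model = fit_meta_simultaneous(
                dataset, cvmat, spec, folds, calibrated=calibrated
            )
        self.model_ = model
        self.path_ = path
        self.folds_ = folds
        self.calibrated_ = calibrated
        self.retained_ = retained
        self.omega_ = model.omega.copy()
        self.coef_ = model.beta_star.copy()
        self.intercept_ = float(model.beta0_star)
        self.n_features_in_ = X.shape[1]
        self.family_ = get_family(self.family)
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of features than at fit")
        return self.intercept_ + X @ self.coef_

    def predict_mean(self, X):
        """Predictions on the mean scale (value or probability)."""
        return self.family_.inverse_link(self.decision_function(X))

    def predict(self, X):
        mu = self.predict_mean(X)
        if self.family_.name == "binomial":
            return (mu >= 0.5).astype(float)
        return mu

    def predict_proba(self, X):
        if self.family_.name != "binomial":
            raise AttributeError("predict_proba requires the binomial family")
        p = self.predict_mean(X)
        return np.column_stack([1.0 - p, p])
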
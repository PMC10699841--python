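"""Distribution families for the GLM core.

Two families are supported: gaussian responses with the identity link and
binomial responses (coded 0/1) with the logit link.  Each family knows its
inverse link, its per-observation deviance, its null (intercept-only)
prediction, and its deviance residuals, which is everything the rest of the
package needs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Family", "GAUSSIAN", "BINOMIAL", "get_family"]

_EPS = 1e-12
_PMIN = 1e-10


class Family:
    """A GLM family: link, inverse link, deviance and null model."""

    def __init__(self, name: str):
        if name not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {name!r}")
        self.name = name

    def __repr__(self) -> str:  # pragma: no cover
        return f"Family({self.name!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, Family) and other.name == self.name

    def __hash__(self) -> int:
        return hash(("Family", self.name))

    # -- link -------------------------------------------------------------
    def inverse_link(self, eta: np.ndarray) -> np.ndarray:
        """Map the linear predictor to the mean scale."""
        eta = np.asarray(eta, dtype=float)
        if self.name == "gaussian":
            return eta
        # numerically stable logistic
        out = np.empty_like(eta)
        pos = eta >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
        ex = np.exp(eta[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out

    def link(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        if self.name == "gaussian":
            return mu
        mu = np.clip(mu, _PMIN, 1.0 - _PMIN)
        return np.log(mu / (1.0 - mu))

    # -- loss -------------------------------------------------------------
    def deviance(self, y: np.ndarray, mu: np.ndarray) -> float:
        """Mean per-observation deviance (MSE / mean logistic deviance)."""
        return float(np.mean(self.unit_deviance(y, mu)))

    def unit_deviance(self, y: np.ndarray, mu: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        mu = np.asarray(mu, dtype=float)
        if self.name == "gaussian":
            return (y - mu) ** 2
        p = np.clip(mu, _PMIN, 1.0 - _PMIN)
        return -2.0 * (y * np.log(p) + (1.0 - y) * np.log1p(-p))

    def deviance_residuals(self, y: np.ndarray, mu: np.ndarray) -> np.ndarray:
        """Signed square-root of the unit deviance."""
        d = self.unit_deviance(y, mu)
        return np.sign(np.asarray(y, float) - np.asarray(mu, float)) * np.sqrt(d)

    # -- null model -------------------------------------------------------
    def null_mean(self, y: np.ndarray) -> float:
        """Mean prediction of the intercept-only model."""
        return float(np.mean(y))

    def null_intercept(self, y: np.ndarray) -> float:
        mu = self.null_mean(y)
        if self.name == "gaussian":
            return mu
        mu = min(max(mu, _PMIN), 1.0 - _PMIN)
        return float(np.log(mu / (1.0 - mu)))

    def validate_response(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        if self.name == "binomial":
            vals = np.unique(y)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("binomial responses must be coded in {0, 1}")
        return y


GAUSSIAN = Family("gaussian")
BINOMIAL = Family("binomial")


def get_family(family) -> Family:
    """Coerce a family name or Family instance to a Family."""
    if isinstance(family, Family):
        return family
    return Family(str(family))
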
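"""Inverse-variance pooling: fixed-effect and REML random-effects.

Implements the standard normal-normal hierarchical model for k effect
estimates y_i with known sampling variances v_i,

    y_i ~ N(theta_i, v_i),    theta_i ~ N(mu, tau^2),

with tau^2 estimated by restricted maximum likelihood (REML), plus
Cochran's Q, I^2, the DerSimonian-Laird moment estimator as a
diagnostic, normal-approximation confidence intervals, and prediction
intervals for the effect in a new unit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ConvergenceError, InvalidInputError

Method = Literal["fixed", "random_reml"]


@dataclass(frozen=True)
class PooledEffect:
    """A pooled estimate with its variance and heterogeneity statistics."""

    value: float
    variance: float
    tau2: float
    q_stat: float
    i2: float
    k: int
    method: Method

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Normal-approximation confidence interval on the pooling scale."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        return self.value - z * self.se, self.value + z * self.se


@dataclass(frozen=True)
class PredictionInterval:
    """Interval expected to contain the true effect of a new unit."""

    lower: float
    upper: float
    level: float
    method: Literal["z", "t"]


def _extract(estimates: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Values and variances of non-excluded estimates, with scale check."""
    kept = [e for e in estimates if not getattr(e, "excluded", False)]
    if not kept:
        raise InvalidInputError("no non-excluded estimates to pool")
    scales = {getattr(e, "scale", None) for e in kept} - {None}
    if len(scales) > 1:
        raise InvalidInputError(f"cannot pool estimates on mixed scales: {scales}")
    y = np.array([e.value for e in kept], dtype=float)
    v = np.array([e.variance for e in kept], dtype=float)
    if np.any(v <= 0) or not np.all(np.isfinite(y)) or not np.all(np.isfinite(v)):
        raise InvalidInputError("estimates must have finite values and variances > 0")
    return y, v


def _q_i2(y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Cochran's Q with fixed-effect weights and I^2 (%)."""
    k = y.size
    if k < 2:
        return 0.0, 0.0
    w = 1.0 / v
    mu = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu) ** 2))
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    return q, i2


def pool_fixed(estimates: Sequence) -> PooledEffect:
    """Fixed-effect (common-effect) inverse-variance pooled estimate.

    A single estimate passes through unchanged. Q and I^2 are computed
    as side outputs; tau^2 is 0 by definition of the model.
    """
    y, v = _extract(estimates)
    w = 1.0 / v
    sw = float(np.sum(w))
    q, i2 = _q_i2(y, v)
    return PooledEffect(
        value=float(np.sum(w * y) / sw),
        variance=1.0 / sw,
        tau2=0.0,
        q_stat=q,
        i2=i2,
        k=int(y.size),
        method="fixed",
    )


def pool_random_reml(
    estimates: Sequence, tol: float = 1e-8, max_iter: int = 100
) -> PooledEffect:
    """Random-effects pooled estimate with REML between-unit variance.

    tau^2 solves the restricted-likelihood score equation by the standard
    fixed-point (scoring) iteration

        tau2 <- sum(w^2 ((y - mu)^2 - v)) / sum(w^2) + 1 / sum(w),

    w = 1/(v + tau2), floored at 0, declared converged when successive
    iterates differ by less than ``tol``. With a single estimate the
    fixed-effect passthrough is returned with a warning.
    """
    y, v = _extract(estimates)
    k = y.size
    if k < 2:
        warnings.warn(
            "random-effects pooling needs k >= 2; falling back to fixed effect",
            stacklevel=2,
        )
        return pool_fixed(estimates)

    q, i2 = _q_i2(y, v)
    tau2 = _tau2_dl(y, v)  # moment estimate as the starting value
    converged = False
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = float(np.sum(w * y) / np.sum(w))
        new = float(
            np.sum(w**2 * ((y - mu) ** 2 - v)) / np.sum(w**2) + 1.0 / np.sum(w)
        )
        new = max(0.0, new)
        if abs(new - tau2) < tol:
            tau2 = new
            converged = True
            break
        tau2 = new
    if not converged:
        raise ConvergenceError(
            f"REML did not converge within {max_iter} iterations", last_value=tau2
        )

    w = 1.0 / (v + tau2)
    sw = float(np.sum(w))
    return PooledEffect(
        value=float(np.sum(w * y) / sw),
        variance=1.0 / sw,
        tau2=tau2,
        q_stat=q,
        i2=i2,
        k=int(k),
        method="random_reml",
    )


def _tau2_dl(y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian-Laird moment estimator of tau^2 (floored at 0)."""
    k = y.size
    w = 1.0 / v
    mu = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / denom)


def heterogeneity(estimates: Sequence) -> tuple[float, float, float]:
    """Cochran's Q, I^2 (%), and the DerSimonian-Laird tau^2 diagnostic."""
    y, v = _extract(estimates)
    if y.size < 2:
        raise InvalidInputError("heterogeneity statistics need k >= 2 estimates")
    q, i2 = _q_i2(y, v)
    return q, i2, _tau2_dl(y, v)


def prediction_interval(
    pooled: PooledEffect,
    level: float = 0.95,
    method: Literal["z", "t"] = "z",
) -> PredictionInterval:
    """Prediction interval for the true effect of a new unit.

    The new unit's effect has variance tau^2 + Var(mu_hat). The default
    z form uses the standard normal quantile; the t form uses t_{k-2}
    and therefore requires k >= 3.
    """
    if pooled.method != "random_reml":
        raise InvalidInputError(
            "prediction intervals are defined for random-effects fits"
        )
    if not 0 < level < 1:
        raise InvalidInputError("level must lie in (0, 1)")
    spread = math.sqrt(pooled.tau2 + pooled.variance)
    if method == "z":
        crit = stats.norm.ppf(0.5 + level / 2.0)
    elif method == "t":
        if pooled.k < 3:
            raise InvalidInputError("t prediction interval requires k >= 3")
        crit = stats.t.ppf(0.5 + level / 2.0, df=pooled.k - 2)
    else:
        raise InvalidInputError(f"unknown prediction-interval method {method!r}")
    return PredictionInterval(
        lower=pooled.value - crit * spread,
        upper=pooled.value + crit * spread,
        level=level,
        method=method,
    )
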
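"""Independent reference computations used only by the tests.

These deliberately avoid the package's own code paths: the REML oracle
is a brute-force grid search over the restricted log-likelihood, and the
variance oracle is plain Monte-Carlo resampling of multinomial tables.
"""

from __future__ import annotations

import numpy as np


def reml_tau2_grid(y, v, hi: float = 5.0, step: float = 5e-4) -> float:
    """Grid-search maximizer of the restricted log-likelihood over tau^2."""
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    grid = np.arange(0.0, hi + step, step)
    vt = v[None, :] + grid[:, None]
    w = 1.0 / vt
    sw = w.sum(axis=1)
    mu = (w * y).sum(axis=1) / sw
    ll = -0.5 * (
        np.log(vt).sum(axis=1) + np.log(sw) + (w * (y - mu[:, None]) ** 2).sum(axis=1)
    )
    return float(grid[np.argmax(ll)])


def mc_marginal_log_or_variance(
    n: int, cell_probs, rng: np.random.Generator, reps: int = 200_000
) -> float:
    """Empirical variance of the log marginal OR over resampled tables.

    Resamples the joint 2x2 multinomial, applies the same 0.5-per-cell
    continuity handling for degenerate margins, and returns the sample
    variance of logit(p1) - logit(p2).
    """
    draws = rng.multinomial(n, cell_probs, size=reps).astype(float)
    x11, x10, x01, _ = draws.T
    e1 = x11 + x10
    e2 = x11 + x01
    tot = np.full(reps, float(n))
    bad = (e1 == 0) | (e1 == n) | (e2 == 0) | (e2 == n)
    e1 = np.where(bad, e1 + 1.0, e1)  # +0.5 per joint cell adds 1 per margin
    e2 = np.where(bad, e2 + 1.0, e2)
    tot = np.where(bad, tot + 2.0, tot)
    p1 = e1 / tot
    p2 = e2 / tot
    log_or = np.log(p1 / (1.0 - p1)) - np.log(p2 / (1.0 - p2))
    return float(log_or.var(ddof=1))


def random_paired_table_params(rng: np.random.Generator):
    """A non-degenerate (n, p1, p2, rho) tuple with rho inside the
    feasible (Frechet) region for the margins."""
    n = int(rng.integers(200, 1001))
    p1 = float(rng.uniform(0.2, 0.8))
    p2 = float(rng.uniform(0.2, 0.8))
    q1, q2 = 1.0 - p1, 1.0 - p2
    # highest rho for which p1*p2 + rho*sqrt(p1*q1*p2*q2) <= min(p1, p2)
    rho_max = (min(p1, p2) - p1 * p2) / np.sqrt(p1 * q1 * p2 * q2)
    rho = float(rng.uniform(0.0, 0.9 * rho_max))
    return n, p1, p2, rho
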
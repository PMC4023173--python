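"""Monte-Carlo experiments over the full two-step pipeline.

Two canned studies support calibration and consistency claims:

* :func:`null_coverage` — simulate many datasets with no true design
  effect and measure how often the combined contrast's 95% CI covers
  zero (nominal: 95%);
* :func:`recover_design_effect` — simulate datasets with a known design
  effect under the consistency conditions (many meta-analyses,
  moderately large trials) and measure the bias of the combined
  estimate against Monte-Carlo noise.

Child seeds are derived from one master seed, so every replicate is
reproducible and replicates are mutually independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .pipeline import compute_contrasts, pool_contrasts
from .simulate import SimulationConfig, recovery_config, simulate_metaepi_dataset


def child_seeds(seed: int, n: int) -> np.ndarray:
    """``n`` independent 31-bit child seeds derived from ``seed``."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return (state & 0x7FFFFFFF).astype(np.int64)


def _combined_for_config(config: SimulationConfig, within_method: str = "fixed"):
    metas = simulate_metaepi_dataset(config)
    contrasts = compute_contrasts(metas, within_method=within_method)
    if len(contrasts) < 2:
        return None
    return pool_contrasts(
        contrasts, outcome_type=config.outcome_type, within_method=within_method
    )


def null_coverage(
    outcome_type: Literal["binary", "continuous"],
    n_replicates: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> float:
    """Coverage (%) of the combined-contrast CI under a null design effect.

    Each replicate simulates a dataset at the generator's default scale
    (15 meta-analyses, 2-4 trials per design, split-mouth n around 20,
    parallel-arm n around 40) with delta = 0, runs the two-step pipeline
    with fixed-effect within-pooling, and checks whether the level-CI
    of the combined contrast covers zero. Replicates where fewer than
    two meta-analyses survive exclusions are dropped from the
    denominator (this is rare and logged by the pipeline).
    """
    seeds = child_seeds(seed, n_replicates)
    covered = 0
    used = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in seeds:
            config = SimulationConfig(
                outcome_type=outcome_type, delta=0.0, seed=int(s)
            )
            res = _combined_for_config(config)
            if res is None:
                continue
            used += 1
            if res.ci_lower <= 0.0 <= res.ci_upper:
                covered += 1
    if used == 0:
        raise RuntimeError("no replicate produced a poolable dataset")
    return 100.0 * covered / used


@dataclass(frozen=True)
class RecoveryResult:
    """Bias summary of the combined design-effect estimate."""

    true_delta: float
    mean_estimate: float
    mc_se: float
    n_replicates: int

    @property
    def bias(self) -> float:
        return self.mean_estimate - self.true_delta

    @property
    def bias_in_se(self) -> float:
        return abs(self.bias) / self.mc_se


def recover_design_effect(
    outcome_type: Literal["binary", "continuous"],
    delta: float,
    n_replicates: int = 200,
    seed: int = 0,
) -> RecoveryResult:
    """Mean combined estimate over replicates under a known design effect.

    Runs under the consistency conditions (200 meta-analyses per
    dataset, split-mouth n around 400, parallel around 800) so that the
    estimator's first-order asymptotics apply; see the generator
    documentation for why recovery is not assessed at the small-trial
    descriptive scale.
    """
    seeds = child_seeds(seed, n_replicates)
    estimates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in seeds:
            config = recovery_config(outcome_type, delta=delta, seed=int(s))
            res = _combined_for_config(config)
            if res is not None:
                estimates.append(res.combined)
    est = np.asarray(estimates)
    return RecoveryResult(
        true_delta=delta,
        mean_estimate=float(est.mean()),
        mc_se=float(est.std(ddof=1) / math.sqrt(est.size)),
        n_replicates=int(est.size),
    )
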
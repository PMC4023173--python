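"""Synthetic meta-epidemiological datasets with a known design effect.

The generator mirrors the hierarchical structure the two-step analysis
assumes. For meta-analysis m a true effect theta_m ~ N(mu, tau2_effect)
is shared by all its trials, and a design offset
delta_m ~ N(delta, tau2_delta) shifts the split-mouth trials only:
parallel-arm trials are drawn at theta_m, split-mouth trials at
theta_m + delta_m. ``delta`` is therefore the true mean log ROR (binary)
or dSMD (continuous), and the two-step pipeline is a consistent
estimator of it, which makes parameter-recovery tests possible.

Binary trials inject effects on the log-odds scale around a control
risk; split-mouth tables are multinomial draws over the joint cells with
pi11 = p1*p2 + rho*sqrt(p1*q1*p2*q2). Continuous trials draw per-patient
outcomes with unit SDs, so the injected effect is directly on the SMD
scale; split-mouth outcomes are bivariate normal with correlation rho.

Default scale parameters follow the descriptive medians of published
dental meta-analyses of this kind: 15 meta-analyses, 2-4 trials per
design, about 20 patients per split-mouth trial and about 40 (total)
per parallel-arm trial, a modest beneficial mean effect, and a null
design effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np

from . import effects as eff
from .effects import EffectEstimate, PairedBinaryTable, PairedContinuous
from .errors import InvalidInputError
from .io import TrialRecord
from .pipeline import MetaAnalysisInput

RngLike = Union[int, np.random.Generator, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic meta-epidemiological dataset.

    ``mu`` and ``delta`` are on the log-OR scale for binary outcomes and
    the SMD scale for continuous ones. ``patients_split`` is the number
    of patients per split-mouth trial (each contributing both sites);
    ``patients_parallel`` is the per-trial total across both arms, so
    the per-proportion sample sizes of the two designs match, as they do
    in the published trials this emulates (medians 20 vs 40).
    """

    n_meta: int = 15
    trials_per_design: tuple[int, int] = (2, 4)
    patients_split: tuple[int, int] = (15, 25)
    patients_parallel: tuple[int, int] = (30, 50)
    mu: float = -0.3
    tau2_effect: float = 0.1
    delta: float = 0.0
    tau2_delta: float = 0.0
    rho: float = 0.5
    control_risk: float = 0.3
    outcome_type: Literal["binary", "continuous"] = "binary"
    seed: int = 0

    def __post_init__(self):
        for name in ("tau2_effect", "tau2_delta"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        for name in ("trials_per_design", "patients_split", "patients_parallel"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise InvalidInputError(f"{name} must be a non-empty positive range")
        if not 0.0 < self.control_risk < 1.0:
            raise InvalidInputError("control_risk must lie in (0, 1)")
        if not -1.0 <= self.rho <= 1.0:
            raise InvalidInputError("rho must lie in [-1, 1]")
        if self.outcome_type not in ("binary", "continuous"):
            raise InvalidInputError("outcome_type must be binary or continuous")


def simulate_paired_binary_trial(
    n: int, p1: float, p2: float, rho: float, seed: RngLike = None
) -> PairedBinaryTable:
    """Multinomial draw of one split-mouth trial's joint 2x2 cells.

    Cell probabilities come from the margins and the within-patient
    correlation, clamped to the Frechet bounds when rho is infeasible
    (with a warning). Deterministic given the seed.
    """
    if n <= 0:
        raise InvalidInputError("n must be positive")
    rng = _rng(seed)
    probs = eff.paired_cells_from_marginals(p1 * n, p2 * n, n, rho)
    p = np.array([probs.n11, probs.n10, probs.n01, probs.n00]) / n
    n11, n10, n01, n00 = rng.multinomial(n, p)
    return PairedBinaryTable(float(n11), float(n10), float(n01), float(n00))


def simulate_paired_continuous_trial(
    n: int, effect: float, rho: float, seed: RngLike = None
) -> PairedContinuous:
    """Bivariate-normal split-mouth trial, returned as summary statistics.

    Site outcomes have unit SDs, mean difference ``effect`` and
    correlation ``rho``; the summary carries the sample means, per-site
    SDs, the empirical correlation and the sample SD of within-patient
    differences (which therefore drives the variance downstream).
    """
    if not -1.0 < rho < 1.0:
        raise InvalidInputError("rho must lie strictly inside (-1, 1)")
    if n <= 1:
        raise InvalidInputError("need n > 1 patients")
    rng = _rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    x = rng.multivariate_normal([effect, 0.0], cov, size=n, method="cholesky")
    diffs = x[:, 0] - x[:, 1]
    r = float(np.corrcoef(x[:, 0], x[:, 1])[0, 1])
    return PairedContinuous(
        mean_exp=float(x[:, 0].mean()),
        mean_ctl=float(x[:, 1].mean()),
        sd_exp=float(x[:, 0].std(ddof=1)),
        sd_ctl=float(x[:, 1].std(ddof=1)),
        n=n,
        rho=max(-1.0, min(1.0, r)),
        sd_diff=float(diffs.std(ddof=1)),
    )


@dataclass(frozen=True)
class _RawTrial:
    """One simulated trial's raw summary data, before effect computation."""

    meta_id: str
    trial_id: str
    design: Literal["split_mouth", "parallel"]
    table: Optional[PairedBinaryTable] = None
    arms_binary: Optional[eff.BinaryArms] = None
    paired_cont: Optional[PairedContinuous] = None
    arms_cont: Optional[eff.ContinuousArms] = None


def _simulate_raw(config: SimulationConfig) -> list[_RawTrial]:
    rng = np.random.default_rng(config.seed)
    lo_t, hi_t = config.trials_per_design
    out: list[_RawTrial] = []
    for m in range(config.n_meta):
        meta_id = f"MA{m + 1:03d}"
        theta = rng.normal(config.mu, math.sqrt(config.tau2_effect))
        delta_m = rng.normal(config.delta, math.sqrt(config.tau2_delta))
        k_split = int(rng.integers(lo_t, hi_t + 1))
        k_par = int(rng.integers(lo_t, hi_t + 1))
        for j in range(k_split):
            tid = f"{meta_id}-S{j + 1}"
            n = int(rng.integers(config.patients_split[0], config.patients_split[1] + 1))
            if config.outcome_type == "binary":
                p2 = config.control_risk
                p1 = _expit(_logit(p2) + theta + delta_m)
                table = simulate_paired_binary_trial(n, p1, p2, config.rho, rng)
                out.append(_RawTrial(meta_id, tid, "split_mouth", table=table))
            else:
                data = simulate_paired_continuous_trial(
                    n, theta + delta_m, config.rho, rng
                )
                out.append(_RawTrial(meta_id, tid, "split_mouth", paired_cont=data))
        for j in range(k_par):
            tid = f"{meta_id}-P{j + 1}"
            total = int(
                rng.integers(config.patients_parallel[0], config.patients_parallel[1] + 1)
            )
            n_arm = max(1, total // 2)
            if config.outcome_type == "binary":
                pc = config.control_risk
                pe = _expit(_logit(pc) + theta)
                arms = eff.BinaryArms(
                    events_exp=int(rng.binomial(n_arm, pe)),
                    total_exp=n_arm,
                    events_ctl=int(rng.binomial(n_arm, pc)),
                    total_ctl=n_arm,
                )
                out.append(_RawTrial(meta_id, tid, "parallel", arms_binary=arms))
            else:
                xe = rng.normal(theta, 1.0, size=n_arm)
                xc = rng.normal(0.0, 1.0, size=n_arm)
                arms = eff.ContinuousArms(
                    mean_exp=float(xe.mean()),
                    sd_exp=float(xe.std(ddof=1)),
                    n_exp=n_arm,
                    mean_ctl=float(xc.mean()),
                    sd_ctl=float(xc.std(ddof=1)),
                    n_ctl=n_arm,
                )
                out.append(_RawTrial(meta_id, tid, "parallel", arms_cont=arms))
    return out


def _analyze_raw(raw: _RawTrial, config: SimulationConfig) -> EffectEstimate:
    if raw.table is not None:
        return eff.marginal_log_or_split_mouth(raw.table, trial_id=raw.trial_id)
    if raw.arms_binary is not None:
        return eff.log_or_parallel(raw.arms_binary, trial_id=raw.trial_id)
    if raw.paired_cont is not None:
        return eff.smd_split_mouth(
            raw.paired_cont, default_rho=config.rho, trial_id=raw.trial_id
        )
    return eff.smd_parallel(raw.arms_cont, trial_id=raw.trial_id)


def simulate_metaepi_dataset(config: SimulationConfig) -> list[MetaAnalysisInput]:
    """Simulate a dataset and compute per-trial effects, grouped by meta-analysis.

    The outcomes are already on the benefit-downward coding, so no
    further orientation is applied. Fully reproducible given
    ``config.seed``.
    """
    metas: dict[str, MetaAnalysisInput] = {}
    for raw in _simulate_raw(config):
        est = _analyze_raw(raw, config)
        if raw.meta_id not in metas:
            metas[raw.meta_id] = MetaAnalysisInput(
                id=raw.meta_id, outcome_type=config.outcome_type, trials=[]
            )
        metas[raw.meta_id].trials.append(est)
        metas[raw.meta_id].trial_ids.add(raw.trial_id)
    return list(metas.values())


def simulate_trial_records(config: SimulationConfig) -> list[TrialRecord]:
    """Simulate a dataset in the flat CSV schema (same draws as above).

    Split-mouth binary trials are written as joint cells; continuous
    ones carry the sample per-site SDs, correlation and difference SD,
    so the CSV path reproduces the in-memory analysis exactly.
    """
    records: list[TrialRecord] = []
    for raw in _simulate_raw(config):
        kw = dict(
            meta_id=raw.meta_id,
            trial_id=raw.trial_id,
            design=raw.design,
            outcome_type=config.outcome_type,
            beneficial_direction="lower",
        )
        if raw.table is not None:
            t = raw.table
            records.append(
                TrialRecord(**kw, n11=t.n11, n10=t.n10, n01=t.n01, n00=t.n00)
            )
        elif raw.arms_binary is not None:
            a = raw.arms_binary
            records.append(
                TrialRecord(
                    **kw,
                    events_exp=float(a.events_exp),
                    total_exp=float(a.total_exp),
                    events_ctl=float(a.events_ctl),
                    total_ctl=float(a.total_ctl),
                )
            )
        elif raw.paired_cont is not None:
            d = raw.paired_cont
            records.append(
                TrialRecord(
                    **kw,
                    mean_exp=d.mean_exp,
                    sd_exp=d.sd_exp,
                    n_exp=float(d.n),
                    mean_ctl=d.mean_ctl,
                    sd_ctl=d.sd_ctl,
                    n_ctl=float(d.n),
                    rho=d.rho,
                    sd_diff=d.sd_diff,
                )
            )
        else:
            a = raw.arms_cont
            records.append(
                TrialRecord(
                    **kw,
                    mean_exp=a.mean_exp,
                    sd_exp=a.sd_exp,
                    n_exp=float(a.n_exp),
                    mean_ctl=a.mean_ctl,
                    sd_ctl=a.sd_ctl,
                    n_ctl=float(a.n_ctl),
                )
            )
    return records


#: Study conditions for consistency (parameter-recovery) experiments:
#: many meta-analyses and moderately large trials, where the first-order
#: asymptotics of the log-odds estimators hold and the estimator's
#: O(1/n) small-sample bias is negligible next to Monte-Carlo noise.
RECOVERY_CONDITIONS = dict(
    n_meta=200,
    patients_split=(360, 440),
    patients_parallel=(720, 880),
    mu=0.0,
    tau2_effect=0.15,
    tau2_delta=0.1,
    control_risk=0.4,
)


def recovery_config(
    outcome_type: Literal["binary", "continuous"], delta: float, seed: int
) -> SimulationConfig:
    """A :class:`SimulationConfig` under the consistency-test conditions."""
    return SimulationConfig(
        outcome_type=outcome_type, delta=delta, seed=seed, **RECOVERY_CONDITIONS
    )
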
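"""The two-step meta-epidemiological contrast of trial designs.

Step one treats each meta-analysis separately: the split-mouth trials
and the parallel-arm trials are pooled within their design subgroups,
and the difference of the two subgroup summaries is the meta-analysis's
design contrast — a log ratio of odds ratios (log ROR) for binary
outcomes, a difference in standardized mean differences (dSMD) for
continuous outcomes — with variance equal to the sum of the subgroup
variances. Step two pools these contrasts across meta-analyses with a
REML random-effects model, yielding a combined contrast, normal CI,
two-tailed z p-value, heterogeneity statistics and a 95% prediction
interval.

A contrast below zero (ROR < 1, dSMD < 0) means split-mouth trials
yielded larger (more beneficial) intervention effects than parallel-arm
trials in the same meta-analysis.

Meta-analyses sharing trials would violate the independence of the
contrasts, so overlapping meta-analyses are resolved by keeping the one
with more trials (``exclude_overlapping``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import pandas as pd
from scipy import stats

from . import effects as eff
from .effects import DEFAULT_RHO, EffectEstimate
from .errors import InvalidInputError
from .io import TrialRecord
from .pooling import (
    PooledEffect,
    PredictionInterval,
    pool_fixed,
    pool_random_reml,
    prediction_interval,
)

logger = logging.getLogger("splitmeta")

WithinMethod = Literal["fixed", "random_reml"]


@dataclass
class MetaAnalysisInput:
    """One meta-analysis: per-trial effects tagged by design."""

    id: str
    outcome_type: Literal["binary", "continuous"]
    trials: list[EffectEstimate]
    trial_ids: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.trial_ids:
            self.trial_ids = {t.trial_id for t in self.trials}

    def subgroup(self, design: str) -> list[EffectEstimate]:
        return [t for t in self.trials if t.design == design and not t.excluded]


@dataclass(frozen=True)
class DesignContrast:
    """One meta-analysis's log ROR or dSMD with its variance."""

    meta_id: str
    value: float
    variance: float
    k_split: int
    k_parallel: int

    def __post_init__(self):
        if not math.isfinite(self.value) or not (self.variance > 0):
            raise InvalidInputError(
                f"contrast for {self.meta_id!r} must be finite with variance > 0"
            )


@dataclass(frozen=True)
class MetaEpiResult:
    """Combined design contrast across meta-analyses."""

    combined: float
    ci_lower: float
    ci_upper: float
    p_value: float
    tau2: float
    i2: float
    prediction: PredictionInterval
    n_meta: int
    within_method: WithinMethod
    outcome_type: Literal["binary", "continuous"]
    variance: float


@dataclass(frozen=True)
class ExclusionRecord:
    """One dropped trial or meta-analysis, with a machine-readable reason."""

    level: Literal["trial", "meta_analysis"]
    id: str
    reason: str
    detail: str = ""


class SubgroupEmptyError(InvalidInputError):
    """A design subgroup is empty after trial-level exclusions."""


# ---------------------------------------------------------------------------
# Step one: per-meta-analysis contrasts
# ---------------------------------------------------------------------------

def design_contrast(
    meta: MetaAnalysisInput, within_method: WithinMethod = "fixed"
) -> DesignContrast:
    """Split-mouth minus parallel-arm subgroup summary for one meta-analysis.

    The subgroup summaries are pooled by the requested within-method
    (fixed-effect by default); the contrast's variance is the sum of the
    two subgroup variances because the subgroups share no trials.
    """
    split = meta.subgroup("split_mouth")
    parallel = meta.subgroup("parallel")
    if not split or not parallel:
        raise SubgroupEmptyError(
            f"meta-analysis {meta.id!r} lacks a usable "
            f"{'split-mouth' if not split else 'parallel-arm'} subgroup"
        )
    pool = pool_fixed if within_method == "fixed" else pool_random_reml
    s: PooledEffect = pool(split)
    p: PooledEffect = pool(parallel)
    return DesignContrast(
        meta_id=meta.id,
        value=s.value - p.value,
        variance=s.variance + p.variance,
        k_split=len(split),
        k_parallel=len(parallel),
    )


def compute_contrasts(
    metas: Sequence[MetaAnalysisInput],
    within_method: WithinMethod = "fixed",
    exclusions: Optional[list[ExclusionRecord]] = None,
) -> list[DesignContrast]:
    """Contrasts for every eligible meta-analysis, dropping the rest.

    Meta-analyses whose split-mouth or parallel subgroup is empty after
    trial-level exclusions (e.g. all binary trials double-zero) are
    dropped with a logged :class:`ExclusionRecord`.
    """
    out: list[DesignContrast] = []
    for meta in metas:
        try:
            out.append(design_contrast(meta, within_method))
        except SubgroupEmptyError as exc:
            logger.info("dropping meta-analysis %s: %s", meta.id, exc)
            if exclusions is not None:
                exclusions.append(
                    ExclusionRecord("meta_analysis", meta.id, "empty_subgroup", str(exc))
                )
    return out


# ---------------------------------------------------------------------------
# Step two: pooling contrasts across meta-analyses
# ---------------------------------------------------------------------------

def pool_contrasts(
    contrasts: Sequence[DesignContrast],
    outcome_type: Literal["binary", "continuous"] = "binary",
    within_method: WithinMethod = "fixed",
    level: float = 0.95,
) -> MetaEpiResult:
    """REML random-effects pooling of design contrasts across meta-analyses.

    Returns the combined log ROR or dSMD with a normal-approximation CI,
    a two-tailed z p-value, tau^2 and I^2 across meta-analyses, and a
    z-method prediction interval at the same level.
    """
    if len(contrasts) < 2:
        raise InvalidInputError("pooling contrasts requires at least 2 meta-analyses")
    pooled = pool_random_reml(contrasts)
    lo, hi = pooled.ci(level)
    z = pooled.value / pooled.se
    p = 2.0 * stats.norm.sf(abs(z))
    return MetaEpiResult(
        combined=pooled.value,
        ci_lower=lo,
        ci_upper=hi,
        p_value=p,
        tau2=pooled.tau2,
        i2=pooled.i2,
        prediction=prediction_interval(pooled, level=level, method="z"),
        n_meta=pooled.k,
        within_method=within_method,
        outcome_type=outcome_type,
        variance=pooled.variance,
    )


# ---------------------------------------------------------------------------
# Dataset-level filters
# ---------------------------------------------------------------------------

def exclude_overlapping(
    metas: Sequence[MetaAnalysisInput],
    exclusions: Optional[list[ExclusionRecord]] = None,
) -> list[MetaAnalysisInput]:
    """Drop overlapping meta-analyses, keeping the one with more trials.

    Two meta-analyses overlap when they share at least one trial id.
    The member with fewer trials is removed; ties keep the
    earlier-listed meta-analysis. The rule is applied iteratively until
    the surviving trial-id sets are pairwise disjoint; input order is
    preserved.
    """
    kept = list(metas)
    changed = True
    while changed:
        changed = False
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                if kept[i].trial_ids & kept[j].trial_ids:
                    drop = j if len(kept[j].trials) <= len(kept[i].trials) else i
                    keep = i if drop == j else j
                    logger.info(
                        "overlap between %s and %s: dropping %s (fewer trials)",
                        kept[i].id,
                        kept[j].id,
                        kept[drop].id,
                    )
                    if exclusions is not None:
                        exclusions.append(
                            ExclusionRecord(
                                "meta_analysis",
                                kept[drop].id,
                                "overlap",
                                f"shares trials with {kept[keep].id}",
                            )
                        )
                    kept.pop(drop)
                    changed = True
                    break
            if changed:
                break
    return kept


# ---------------------------------------------------------------------------
# Building meta-analyses from trial records
# ---------------------------------------------------------------------------

def effect_from_record(
    rec: TrialRecord, default_rho: float = DEFAULT_RHO
) -> EffectEstimate:
    """Compute one trial's oriented effect estimate from its record.

    Split-mouth rows reported only as marginal counts are routed through
    the joint-cell reconstruction with the record's rho (falling back to
    ``default_rho``); continuous split-mouth rows use sd_diff when
    present, otherwise the per-site SDs, with the same rho precedence.
    """
    rho = rec.rho if rec.rho is not None else default_rho
    if rec.outcome_type == "binary":
        if rec.design == "parallel":
            est = eff.log_or_parallel(
                eff.BinaryArms(
                    int(rec.events_exp),
                    int(rec.total_exp),
                    int(rec.events_ctl),
                    int(rec.total_ctl),
                ),
                trial_id=rec.trial_id,
            )
        else:
            if rec.has_joint_cells():
                table = eff.PairedBinaryTable(rec.n11, rec.n10, rec.n01, rec.n00)
            else:
                table = eff.paired_cells_from_marginals(
                    rec.events_exp, rec.events_ctl, rec.total_exp, rho
                )
            est = eff.marginal_log_or_split_mouth(table, trial_id=rec.trial_id)
    else:
        if rec.design == "parallel":
            est = eff.smd_parallel(
                eff.ContinuousArms(
                    rec.mean_exp,
                    rec.sd_exp,
                    int(rec.n_exp),
                    rec.mean_ctl,
                    rec.sd_ctl,
                    int(rec.n_ctl),
                ),
                trial_id=rec.trial_id,
            )
        else:
            if rec.rho is not None and rec.sd_diff is not None:
                logger.warning(
                    "trial %s reports both rho and sd_diff; sd_diff drives the "
                    "variance, rho only converts it to a single-site SD",
                    rec.trial_id,
                )
            data = eff.PairedContinuous(
                mean_exp=rec.mean_exp,
                mean_ctl=rec.mean_ctl,
                sd_exp=rec.sd_exp,
                sd_ctl=rec.sd_ctl,
                n=int(rec.n_exp),
                rho=rec.rho,
                sd_diff=rec.sd_diff,
            )
            est = eff.smd_split_mouth(data, default_rho=default_rho, trial_id=rec.trial_id)
    return eff.orient_effect(est, rec.beneficial_direction)


def effects_from_records(
    records: Sequence[TrialRecord],
    default_rho: float = DEFAULT_RHO,
    exclusions: Optional[list[ExclusionRecord]] = None,
) -> list[MetaAnalysisInput]:
    """Group trial records into meta-analyses with computed effects.

    Meta-analyses keep the order of first appearance; excluded trials
    (double-zero tables) stay in the trial list flagged, and are also
    logged as :class:`ExclusionRecord` entries.
    """
    by_meta: dict[str, MetaAnalysisInput] = {}
    for rec in records:
        est = effect_from_record(rec, default_rho=default_rho)
        if est.excluded:
            logger.info(
                "excluding trial %s (%s): %s",
                rec.trial_id,
                rec.meta_id,
                est.exclusion_reason,
            )
            if exclusions is not None:
                exclusions.append(
                    ExclusionRecord(
                        "trial",
                        rec.trial_id,
                        est.exclusion_reason or "excluded",
                        f"meta-analysis {rec.meta_id}",
                    )
                )
        if rec.meta_id not in by_meta:
            by_meta[rec.meta_id] = MetaAnalysisInput(
                id=rec.meta_id, outcome_type=rec.outcome_type, trials=[]
            )
        meta = by_meta[rec.meta_id]
        if meta.outcome_type != rec.outcome_type:
            raise InvalidInputError(
                f"meta-analysis {rec.meta_id!r} mixes binary and continuous outcomes"
            )
        meta.trials.append(est)
        meta.trial_ids.add(rec.trial_id)
    return list(by_meta.values())


# ---------------------------------------------------------------------------
# Sensitivity grid and forest export
# ---------------------------------------------------------------------------

def sensitivity_suite(
    records: Sequence[TrialRecord],
    rho_values: Sequence[float] = (0.0, 0.25, DEFAULT_RHO),
    within_methods: Sequence[WithinMethod] = ("fixed", "random_reml"),
) -> pd.DataFrame:
    """Re-run the full two-step analysis over a (rho, within-method) grid.

    Each grid point recomputes effects from the raw summaries so that
    the assumed within-patient correlation is re-applied wherever the
    joint data was not reported. Returns one row per (rho, method,
    outcome type); deterministic given the records.
    """
    rows = []
    for rho in rho_values:
        for method in within_methods:
            metas = effects_from_records(records, default_rho=rho)
            metas = exclude_overlapping(metas)
            for outcome in ("binary", "continuous"):
                group = [m for m in metas if m.outcome_type == outcome]
                contrasts = compute_contrasts(group, within_method=method)
                if len(contrasts) < 2:
                    continue
                res = pool_contrasts(
                    contrasts, outcome_type=outcome, within_method=method
                )
                rows.append(
                    {
                        "rho": rho,
                        "within_method": method,
                        "outcome_type": outcome,
                        "n_meta": res.n_meta,
                        "combined": res.combined,
                        "ci_lower": res.ci_lower,
                        "ci_upper": res.ci_upper,
                        "p_value": res.p_value,
                        "tau2": res.tau2,
                        "i2": res.i2,
                        "pi_lower": res.prediction.lower,
                        "pi_upper": res.prediction.upper,
                    }
                )
    return pd.DataFrame(rows)


def forest_export(
    contrasts: Sequence[DesignContrast],
    result: MetaEpiResult,
    exponentiate: bool = False,
) -> pd.DataFrame:
    """Forest-plot table: one row per meta-analysis plus summary and PI rows.

    Per-meta-analysis weights are the REML random-effects weights
    1/(v + tau^2) normalized to sum to 100%. With ``exponentiate`` the
    estimate and interval columns are put on the ratio scale (RORs).
    """
    tau2 = result.tau2
    z = stats.norm.ppf(0.5 + 0.95 / 2.0)
    weights = [1.0 / (c.variance + tau2) for c in contrasts]
    total = sum(weights)
    tx = math.exp if exponentiate else (lambda x: x)
    rows = []
    for c, w in zip(contrasts, weights):
        se = math.sqrt(c.variance)
        rows.append(
            {
                "meta_id": c.meta_id,
                "estimate": tx(c.value),
                "ci_lower": tx(c.value - z * se),
                "ci_upper": tx(c.value + z * se),
                "weight_pct": 100.0 * w / total,
                "row_type": "meta_analysis",
            }
        )
    rows.append(
        {
            "meta_id": "combined",
            "estimate": tx(result.combined),
            "ci_lower": tx(result.ci_lower),
            "ci_upper": tx(result.ci_upper),
            "weight_pct": 100.0,
            "row_type": "summary",
        }
    )
    rows.append(
        {
            "meta_id": "prediction",
            "estimate": tx(result.combined),
            "ci_lower": tx(result.prediction.lower),
            "ci_upper": tx(result.prediction.upper),
            "weight_pct": float("nan"),
            "row_type": "prediction",
        }
    )
    return pd.DataFrame(
        rows, columns=["meta_id", "estimate", "ci_lower", "ci_upper", "weight_pct", "row_type"]
    )
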
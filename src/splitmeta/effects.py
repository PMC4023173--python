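"""Per-trial effect measures for split-mouth and parallel-arm trials.

A split-mouth trial randomizes the experimental and control interventions
to different sites in the same mouth, so every patient contributes one
outcome per arm. Binary outcomes then form a paired 2x2 table of joint
cell counts and continuous outcomes a correlated pair of site
measurements. Treating the two "arms" as independent samples misstates
the sampling variance, so this module provides design-aware estimators:

* parallel binary outcomes: the ordinary log odds ratio with a 0.5
  continuity correction for zero cells and exclusion of double-zero
  trials;
* split-mouth binary outcomes: the marginal (population-averaged) log
  odds ratio with the Becker-Balagtas delta-method variance, which
  subtracts the within-patient covariance of the two margins;
* parallel continuous outcomes: Cohen's d with its usual large-sample
  variance;
* split-mouth continuous outcomes: Cohen's d standardized by the
  single-site SD, with the matched-groups variance that shrinks by the
  factor 2(1 - rho).

When a split-mouth report gives only marginal event counts, the joint
cells can be reconstructed from an assumed within-patient correlation
(``paired_cells_from_marginals``); when it gives only per-site SDs, the
SD of within-patient differences follows from the Follmann imputation.

All effects are returned on the log-OR or SMD scale as
:class:`EffectEstimate` values, with benefit coded downward (log OR < 0,
SMD < 0 beneficial) after :func:`orient_effect`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Literal, Optional

from .errors import FeasibilityWarning, InvalidInputError

Scale = Literal["log_odds_ratio", "smd"]
Design = Literal["split_mouth", "parallel"]

#: Within-patient correlation assumed when a split-mouth report does not
#: provide the joint distribution; 0 and 0.25 are the usual sensitivity
#: settings.
DEFAULT_RHO = 0.5
SENSITIVITY_RHOS = (0.0, 0.25)


@dataclass(frozen=True)
class EffectEstimate:
    """A per-trial effect on the log-OR or SMD scale with its variance.

    ``excluded`` estimates (e.g. double-zero binary trials) carry NaN
    value/variance and a human-readable ``exclusion_reason``; pooling
    functions skip them. ``oriented`` records that the benefit-direction
    convention has already been applied, making orientation idempotent.
    """

    value: float
    variance: float
    scale: Scale
    design: Design
    trial_id: str = ""
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    oriented: bool = False

    def __post_init__(self):
        if not self.excluded:
            if not math.isfinite(self.value):
                raise InvalidInputError(
                    f"non-finite effect value for trial {self.trial_id!r}"
                )
            if not (self.variance > 0):
                raise InvalidInputError(
                    f"variance must be > 0 for trial {self.trial_id!r}, "
                    f"got {self.variance!r}"
                )

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


def _excluded(scale: Scale, design: Design, trial_id: str, reason: str) -> EffectEstimate:
    return EffectEstimate(
        value=float("nan"),
        variance=float("nan"),
        scale=scale,
        design=design,
        trial_id=trial_id,
        excluded=True,
        exclusion_reason=reason,
    )


@dataclass(frozen=True)
class BinaryArms:
    """2x2 arm-level counts from a parallel-arm trial."""

    events_exp: int
    total_exp: int
    events_ctl: int
    total_ctl: int

    def __post_init__(self):
        for events, total, arm in (
            (self.events_exp, self.total_exp, "experimental"),
            (self.events_ctl, self.total_ctl, "control"),
        ):
            if total <= 0:
                raise InvalidInputError(f"{arm} arm total must be > 0")
            if not 0 <= events <= total:
                raise InvalidInputError(
                    f"{arm} arm events must lie in [0, total], "
                    f"got {events}/{total}"
                )


@dataclass(frozen=True)
class PairedBinaryTable:
    """Joint cell counts of the paired 2x2 table from one split-mouth trial.

    ``n11`` counts patients with the event at both sites, ``n10`` at the
    experimental site only, ``n01`` at the control site only and ``n00``
    at neither. Fractional counts are permitted: tables reconstructed
    from marginal counts and an assumed correlation only feed
    proportion-based formulas, so rounding would add avoidable error.
    """

    n11: float
    n10: float
    n01: float
    n00: float

    def __post_init__(self):
        cells = (self.n11, self.n10, self.n01, self.n00)
        if any(c < 0 or not math.isfinite(c) for c in cells):
            raise InvalidInputError("paired table cells must be finite and >= 0")
        if sum(cells) <= 0:
            raise InvalidInputError("paired table must contain at least one patient")

    @property
    def n(self) -> float:
        """Total number of patients (sum of the four cells)."""
        return self.n11 + self.n10 + self.n01 + self.n00

    def margins(self) -> tuple[float, float]:
        """Marginal event proportions (experimental site, control site)."""
        n = self.n
        return (self.n11 + self.n10) / n, (self.n11 + self.n01) / n


@dataclass(frozen=True)
class ContinuousArms:
    """Arm-level summary statistics from a parallel-arm continuous outcome."""

    mean_exp: float
    sd_exp: float
    n_exp: int
    mean_ctl: float
    sd_ctl: float
    n_ctl: int

    def __post_init__(self):
        if self.sd_exp <= 0 or self.sd_ctl <= 0:
            raise InvalidInputError("arm SDs must be strictly positive")
        if self.n_exp <= 0 or self.n_ctl <= 0:
            raise InvalidInputError("arm sizes must be positive")


@dataclass(frozen=True)
class PairedContinuous:
    """Per-site summary statistics from a split-mouth continuous outcome.

    Exactly one of ``rho`` (within-patient correlation) and ``sd_diff``
    (SD of within-patient differences) drives the variance computation;
    when both are present ``sd_diff`` wins and ``rho`` is only used to
    back out the single-site SD.
    """

    mean_exp: float
    mean_ctl: float
    sd_exp: float
    sd_ctl: float
    n: int
    rho: Optional[float] = None
    sd_diff: Optional[float] = None

    def __post_init__(self):
        if self.sd_exp <= 0 or self.sd_ctl <= 0:
            raise InvalidInputError("site SDs must be strictly positive")
        if self.n <= 1:
            raise InvalidInputError("paired continuous data needs n > 1 patients")
        if self.rho is not None and not -1.0 <= self.rho <= 1.0:
            raise InvalidInputError("rho must lie in [-1, 1]")
        if self.sd_diff is not None and self.sd_diff <= 0:
            raise InvalidInputError("sd_diff must be strictly positive")


# ---------------------------------------------------------------------------
# Binary outcomes
# ---------------------------------------------------------------------------

def log_or_parallel(
    arms: BinaryArms, correction: float = 0.5, trial_id: str = ""
) -> EffectEstimate:
    """Log odds ratio of a parallel-arm 2x2 table.

    Zero cells trigger a continuity correction added to all four cells.
    Trials with no events in either arm carry no information about the
    odds ratio and are returned flagged ``excluded``; trials where every
    patient in both arms had the event are rejected as invalid input.
    """
    a = float(arms.events_exp)
    b = float(arms.total_exp - arms.events_exp)
    c = float(arms.events_ctl)
    d = float(arms.total_ctl - arms.events_ctl)
    if a == 0 and c == 0:
        return _excluded("log_odds_ratio", "parallel", trial_id, "double_zero")
    if b == 0 and d == 0:
        raise InvalidInputError(
            "all patients in both arms had the event; the odds ratio is undefined"
        )
    if min(a, b, c, d) == 0:
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
    return EffectEstimate(
        value=math.log((a * d) / (b * c)),
        variance=1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d,
        scale="log_odds_ratio",
        design="parallel",
        trial_id=trial_id,
    )


def marginal_log_or_split_mouth(
    table: PairedBinaryTable, correction: float = 0.5, trial_id: str = ""
) -> EffectEstimate:
    """Marginal (population-averaged) log odds ratio of a paired 2x2 table.

    The point estimate depends only on the marginal event proportions
    p1, p2 of the two sites; the delta-method variance of
    logit(p1) - logit(p2) additionally subtracts twice the within-patient
    covariance term (pi11*pi00 - pi10*pi01)/n, following Becker and
    Balagtas. Zero marginal cells are handled by adding ``correction``
    to every joint cell; tables with events at neither site (or at both
    sites of every patient) are flagged excluded, mirroring the
    double-zero rule for parallel trials.
    """
    n11, n10, n01, n00 = table.n11, table.n10, table.n01, table.n00
    if n11 + n10 + n01 == 0:
        return _excluded("log_odds_ratio", "split_mouth", trial_id, "double_zero")
    if n10 + n01 + n00 == 0:
        return _excluded("log_odds_ratio", "split_mouth", trial_id, "all_events")

    n = table.n
    e1, e2 = n11 + n10, n11 + n01  # marginal event counts
    # Zero marginal cells make the log odds infinite; a table with no
    # discordant pairs (n10 = n01 = 0) makes the delta-method variance
    # exactly zero. Both degeneracies get the same continuity correction.
    if e1 == 0 or e1 == n or e2 == 0 or e2 == n or (n10 == 0 and n01 == 0):
        n11, n10, n01, n00 = (
            n11 + correction,
            n10 + correction,
            n01 + correction,
            n00 + correction,
        )
        n = n11 + n10 + n01 + n00

    p1 = (n11 + n10) / n
    p2 = (n11 + n01) / n
    q1, q2 = 1.0 - p1, 1.0 - p2
    if p1 <= 0 or p1 >= 1 or p2 <= 0 or p2 >= 1:  # pragma: no cover - guarded above
        return _excluded("log_odds_ratio", "split_mouth", trial_id, "degenerate_margins")

    pi11, pi10, pi01, pi00 = n11 / n, n10 / n, n01 / n, n00 / n
    value = math.log((p1 * q2) / (p2 * q1))
    variance = (
        1.0 / (p1 * q1)
        + 1.0 / (p2 * q2)
        - 2.0 * (pi11 * pi00 - pi10 * pi01) / (p1 * q1 * p2 * q2)
    ) / n
    return EffectEstimate(
        value=value,
        variance=variance,
        scale="log_odds_ratio",
        design="split_mouth",
        trial_id=trial_id,
    )


def paired_cells_from_marginals(
    events_exp: float, events_ctl: float, n: float, rho: float
) -> PairedBinaryTable:
    """Reconstruct joint cells of a paired table from marginal counts.

    Many split-mouth reports print only per-site event counts. Given an
    assumed within-patient correlation the concordant-event cell is
    pi11 = p1*p2 + rho*sqrt(p1*q1*p2*q2) and the remaining cells follow
    from the margins. pi11 is clamped to the Frechet bounds
    [max(0, p1+p2-1), min(p1, p2)] when rho is infeasible for the given
    margins, with a :class:`FeasibilityWarning`. Cells are returned as
    (possibly fractional) proportions times ``n``; the margins of the
    output reproduce the inputs exactly whenever rho is feasible.
    """
    if n <= 0:
        raise InvalidInputError("n must be positive")
    if not 0 <= events_exp <= n or not 0 <= events_ctl <= n:
        raise InvalidInputError("event counts must lie in [0, n]")
    p1, p2 = events_exp / n, events_ctl / n
    q1, q2 = 1.0 - p1, 1.0 - p2
    pi11 = p1 * p2 + rho * math.sqrt(p1 * q1 * p2 * q2)
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    if pi11 < lo - 1e-12 or pi11 > hi + 1e-12:
        warnings.warn(
            f"rho={rho} infeasible for margins p1={p1:.4g}, p2={p2:.4g}; "
            "clamping the concordant cell to the Frechet bounds",
            FeasibilityWarning,
            stacklevel=2,
        )
    pi11 = min(max(pi11, lo), hi)
    return PairedBinaryTable(
        n11=pi11 * n,
        n10=(p1 - pi11) * n,
        n01=(p2 - pi11) * n,
        n00=(1.0 - p1 - p2 + pi11) * n,
    )


# ---------------------------------------------------------------------------
# Continuous outcomes
# ---------------------------------------------------------------------------

def smd_parallel(arms: ContinuousArms, trial_id: str = "") -> EffectEstimate:
    """Cohen's d for independent groups, with its large-sample variance.

    The standardizer is the df-weighted pooled SD. No small-sample
    (Hedges) correction is applied: the estimand is Cohen's d.
    """
    ne, nc = arms.n_exp, arms.n_ctl
    df = ne + nc - 2
    if df <= 0:
        raise InvalidInputError("need at least 3 patients across arms")
    s2 = ((ne - 1) * arms.sd_exp**2 + (nc - 1) * arms.sd_ctl**2) / df
    if s2 <= 0:
        raise InvalidInputError("pooled SD is zero; SMD undefined")
    d = (arms.mean_exp - arms.mean_ctl) / math.sqrt(s2)
    variance = (ne + nc) / (ne * nc) + d**2 / (2.0 * (ne + nc))
    return EffectEstimate(
        value=d, variance=variance, scale="smd", design="parallel", trial_id=trial_id
    )


def smd_split_mouth(
    data: PairedContinuous, default_rho: float = DEFAULT_RHO, trial_id: str = ""
) -> EffectEstimate:
    """Cohen's d for matched groups (split-mouth continuous outcomes).

    The mean within-patient difference is standardized by the single-site
    SD so the estimate is comparable with parallel-arm SMDs. When the SD
    of differences is reported it is converted via
    s_within = sd_diff / sqrt(2(1 - rho)); otherwise the pooled per-site
    SD is used directly. The variance

        [1/n + d^2/(2n)] * 2(1 - rho)

    is the independent-groups form shrunk by the pairing factor, hence
    strictly decreasing in rho.
    """
    rho = data.rho if data.rho is not None else default_rho
    if data.sd_diff is not None:
        if rho >= 1.0:
            raise InvalidInputError(
                "rho = 1 makes the sd_diff -> single-site SD conversion singular"
            )
        s_within = data.sd_diff / math.sqrt(2.0 * (1.0 - rho))
    else:
        s_within = math.sqrt((data.sd_exp**2 + data.sd_ctl**2) / 2.0)
    if s_within <= 0:
        raise InvalidInputError("within-group SD is zero; SMD undefined")
    d = (data.mean_exp - data.mean_ctl) / s_within
    variance = (1.0 / data.n + d**2 / (2.0 * data.n)) * 2.0 * (1.0 - rho)
    if variance <= 0:
        raise InvalidInputError("rho = 1 yields a degenerate (zero) variance")
    return EffectEstimate(
        value=d, variance=variance, scale="smd", design="split_mouth", trial_id=trial_id
    )


def follmann_impute_sd_diff(sd_exp: float, sd_ctl: float, rho: float) -> float:
    """SD of within-patient differences from per-site SDs and a correlation.

    The Follmann imputation for matched data whose difference SD is not
    reported: sd_diff = sqrt(sd_exp^2 + sd_ctl^2 - 2*rho*sd_exp*sd_ctl).
    """
    if sd_exp <= 0 or sd_ctl <= 0:
        raise InvalidInputError("SDs must be strictly positive")
    if not -1.0 <= rho <= 1.0:
        raise InvalidInputError("rho must lie in [-1, 1]")
    return math.sqrt(sd_exp**2 + sd_ctl**2 - 2.0 * rho * sd_exp * sd_ctl)


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def orient_effect(
    estimate: EffectEstimate, beneficial_direction: Literal["lower", "higher"]
) -> EffectEstimate:
    """Recode an effect so that negative values indicate benefit.

    Outcomes where a higher score is good (e.g. implant survival) are
    negated; outcomes where a lower score is good (e.g. plaque index)
    pass through. Orientation is applied at most once per estimate.
    """
    if beneficial_direction not in ("lower", "higher"):
        raise InvalidInputError(
            f"beneficial_direction must be 'lower' or 'higher', got {beneficial_direction!r}"
        )
    if estimate.oriented or estimate.excluded:
        return estimate if estimate.oriented else replace(estimate, oriented=True)
    if beneficial_direction == "higher":
        return replace(estimate, value=-estimate.value, oriented=True)
    return replace(estimate, oriented=True)
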
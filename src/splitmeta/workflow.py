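"""End-to-end pipeline: read trials -> effects -> contrasts -> pooled result.

Produces a small results bundle on disk: per-meta-analysis contrasts,
an overall summary JSON (log scale plus ratio scale for binary
outcomes), forest-plot tables, and an exclusion log with
machine-readable reason codes. Outputs carry no timestamps, so repeated
runs on the same input are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import pandas as pd

from .effects import DEFAULT_RHO
from .errors import InvalidInputError
from .io import read_trials
from .pipeline import (
    ExclusionRecord,
    MetaEpiResult,
    WithinMethod,
    compute_contrasts,
    effects_from_records,
    exclude_overlapping,
    forest_export,
    pool_contrasts,
)

logger = logging.getLogger("splitmeta")


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    input_path: str
    out_dir: str
    rho: float = DEFAULT_RHO
    within_method: WithinMethod = "fixed"
    level: float = 0.95
    skip_invalid: bool = False


def _summary_dict(res: MetaEpiResult) -> dict:
    out = {
        "outcome_type": res.outcome_type,
        "n_meta": res.n_meta,
        "within_method": res.within_method,
        "combined": res.combined,
        "ci_lower": res.ci_lower,
        "ci_upper": res.ci_upper,
        "p_value": res.p_value,
        "tau2": res.tau2,
        "i2": res.i2,
        "prediction_lower": res.prediction.lower,
        "prediction_upper": res.prediction.upper,
    }
    if res.outcome_type == "binary":
        # ratio-scale report: exp() of the log-scale quantities
        out["ror"] = math.exp(res.combined)
        out["ror_ci_lower"] = math.exp(res.ci_lower)
        out["ror_ci_upper"] = math.exp(res.ci_upper)
        out["ror_prediction_lower"] = math.exp(res.prediction.lower)
        out["ror_prediction_upper"] = math.exp(res.prediction.upper)
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, MetaEpiResult]:
    """Run the two-step analysis and write the results bundle.

    Writes ``contrasts.csv``, ``summary.json``, ``forest_<outcome>.csv``
    and ``exclusions.csv`` under ``config.out_dir``. Returns the pooled
    results keyed by outcome type. Raises :class:`InvalidInputError`
    when no outcome type has the two or more eligible meta-analyses the
    across-meta-analysis model needs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = read_trials(config.input_path, skip_invalid=config.skip_invalid)
    logger.info("read %d trial records from %s", len(records), config.input_path)

    exclusions: list[ExclusionRecord] = []
    metas = effects_from_records(records, default_rho=config.rho, exclusions=exclusions)
    metas = exclude_overlapping(metas, exclusions=exclusions)
    logger.info("%d meta-analyses after overlap exclusion", len(metas))

    results: dict[str, MetaEpiResult] = {}
    contrast_rows = []
    for outcome in ("binary", "continuous"):
        group = [m for m in metas if m.outcome_type == outcome]
        if not group:
            continue
        contrasts = compute_contrasts(
            group, within_method=config.within_method, exclusions=exclusions
        )
        for c in contrasts:
            contrast_rows.append(
                {
                    "meta_id": c.meta_id,
                    "outcome_type": outcome,
                    "value": c.value,
                    "variance": c.variance,
                    "k_split": c.k_split,
                    "k_parallel": c.k_parallel,
                }
            )
        if len(contrasts) < 2:
            exclusions.append(
                ExclusionRecord(
                    "meta_analysis",
                    f"<{outcome} stratum>",
                    "too_few_contrasts",
                    f"{len(contrasts)} eligible meta-analyses; need >= 2",
                )
            )
            continue
        res = pool_contrasts(
            contrasts,
            outcome_type=outcome,
            within_method=config.within_method,
            level=config.level,
        )
        results[outcome] = res
        forest = forest_export(contrasts, res, exponentiate=(outcome == "binary"))
        forest.to_csv(out_dir / f"forest_{outcome}.csv", index=False)
        logger.info(
            "%s: pooled %d meta-analyses, combined=%.4f (p=%.3f)",
            outcome,
            res.n_meta,
            res.combined,
            res.p_value,
        )

    pd.DataFrame(
        contrast_rows,
        columns=["meta_id", "outcome_type", "value", "variance", "k_split", "k_parallel"],
    ).to_csv(out_dir / "contrasts.csv", index=False)
    pd.DataFrame(
        [dataclasses.asdict(e) for e in exclusions],
        columns=["level", "id", "reason", "detail"],
    ).to_csv(out_dir / "exclusions.csv", index=False)

    if not results:
        raise InvalidInputError(
            "no outcome stratum had the >= 2 eligible meta-analyses needed "
            "for the across-meta-analysis model"
        )

    summary = {k: _summary_dict(v) for k, v in sorted(results.items())}
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return results
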
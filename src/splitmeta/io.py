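"""Flat CSV schema for trial-level summary data.

One row per trial, discriminated by ``design`` and ``outcome_type``:

* parallel / binary: events_exp, total_exp, events_ctl, total_ctl
* split_mouth / binary: either joint cells n11, n10, n01, n00 or
  marginal counts events_exp, events_ctl with total_exp = total_ctl = n
  (the joint cells are then reconstructed from rho)
* parallel / continuous: mean_exp, sd_exp, n_exp, mean_ctl, sd_ctl, n_ctl
* split_mouth / continuous: mean_exp, sd_exp, mean_ctl, sd_ctl,
  n_exp = n_ctl = n, plus rho and/or sd_diff (sd_diff wins)

Empty cells mean "not reported" and are distinct from zeros. A
``schema_version`` column (currently "1") guards dialect drift; unknown
or missing header columns are hard errors. Files are RFC-4180 CSV,
UTF-8, '.' decimal separator.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from typing import Literal, Optional

from .errors import TrialDataError

SCHEMA_VERSION = "1"

SCHEMA_COLUMNS = [
    "schema_version",
    "meta_id",
    "trial_id",
    "design",
    "outcome_type",
    "beneficial_direction",
    "publication_year",
    "events_exp",
    "total_exp",
    "events_ctl",
    "total_ctl",
    "n11",
    "n10",
    "n01",
    "n00",
    "mean_exp",
    "sd_exp",
    "n_exp",
    "mean_ctl",
    "sd_ctl",
    "n_ctl",
    "rho",
    "sd_diff",
]


@dataclass
class TrialRecord:
    """One trial's extracted summary data, pre-validation of field sets."""

    meta_id: str
    trial_id: str
    design: Literal["split_mouth", "parallel"]
    outcome_type: Literal["binary", "continuous"]
    beneficial_direction: Literal["lower", "higher"] = "lower"
    publication_year: Optional[int] = None
    # binary
    events_exp: Optional[float] = None
    total_exp: Optional[float] = None
    events_ctl: Optional[float] = None
    total_ctl: Optional[float] = None
    n11: Optional[float] = None
    n10: Optional[float] = None
    n01: Optional[float] = None
    n00: Optional[float] = None
    # continuous
    mean_exp: Optional[float] = None
    sd_exp: Optional[float] = None
    n_exp: Optional[float] = None
    mean_ctl: Optional[float] = None
    sd_ctl: Optional[float] = None
    n_ctl: Optional[float] = None
    rho: Optional[float] = None
    sd_diff: Optional[float] = None

    def has_joint_cells(self) -> bool:
        return all(x is not None for x in (self.n11, self.n10, self.n01, self.n00))


_INT_FIELDS = {"publication_year"}
_STR_FIELDS = {"meta_id", "trial_id", "design", "outcome_type", "beneficial_direction"}


def _validate_record(rec: TrialRecord) -> list[str]:
    """Field-set consistency checks for one record; returns problem list."""
    problems: list[str] = []
    if rec.design not in ("split_mouth", "parallel"):
        problems.append(f"design must be split_mouth or parallel, got {rec.design!r}")
    if rec.outcome_type not in ("binary", "continuous"):
        problems.append(
            f"outcome_type must be binary or continuous, got {rec.outcome_type!r}"
        )
    if rec.beneficial_direction not in ("lower", "higher"):
        problems.append(
            "beneficial_direction must be lower or higher, "
            f"got {rec.beneficial_direction!r}"
        )
    if problems:
        return problems

    binary = ("events_exp", "total_exp", "events_ctl", "total_ctl")
    joint = ("n11", "n10", "n01", "n00")
    cont = ("mean_exp", "sd_exp", "mean_ctl", "sd_ctl")

    def present(names):
        return [n for n in names if getattr(rec, n) is not None]

    if rec.outcome_type == "binary":
        if present(cont) or rec.n_exp is not None or rec.n_ctl is not None:
            problems.append("continuous fields populated on a binary outcome row")
        if rec.sd_diff is not None:
            problems.append("sd_diff populated on a binary outcome row")
        if rec.design == "parallel":
            if len(present(binary)) != 4:
                problems.append("parallel binary rows need all of " + ", ".join(binary))
            if present(joint):
                problems.append("joint cells populated on a parallel-arm row")
            if rec.rho is not None:
                problems.append("rho populated on a parallel-arm binary row")
        else:  # split_mouth binary
            if rec.has_joint_cells():
                if present(binary):
                    problems.append(
                        "give either joint cells or marginal counts, not both"
                    )
            elif len(present(binary)) == 4:
                if rec.total_exp != rec.total_ctl:
                    problems.append(
                        "split-mouth marginal counts need total_exp == total_ctl "
                        "(the number of patients)"
                    )
            else:
                problems.append(
                    "split-mouth binary rows need joint cells n11..n00 or "
                    "marginal counts events/total per site"
                )
    else:  # continuous
        if present(binary) or present(joint):
            problems.append("binary fields populated on a continuous outcome row")
        if len(present(cont)) != 4:
            problems.append("continuous rows need all of " + ", ".join(cont))
        if rec.design == "parallel":
            if rec.n_exp is None or rec.n_ctl is None:
                problems.append("parallel continuous rows need n_exp and n_ctl")
            if rec.rho is not None or rec.sd_diff is not None:
                problems.append("rho/sd_diff populated on a parallel-arm row")
        else:
            if rec.n_exp is None or rec.n_ctl is None or rec.n_exp != rec.n_ctl:
                problems.append(
                    "split-mouth continuous rows need n_exp == n_ctl "
                    "(the number of patients)"
                )
    return problems


def _parse_row(row: dict, line: int) -> tuple[Optional[TrialRecord], list[str]]:
    problems: list[str] = []
    if (row.get("schema_version") or "").strip() != SCHEMA_VERSION:
        problems.append(
            f"schema_version must be {SCHEMA_VERSION!r}, got {row.get('schema_version')!r}"
        )
    kwargs = {}
    for f in fields(TrialRecord):
        raw = (row.get(f.name) or "").strip()
        if f.name in _STR_FIELDS:
            kwargs[f.name] = raw
            if not raw and f.name in ("meta_id", "trial_id", "design", "outcome_type"):
                problems.append(f"{f.name} is required")
        elif raw == "":
            kwargs[f.name] = None
        else:
            try:
                kwargs[f.name] = int(raw) if f.name in _INT_FIELDS else float(raw)
            except ValueError:
                problems.append(f"{f.name}: cannot parse {raw!r} as a number")
    if problems:
        return None, problems
    rec = TrialRecord(**kwargs)
    return rec, _validate_record(rec)


def read_trials(
    path,
    schema_version: str = SCHEMA_VERSION,
    skip_invalid: bool = False,
) -> list[TrialRecord]:
    """Read and validate a trial CSV.

    Row-level problems are collected with their 1-based line numbers; the
    run aborts with a :class:`TrialDataError` listing every problem
    unless ``skip_invalid`` is set, in which case offending rows are
    dropped. A malformed header is always a hard error.
    """
    if schema_version != SCHEMA_VERSION:
        raise TrialDataError(
            f"unsupported schema version {schema_version!r}; this reader "
            f"understands version {SCHEMA_VERSION!r}"
        )
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        unknown = [c for c in header if c not in SCHEMA_COLUMNS]
        missing = [c for c in SCHEMA_COLUMNS if c not in header]
        if unknown or missing:
            parts = []
            if unknown:
                parts.append(f"unknown columns {unknown}")
            if missing:
                parts.append(f"missing columns {missing}")
            raise TrialDataError(f"malformed header in {path}: " + "; ".join(parts))
        records: list[TrialRecord] = []
        row_errors: list[tuple[int, str]] = []
        for line, row in enumerate(reader, start=2):
            rec, problems = _parse_row(row, line)
            if problems:
                row_errors.extend((line, p) for p in problems)
            else:
                records.append(rec)
    if row_errors and not skip_invalid:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in row_errors[:20])
        raise TrialDataError(
            f"{len(row_errors)} validation problem(s) in {path}: {detail}",
            row_errors=row_errors,
        )
    return records


def _format(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def write_trials(records, path) -> None:
    """Write trial records in the flat CSV schema (lossless round-trip)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCHEMA_COLUMNS)
        for rec in records:
            row = [SCHEMA_VERSION]
            row += [_format(getattr(rec, c)) for c in SCHEMA_COLUMNS[1:]]
            writer.writerow(row)
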
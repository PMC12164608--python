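"""Read, validate and write cohort tables and result tables.

Cohort files are UTF-8 comma-delimited text with a header row and one record
per row. Caregiver income losses are stored as a semicolon-joined sub-list in
a single column and multi-select coping sources as semicolon-joined codes.
Columns outside the documented dictionary are carried through untouched in
``HouseholdRecord.extra``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pydantic import ValidationError

from .records import (
    DME_FIELDS,
    DNME_FIELDS,
    CopingSource,
    ExpenditureBreakdown,
    HouseholdRecord,
    VisitType,
)

SCHEMA_VERSION = "1"

_SCALAR_COLUMNS = (
    "record_id",
    "adults",
    "children",
    "annual_consumption",
    "annual_food_expenditure",
    "visit_type",
    "facility_type",
    "disease_stage",
    "insured",
    "residence",
    "region",
    "age_years",
    "sex",
    "died_during_followup",
)

_MONEY_COLUMNS = DME_FIELDS + DNME_FIELDS + (
    "reimbursement_6m",
    "income_loss_patient_6m",
)

_LIST_COLUMNS = ("income_loss_caregivers_6m", "coping_sources")

#: the fixed, versioned column dictionary of a cohort file
COHORT_COLUMNS: tuple[str, ...] = _SCALAR_COLUMNS + _MONEY_COLUMNS + _LIST_COLUMNS


class SchemaError(ValueError):
    """Cohort file does not match the documented column dictionary."""


class RecordError(ValueError):
    """One or more rows failed validation; carries the offending record ids."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no", ""}:
        return False
    raise ValueError(f"unparseable boolean: {value!r}")


def _row_to_record(row: pd.Series, extra_cols: Sequence[str]) -> HouseholdRecord:
    caregivers_raw = row["income_loss_caregivers_6m"]
    if caregivers_raw is None or (isinstance(caregivers_raw, float) and pd.isna(caregivers_raw)):
        caregivers: tuple[float, ...] = ()
    else:
        s = str(caregivers_raw).strip()
        caregivers = tuple(float(x) for x in s.split(";") if x.strip() != "")

    coping_raw = row["coping_sources"]
    if coping_raw is None or (isinstance(coping_raw, float) and pd.isna(coping_raw)):
        coping: frozenset[CopingSource] = frozenset()
    else:
        codes = [c.strip() for c in str(coping_raw).split(";") if c.strip()]
        coping = frozenset(CopingSource(c) for c in codes)

    breakdown = ExpenditureBreakdown(
        **{f: float(row[f]) for f in DME_FIELDS + DNME_FIELDS}
    )
    return HouseholdRecord(
        record_id=str(row["record_id"]),
        adults=int(row["adults"]),
        children=int(row["children"]),
        annual_consumption=float(row["annual_consumption"]),
        annual_food_expenditure=float(row["annual_food_expenditure"]),
        visit_type=str(row["visit_type"]),
        facility_type=str(row["facility_type"]),
        disease_stage=int(row["disease_stage"]),
        insured=_parse_bool(row["insured"]),
        residence=str(row["residence"]),
        region=str(row["region"]) if not pd.isna(row["region"]) else "",
        age_years=float(row["age_years"]),
        sex=str(row["sex"]),
        died_during_followup=_parse_bool(row["died_during_followup"]),
        oop=breakdown,
        reimbursement_6m=float(row["reimbursement_6m"]),
        income_loss_patient_6m=float(row["income_loss_patient_6m"]),
        income_loss_caregivers_6m=caregivers,
        coping_sources=coping,
        extra={c: row[c] for c in extra_cols},
    )


def load_cohort(path: str | Path, schema_version: str = SCHEMA_VERSION) -> list[HouseholdRecord]:
    """Load a cohort file into validated records, preserving row order.

    Raises :class:`SchemaError` when a mandatory column is missing and
    :class:`RecordError` (listing record ids) when rows fail validation.
    """
    path = Path(path)
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version: {schema_version}")
    df = pd.read_csv(path, dtype={"record_id": str}, keep_default_na=True)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    extra_cols = [c for c in df.columns if c not in COHORT_COLUMNS]

    records: list[HouseholdRecord] = []
    errors: list[str] = []
    for _, row in df.iterrows():
        rid = str(row["record_id"])
        try:
            records.append(_row_to_record(row, extra_cols))
        except (ValueError, ValidationError) as exc:
            errors.append(f"record {rid}: {exc}")
    if errors:
        raise RecordError(errors)
    return records


@dataclasses.dataclass
class ValidationReport:
    """Per-record invariant violations plus cohort-level warnings."""

    violations: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    warnings: list[str] = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_cohort(records: Iterable[HouseholdRecord]) -> ValidationReport:
    """Report every typed-invariant violation; never raises.

    Records arriving here are normally already validated at construction, so
    this re-checks the invariants structurally (useful for records built via
    ``model_construct`` or mutated copies) and adds cohort-level warnings such
    as empty visit-type strata.
    """
    report = ValidationReport()
    records = list(records)
    seen_visit_types: set[VisitType] = set()
    for r in records:
        seen_visit_types.add(r.visit_type)
        if r.adults < 1:
            report.violations.append((r.record_id, "adults >= 1"))
        if r.children < 0:
            report.violations.append((r.record_id, "children >= 0"))
        if r.annual_food_expenditure > r.annual_consumption + 1e-9:
            report.violations.append(
                (r.record_id, "annual_food_expenditure <= annual_consumption")
            )
        if r.annual_consumption < 0 or r.annual_food_expenditure < 0:
            report.violations.append((r.record_id, "money fields >= 0"))
        if any(getattr(r.oop, f) < 0 for f in DME_FIELDS + DNME_FIELDS):
            report.violations.append((r.record_id, "OOP components >= 0"))
        if r.reimbursement_6m < 0:
            report.violations.append((r.record_id, "reimbursement_6m >= 0"))
        elif r.reimbursement_6m > r.oop.total_6m + 1e-9:
            report.violations.append(
                (r.record_id, "reimbursement_6m <= total 6-month OOP")
            )
        if not 1 <= r.disease_stage <= 5:
            report.violations.append((r.record_id, "disease_stage in 1..5"))
        if r.income_loss_patient_6m < 0 or any(
            x < 0 for x in r.income_loss_caregivers_6m
        ):
            report.violations.append((r.record_id, "income losses >= 0"))
    if records:
        for vt in VisitType:
            if vt not in seen_visit_types:
                report.warnings.append(f"empty stratum: {vt.value}")
    return report


def _record_to_row(r: HouseholdRecord) -> dict:
    row: dict = {c: getattr(r, c) for c in _SCALAR_COLUMNS}
    for enum_col in ("visit_type", "facility_type", "residence", "sex"):
        row[enum_col] = getattr(r, enum_col).value
    for f in DME_FIELDS + DNME_FIELDS:
        row[f] = getattr(r.oop, f)
    row["reimbursement_6m"] = r.reimbursement_6m
    row["income_loss_patient_6m"] = r.income_loss_patient_6m
    row["income_loss_caregivers_6m"] = ";".join(
        repr(x) for x in r.income_loss_caregivers_6m
    )
    row["coping_sources"] = ";".join(sorted(c.value for c in r.coping_sources))
    row.update(r.extra)
    return row


def cohort_to_frame(records: Iterable[HouseholdRecord]) -> pd.DataFrame:
    """Flatten records into the canonical analysis DataFrame (one row each)."""
    rows = [_record_to_row(r) for r in records]
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS) if not rows else None)
    if rows:
        ordered = [c for c in COHORT_COLUMNS if c in df.columns]
        extras = [c for c in df.columns if c not in COHORT_COLUMNS]
        df = df[ordered + extras]
    return df


def write_cohort(records: Iterable[HouseholdRecord], path: str | Path) -> Path:
    """Write records as delimited text; ``load_cohort`` inverts this exactly.

    Floats are serialised with ``repr`` round-trip precision.
    """
    path = Path(path)
    df = cohort_to_frame(records)
    if df.empty:
        df = pd.DataFrame(columns=list(COHORT_COLUMNS))
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Serialise result tables as CSV plus one structured JSON document.

    Floats keep >= 6 significant digits in the delimited output; the JSON
    document keeps full double precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    summary: dict[str, list[dict]] = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.8g")
        paths[name] = p
        summary[name] = json.loads(df.to_json(orient="records"))
    summary_path = out_dir / "results.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    paths["results_json"] = summary_path
    return paths
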
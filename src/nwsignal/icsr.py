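"""Domain model and tabular I/O for individual case safety reports (ICSRs).

A spontaneous report describes one patient, one or more drugs (each with a
causality role assigned by the reporter) and one or more coded adverse
reactions.  Two on-disk dialects are supported:

* ``long`` — a single CSV with one row per (report, drug, reaction)
  combination; report-level fields are repeated on every row.
* ``relational`` — a directory with three linked CSVs (``reports.csv``,
  ``drugs.csv``, ``reactions.csv``) joined on ``report_id``.

Missing optional values are represented as ``None`` / absent, never as
sentinel numbers: downstream summaries and comparisons skip them.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "ROLES",
    "SEXES",
    "SERIOUSNESS_CRITERIA",
    "DrugEntry",
    "ReactionEntry",
    "PatientInfo",
    "IcsrReport",
    "ReportSet",
    "SchemaError",
    "ConsistencyError",
    "read_reports",
    "write_reports",
    "deduplicate",
]

ROLES = ("suspected", "interacting", "concomitant")
SEXES = ("female", "male", "unknown")
SERIOUSNESS_CRITERIA = (
    "death",
    "hospitalization",
    "life_threatening",
    "congenital_anomaly",
    "permanent_sequelae",
    "other",
)


class SchemaError(ValueError):
    """A required column is missing or a field value is malformed."""


class ConsistencyError(ValueError):
    """Rows sharing a report_id disagree on a report-level field."""


@dataclass(frozen=True, slots=True)
class DrugEntry:
    """One drug mentioned on a report.

    ``role`` is the reporter-assigned causality role; only ``suspected`` and
    ``interacting`` entries count as exposure in the case/non-case analysis.
    ``daily_dose_ddd`` is the dose as a multiple of the WHO defined daily
    dose; ``treatment_duration_weeks`` is the maternal treatment duration.
    """

    name: str
    atc_code: Optional[str] = None
    role: str = "suspected"
    daily_dose_ddd: Optional[float] = None
    treatment_duration_weeks: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", self.name.strip().lower())
        if self.atc_code is not None:
            object.__setattr__(self, "atc_code", self.atc_code.strip().upper() or None)
        if self.role not in ROLES:
            raise SchemaError(f"drug role must be one of {ROLES}, got {self.role!r}")
        if not self.name:
            raise SchemaError("drug name must be non-empty")
        if self.daily_dose_ddd is not None and self.daily_dose_ddd < 0:
            raise SchemaError("daily_dose_ddd must be non-negative")
        if self.treatment_duration_weeks is not None and self.treatment_duration_weeks < 0:
            raise SchemaError("treatment_duration_weeks must be non-negative")


@dataclass(frozen=True, slots=True)
class ReactionEntry:
    """One coded adverse reaction (MedDRA-PT-like term) on a report."""

    pt: str
    smq_tags: frozenset = frozenset()
    duration_days: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pt", self.pt.strip().lower())
        if not self.pt:
            raise SchemaError("reaction pt must be non-empty")
        object.__setattr__(self, "smq_tags", frozenset(t.strip().lower() for t in self.smq_tags))
        if self.duration_days is not None and self.duration_days < 0:
            raise SchemaError("duration_days must be non-negative")


@dataclass(frozen=True, slots=True)
class PatientInfo:
    """Patient demographics; ``patient_id`` links multiple reports to one
    patient when the source provides it (otherwise each report is one
    patient)."""

    age_days: Optional[int] = None
    sex: str = "unknown"
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise SchemaError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_days is not None and self.age_days < 0:
            raise SchemaError("age_days must be non-negative")


@dataclass(frozen=True, slots=True)
class IcsrReport:
    """One spontaneous report: patient, drugs, reactions, seriousness.

    ``serious`` follows the regulatory definition (death, hospitalization,
    life threat, congenital anomaly, permanent sequelae); ``None`` encodes
    unknown seriousness.  ``seriousness_criteria`` may be empty even for
    serious reports — source data are incomplete.
    """

    report_id: str
    patient: PatientInfo
    drugs: tuple
    reactions: tuple
    serious: Optional[bool] = None
    seriousness_criteria: frozenset = frozenset()
    country: Optional[str] = None
    received_date: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        if not self.report_id:
            raise SchemaError("report_id must be non-empty")
        if not self.drugs:
            raise SchemaError(f"report {self.report_id}: drugs must be non-empty")
        if not self.reactions:
            raise SchemaError(f"report {self.report_id}: reactions must be non-empty")
        crit = frozenset(self.seriousness_criteria)
        bad = crit - set(SERIOUSNESS_CRITERIA)
        if bad:
            raise SchemaError(f"unknown seriousness criteria: {sorted(bad)}")
        object.__setattr__(self, "seriousness_criteria", crit)

    def dedup_key(self) -> tuple:
        """Exact-match duplicate key: (country, sex, age, drug-name multiset,
        PT multiset)."""
        return (
            self.country,
            self.patient.sex,
            self.patient.age_days,
            tuple(sorted(d.name for d in self.drugs)),
            tuple(sorted(r.pt for r in self.reactions)),
        )


@dataclass(slots=True)
class ReportSet:
    """Ordered collection of reports with unique ids."""

    reports: list = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.reports]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ConsistencyError(f"duplicate report_id in ReportSet: {dup!r}")

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[IcsrReport]:
        return iter(self.reports)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReportSet):
            return NotImplemented
        return self.reports == other.reports


# ---------------------------------------------------------------------------
# CSV serialization

_REPORT_COLS = [
    "report_id",
    "patient_id",
    "age_days",
    "sex",
    "serious",
    "seriousness_criteria",
    "country",
    "received_date",
]
_DRUG_COLS = ["drug_name", "atc_code", "drug_role", "daily_dose_ddd", "treatment_duration_weeks"]
_REACTION_COLS = ["reaction_pt", "smq_tags", "reaction_duration_days"]
LONG_COLUMNS = _REPORT_COLS + _DRUG_COLS + _REACTION_COLS

# patient_id is optional on input for backward-compatible files
_OPTIONAL_COLS = {"patient_id"}

_LIST_SEP = ";"


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_float(text: str, col: str) -> Optional[float]:
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise SchemaError(f"column {col}: not a number: {text!r}") from None


def _parse_int(text: str, col: str) -> Optional[int]:
    if text == "":
        return None
    try:
        return int(float(text))
    except ValueError:
        raise SchemaError(f"column {col}: not an integer: {text!r}") from None


def _parse_serious(text: str) -> Optional[bool]:
    t = text.strip().lower()
    if t in ("", "unknown"):
        return None
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise SchemaError(f"column serious: cannot parse {text!r}")


def _parse_set(text: str) -> frozenset:
    if not text.strip():
        return frozenset()
    return frozenset(t.strip() for t in text.split(_LIST_SEP) if t.strip())


def _report_fields(row: dict) -> dict:
    return {
        "patient_id": row.get("patient_id", "") or None,
        "age_days": _parse_int(row["age_days"], "age_days"),
        "sex": row["sex"].strip().lower() or "unknown",
        "serious": _parse_serious(row["serious"]),
        "seriousness_criteria": _parse_set(row["seriousness_criteria"]),
        "country": row["country"].strip() or None,
        "received_date": row["received_date"].strip() or None,
    }


def _drug_from_row(row: dict) -> DrugEntry:
    return DrugEntry(
        name=row["drug_name"],
        atc_code=row["atc_code"].strip() or None,
        role=row["drug_role"].strip().lower() or "suspected",
        daily_dose_ddd=_parse_float(row["daily_dose_ddd"], "daily_dose_ddd"),
        treatment_duration_weeks=_parse_float(
            row["treatment_duration_weeks"], "treatment_duration_weeks"
        ),
    )


def _reaction_from_row(row: dict) -> ReactionEntry:
    return ReactionEntry(
        pt=row["reaction_pt"],
        smq_tags=_parse_set(row["smq_tags"]),
        duration_days=_parse_float(row["reaction_duration_days"], "reaction_duration_days"),
    )


def _build_report(report_id: str, fields: dict, drugs: list, reactions: list) -> IcsrReport:
    return IcsrReport(
        report_id=report_id,
        patient=PatientInfo(
            age_days=fields["age_days"], sex=fields["sex"], patient_id=fields["patient_id"]
        ),
        drugs=tuple(drugs),
        reactions=tuple(reactions),
        serious=fields["serious"],
        seriousness_criteria=fields["seriousness_criteria"],
        country=fields["country"],
        received_date=fields["received_date"],
    )


def _check_columns(header: Iterable[str], required: Iterable[str], where: str) -> None:
    present = set(header)
    for col in required:
        if col not in present and col not in _OPTIONAL_COLS:
            raise SchemaError(f"{where}: missing required column {col!r}")


def _read_rows(path: str, required: list) -> list:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        _check_columns(reader.fieldnames, required, os.path.basename(path))
        rows = []
        for row in reader:
            row.setdefault("patient_id", "")
            rows.append(row)
        return rows


def _read_long(path: str) -> ReportSet:
    rows = _read_rows(path, LONG_COLUMNS)
    order: list = []
    fields_by_id: dict = {}
    drugs_by_id: dict = {}
    reactions_by_id: dict = {}
    for row in rows:
        rid = row["report_id"].strip()
        if not rid:
            raise SchemaError("empty report_id")
        fields = _report_fields(row)
        if rid not in fields_by_id:
            order.append(rid)
            fields_by_id[rid] = fields
            drugs_by_id[rid] = {}
            reactions_by_id[rid] = {}
        elif fields_by_id[rid] != fields:
            raise ConsistencyError(
                f"report {rid!r}: conflicting report-level fields across rows"
            )
        drug = _drug_from_row(row)
        drugs_by_id[rid].setdefault(drug, None)
        reaction = _reaction_from_row(row)
        reactions_by_id[rid].setdefault(reaction, None)
    reports = [
        _build_report(rid, fields_by_id[rid], list(drugs_by_id[rid]), list(reactions_by_id[rid]))
        for rid in order
    ]
    return ReportSet(reports=reports, provenance=f"read_reports(long, {path})")


def _read_relational(path: str) -> ReportSet:
    rpath = os.path.join(path, "reports.csv")
    dpath = os.path.join(path, "drugs.csv")
    xpath = os.path.join(path, "reactions.csv")
    report_rows = _read_rows(rpath, _REPORT_COLS)
    drug_rows = _read_rows(dpath, ["report_id"] + _DRUG_COLS)
    reaction_rows = _read_rows(xpath, ["report_id"] + _REACTION_COLS)

    order: list = []
    fields_by_id: dict = {}
    for row in report_rows:
        rid = row["report_id"].strip()
        if rid in fields_by_id:
            if fields_by_id[rid] != _report_fields(row):
                raise ConsistencyError(f"report {rid!r}: conflicting rows in reports.csv")
            continue
        order.append(rid)
        fields_by_id[rid] = _report_fields(row)

    drugs_by_id: dict = {rid: {} for rid in order}
    for row in drug_rows:
        rid = row["report_id"].strip()
        if rid not in fields_by_id:
            raise ConsistencyError(f"drugs.csv references unknown report_id {rid!r}")
        drugs_by_id[rid].setdefault(_drug_from_row(row), None)
    reactions_by_id: dict = {rid: {} for rid in order}
    for row in reaction_rows:
        rid = row["report_id"].strip()
        if rid not in fields_by_id:
            raise ConsistencyError(f"reactions.csv references unknown report_id {rid!r}")
        reactions_by_id[rid].setdefault(_reaction_from_row(row), None)

    reports = [
        _build_report(rid, fields_by_id[rid], list(drugs_by_id[rid]), list(reactions_by_id[rid]))
        for rid in order
    ]
    return ReportSet(reports=reports, provenance=f"read_reports(relational, {path})")


def read_reports(path: str, dialect: str = "long") -> ReportSet:
    """Read a ReportSet from ``path``.

    ``long`` expects a single CSV; ``relational`` expects a directory with
    ``reports.csv``, ``drugs.csv`` and ``reactions.csv``.  Rows sharing a
    report_id are merged into one report with the union of drug and reaction
    entries; conflicting report-level fields raise :class:`ConsistencyError`.
    """
    if dialect == "long":
        return _read_long(path)
    if dialect == "relational":
        return _read_relational(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _report_row(report: IcsrReport) -> dict:
    return {
        "report_id": report.report_id,
        "patient_id": _fmt(report.patient.patient_id),
        "age_days": _fmt(report.patient.age_days),
        "sex": report.patient.sex,
        "serious": _fmt(report.serious),
        "seriousness_criteria": _LIST_SEP.join(sorted(report.seriousness_criteria)),
        "country": _fmt(report.country),
        "received_date": _fmt(report.received_date),
    }


def _drug_row(drug: DrugEntry) -> dict:
    return {
        "drug_name": drug.name,
        "atc_code": _fmt(drug.atc_code),
        "drug_role": drug.role,
        "daily_dose_ddd": _fmt(drug.daily_dose_ddd),
        "treatment_duration_weeks": _fmt(drug.treatment_duration_weeks),
    }


def _reaction_row(reaction: ReactionEntry) -> dict:
    return {
        "reaction_pt": reaction.pt,
        "smq_tags": _LIST_SEP.join(sorted(reaction.smq_tags)),
        "reaction_duration_days": _fmt(reaction.duration_days),
    }


def write_reports(rs: ReportSet, path: str, dialect: str = "long") -> None:
    """Write ``rs`` so that :func:`read_reports` recovers an equal set.

    The long dialect emits the cartesian product of each report's drugs and
    reactions (one row per combination).
    """
    if dialect == "long":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=LONG_COLUMNS)
            writer.writeheader()
            for report in rs:
                base = _report_row(report)
                for drug in report.drugs:
                    drow = _drug_row(drug)
                    for reaction in report.reactions:
                        writer.writerow({**base, **drow, **_reaction_row(reaction)})
        return
    if dialect == "relational":
        os.makedirs(path, exist_ok=True)
        with open(os.path.join(path, "reports.csv"), "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_REPORT_COLS)
            writer.writeheader()
            for report in rs:
                writer.writerow(_report_row(report))
        with open(os.path.join(path, "drugs.csv"), "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=["report_id"] + _DRUG_COLS)
            writer.writeheader()
            for report in rs:
                for drug in report.drugs:
                    writer.writerow({"report_id": report.report_id, **_drug_row(drug)})
        with open(os.path.join(path, "reactions.csv"), "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=["report_id"] + _REACTION_COLS)
            writer.writeheader()
            for report in rs:
                for reaction in report.reactions:
                    writer.writerow({"report_id": report.report_id, **_reaction_row(reaction)})
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def deduplicate(rs: ReportSet) -> ReportSet:
    """Collapse duplicate reports, keeping the first occurrence.

    Duplicates are exact matches on (country, sex, age_days, sorted drug-name
    multiset, sorted PT multiset).  Idempotent; surviving reports are
    returned unchanged.
    """
    seen: set = set()
    kept: list = []
    for report in rs:
        key = report.dedup_key()
        if key in seen:
            continue
        seen.add(key)
        kept.append(report)
    return ReportSet(reports=kept, provenance=rs.provenance + " | deduplicated")
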
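"""Stay-level domain model, code syntax validation, cohort I/O and the
gold-standard case definition.

The unit of analysis is the hospital stay.  Each stay pairs a chart-review
abstract (the gold standard) with the coded discharge record that the
detection algorithms operate on, plus the administrative fields used for
eligibility filtering.

A stay is a *CEPSB* case (complicated ectopic pregnancy with severe
bleeding) when the ectopic pregnancy is histologically confirmed and at
least one of three complications is documented: tubal rupture,
hemoperitoneum of 500 cc or more, or active bleeding.  The 500 cc
threshold is inclusive.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "CepsbError",
    "CodeSyntaxError",
    "SchemaError",
    "ExcludedStayError",
    "CodeSystem",
    "Code",
    "parse_code",
    "format_code",
    "AlternativeDiagnosis",
    "AdminData",
    "MedicalRecordAbstract",
    "HDDRecord",
    "StayPair",
    "classify_gold",
    "gold_labels",
    "analyzable",
    "read_stays",
    "write_stays",
]


class CepsbError(Exception):
    """Base class for all package errors."""


class CodeSyntaxError(CepsbError, ValueError):
    """A diagnosis or procedure code does not match its system's syntax."""


class SchemaError(CepsbError, ValueError):
    """A stay file violates the documented column schema."""


class ExcludedStayError(CepsbError):
    """Raised when a gold-standard operation is requested for a stay whose
    medical record is unavailable (such stays are excluded from analysis,
    never classified)."""


class CodeSystem(str, Enum):
    """Coding system of a :class:`Code`."""

    ICD10 = "ICD10"
    CCAM = "CCAM"


# ICD-10: one letter, two digits, optional one further alphanumeric
# subcode character.  Stored without the dot ("O00.1" -> "O001").
_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]?$")
# CCAM: four letters followed by three digits.
_CCAM_RE = re.compile(r"^[A-Z]{4}[0-9]{3}$")


@dataclass(frozen=True, slots=True)
class Code:
    """A single diagnosis (ICD-10) or procedure (CCAM) code.

    Values are stored normalized: uppercase and, for ICD-10, dot-free.
    Equality and hashing use ``(system, value)`` only.
    """

    system: CodeSystem
    value: str

    def __post_init__(self) -> None:
        pattern = _ICD10_RE if self.system is CodeSystem.ICD10 else _CCAM_RE
        if not pattern.match(self.value):
            raise CodeSyntaxError(
                f"{self.value!r} is not a valid {self.system.value} code"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def parse_code(text: str, system: CodeSystem) -> Code:
    """Normalize *text* into a :class:`Code` of the given *system*.

    Case is folded to uppercase and a dot separator after the third
    character of an ICD-10 code is accepted and removed.  Malformed input
    raises :class:`CodeSyntaxError` naming the offending string.
    """
    if not text:
        raise CodeSyntaxError("empty code string")
    value = text.strip().upper()
    if system is CodeSystem.ICD10:
        value = value.replace(".", "")
    return Code(CodeSystem(system), value)


def format_code(code: Code) -> str:
    """Printable spelling of a code: ICD-10 codes with a subcode character
    re-insert the dot after the third character (``O001`` -> ``O00.1``)."""
    if code.system is CodeSystem.ICD10 and len(code.value) == 4:
        return code.value[:3] + "." + code.value[3]
    return code.value


class AlternativeDiagnosis(str, Enum):
    """Final diagnosis of a stay that is not a CEPSB case."""

    NONE = "none"
    SPONTANEOUS_ABORTION = "spontaneous_abortion"
    OVARIAN_CYST_RUPTURE = "ovarian_cyst_rupture"
    IUP_METRORRHAGIA = "iup_metrorrhagia"
    UNCOMPLICATED_EP = "uncomplicated_ep"
    PELVIC_INFECTION = "pelvic_infection"
    OTHER = "other"


@dataclass(frozen=True, slots=True)
class AdminData:
    """Administrative fields of one hospital stay."""

    stay_id: str
    center: str  # "A" or "B"
    sex: str  # "F" or "M"
    age: int
    year: int
    unit: str
    duration: float  # days

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.center not in ("A", "B"):
            raise ValueError(f"center must be 'A' or 'B', got {self.center!r}")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if not self.stay_id:
            raise ValueError("stay_id must be non-empty")


@dataclass(frozen=True, slots=True)
class MedicalRecordAbstract:
    """Chart-review abstract of a stay (the gold standard).

    ``record_available=False`` marks a stay whose medical record could not
    be retrieved; such stays are carried through files but dropped from
    every analysis stage.
    """

    record_available: bool = True
    pregnancy_test_positive: bool = False
    ep_confirmed_histology: bool = False
    laparoscopy_performed: bool = False
    tubal_rupture: bool = False
    hemoperitoneum_cc: float = 0.0
    active_bleeding: bool = False
    alternative_diagnosis: AlternativeDiagnosis = AlternativeDiagnosis.NONE

    def __post_init__(self) -> None:
        if self.hemoperitoneum_cc < 0:
            raise ValueError("hemoperitoneum_cc must be >= 0")
        if self.ep_confirmed_histology and not self.pregnancy_test_positive:
            raise ValueError(
                "histologically confirmed EP requires a positive pregnancy test"
            )
        if self.tubal_rupture and not self.laparoscopy_performed:
            raise ValueError("tubal rupture is visualized at laparoscopy")


@dataclass(frozen=True, slots=True)
class HDDRecord:
    """Coded discharge record of one stay.

    ``main_diagnosis`` is absent only for an uncoded stay, in which case
    the associated diagnoses and procedures are empty as well.
    """

    main_diagnosis: Code | None = None
    associated_diagnoses: frozenset[Code] = frozenset()
    procedures: frozenset[Code] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "associated_diagnoses", frozenset(self.associated_diagnoses)
        )
        object.__setattr__(self, "procedures", frozenset(self.procedures))
        if self.main_diagnosis is None:
            if self.associated_diagnoses or self.procedures:
                raise ValueError(
                    "an uncoded stay (no main diagnosis) cannot carry "
                    "associated diagnoses or procedures"
                )
        else:
            if self.main_diagnosis.system is not CodeSystem.ICD10:
                raise ValueError("main diagnosis must be an ICD-10 code")
            if self.main_diagnosis in self.associated_diagnoses:
                raise ValueError(
                    "main diagnosis may not repeat among associated diagnoses"
                )
        for code in self.associated_diagnoses:
            if code.system is not CodeSystem.ICD10:
                raise ValueError("associated diagnoses must be ICD-10 codes")
        for code in self.procedures:
            if code.system is not CodeSystem.CCAM:
                raise ValueError("procedures must be CCAM codes")

    @property
    def is_uncoded(self) -> bool:
        return self.main_diagnosis is None

    def all_diagnoses(self) -> frozenset[Code]:
        """Main and associated diagnoses together."""
        if self.main_diagnosis is None:
            return self.associated_diagnoses
        return self.associated_diagnoses | {self.main_diagnosis}


@dataclass(frozen=True, slots=True)
class StayPair:
    """One hospital stay: administrative data, gold standard and coded record."""

    admin: AdminData
    gold: MedicalRecordAbstract
    hdd: HDDRecord

    @property
    def stay_id(self) -> str:
        return self.admin.stay_id


def classify_gold(gold: MedicalRecordAbstract) -> bool:
    """Gold-standard verdict: is this stay a CEPSB case?

    True iff the ectopic pregnancy is histologically confirmed and at
    least one complication is present (tubal rupture, hemoperitoneum of
    500 cc or more — inclusive threshold — or active bleeding).  Raises
    :class:`ExcludedStayError` when the medical record is unavailable:
    such a stay has no gold-standard classification.
    """
    if not gold.record_available:
        raise ExcludedStayError("stay has no medical record; excluded from analysis")
    return gold.ep_confirmed_histology and (
        gold.tubal_rupture
        or gold.hemoperitoneum_cc >= 500.0
        or gold.active_bleeding
    )


def analyzable(cohort: Iterable[StayPair]) -> list[StayPair]:
    """Stays with an available medical record, in cohort order.

    The number of dropped stays is logged (never silently discarded)."""
    stays = list(cohort)
    kept = [s for s in stays if s.gold.record_available]
    dropped = len(stays) - len(kept)
    if dropped:
        logger.info("excluded %d stay(s) without a medical record", dropped)
    return kept


def gold_labels(cohort: Iterable[StayPair]) -> dict[str, bool]:
    """Gold-standard labels for every analyzable stay, keyed by stay id."""
    return {s.stay_id: classify_gold(s.gold) for s in analyzable(cohort)}


# ---------------------------------------------------------------------------
# Cohort serialization
# ---------------------------------------------------------------------------

#: Column schema of the flat stay file (CSV or JSONL), one row per stay.
STAY_COLUMNS = (
    "stay_id",
    "center",
    "sex",
    "age",
    "year",
    "unit",
    "duration_days",
    "main_dx",
    "assoc_dx",
    "procedures",
    "record_available",
    "pregnancy_test",
    "ep_histology",
    "laparoscopy",
    "tubal_rupture",
    "hemoperitoneum_cc",
    "active_bleeding",
    "alternative_dx",
)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(text: str, column: str) -> bool:
    lowered = str(text).strip().lower()
    if lowered in _TRUE:
        return True
    if lowered in _FALSE:
        return False
    raise SchemaError(f"column {column!r}: cannot parse boolean {text!r}")


def _split_codes(raw: object, system: CodeSystem) -> frozenset[Code]:
    """Parse a ";"-joined string (CSV) or a list of strings (JSONL)."""
    if raw is None:
        return frozenset()
    parts = raw if isinstance(raw, list) else str(raw).split(";")
    return frozenset(parse_code(str(part), system) for part in parts if part)


def _stay_from_row(row: Mapping[str, object]) -> StayPair:
    admin = AdminData(
        stay_id=str(row["stay_id"]),
        center=str(row["center"]),
        sex=str(row["sex"]),
        age=int(row["age"]),
        year=int(row["year"]),
        unit=str(row["unit"]),
        duration=float(row["duration_days"]),
    )
    gold = MedicalRecordAbstract(
        record_available=_parse_bool(row["record_available"], "record_available"),
        pregnancy_test_positive=_parse_bool(row["pregnancy_test"], "pregnancy_test"),
        ep_confirmed_histology=_parse_bool(row["ep_histology"], "ep_histology"),
        laparoscopy_performed=_parse_bool(row["laparoscopy"], "laparoscopy"),
        tubal_rupture=_parse_bool(row["tubal_rupture"], "tubal_rupture"),
        hemoperitoneum_cc=float(row["hemoperitoneum_cc"]),
        active_bleeding=_parse_bool(row["active_bleeding"], "active_bleeding"),
        alternative_diagnosis=AlternativeDiagnosis(str(row["alternative_dx"]) or "none"),
    )
    main_raw = row["main_dx"]
    main = (
        parse_code(str(main_raw), CodeSystem.ICD10)
        if main_raw not in (None, "")
        else None
    )
    assoc_raw = row["assoc_dx"]
    proc_raw = row["procedures"]
    hdd = HDDRecord(
        main_diagnosis=main,
        associated_diagnoses=_split_codes(assoc_raw, CodeSystem.ICD10),
        procedures=_split_codes(proc_raw, CodeSystem.CCAM),
    )
    return StayPair(admin=admin, gold=gold, hdd=hdd)


def _row_from_stay(stay: StayPair, *, lists: bool) -> dict[str, object]:
    assoc = sorted(c.value for c in stay.hdd.associated_diagnoses)
    procs = sorted(c.value for c in stay.hdd.procedures)
    row: dict[str, object] = {
        "stay_id": stay.admin.stay_id,
        "center": stay.admin.center,
        "sex": stay.admin.sex,
        "age": stay.admin.age,
        "year": stay.admin.year,
        "unit": stay.admin.unit,
        "duration_days": stay.admin.duration,
        "main_dx": stay.hdd.main_diagnosis.value if stay.hdd.main_diagnosis else "",
        "assoc_dx": assoc if lists else ";".join(assoc),
        "procedures": procs if lists else ";".join(procs),
        "record_available": stay.gold.record_available,
        "pregnancy_test": stay.gold.pregnancy_test_positive,
        "ep_histology": stay.gold.ep_confirmed_histology,
        "laparoscopy": stay.gold.laparoscopy_performed,
        "tubal_rupture": stay.gold.tubal_rupture,
        "hemoperitoneum_cc": stay.gold.hemoperitoneum_cc,
        "active_bleeding": stay.gold.active_bleeding,
        "alternative_dx": stay.gold.alternative_diagnosis.value,
    }
    if not lists:
        for key, value in row.items():
            if isinstance(value, bool):
                row[key] = "true" if value else "false"
            elif isinstance(value, float):
                row[key] = repr(value)
    return row


def read_stays(path: str | Path, fmt: str | None = None) -> list[StayPair]:
    """Read a cohort from a CSV or JSONL stay file.

    The format is inferred from the file suffix unless *fmt* is given
    (``"csv"`` or ``"jsonl"``).  Row order is preserved.  Unknown or
    missing columns, malformed codes and duplicate stay ids raise
    :class:`SchemaError` with the offending row number.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("csv", "jsonl"):
        raise SchemaError(f"unsupported stay file format {fmt!r}")

    rows: list[Mapping[str, object]] = []
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as handle:
            reader = csv.DictReader(handle)
            header = set(reader.fieldnames or ())
            unknown = header - set(STAY_COLUMNS)
            missing = set(STAY_COLUMNS) - header
            if unknown:
                raise SchemaError(f"unknown column(s): {sorted(unknown)}")
            if missing:
                raise SchemaError(f"missing column(s): {sorted(missing)}")
            rows = list(reader)
    else:
        with path.open(encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                if not line.strip():
                    continue
                obj = json.loads(line)
                unknown = set(obj) - set(STAY_COLUMNS)
                if unknown:
                    raise SchemaError(
                        f"row {lineno}: unknown column(s): {sorted(unknown)}"
                    )
                missing = set(STAY_COLUMNS) - set(obj)
                if missing:
                    raise SchemaError(
                        f"row {lineno}: missing column(s): {sorted(missing)}"
                    )
                rows.append(obj)

    cohort: list[StayPair] = []
    seen: set[str] = set()
    for rowno, row in enumerate(rows, start=1):
        try:
            stay = _stay_from_row(row)
        except (CepsbError, ValueError, KeyError) as exc:
            raise SchemaError(f"row {rowno}: {exc}") from exc
        if stay.stay_id in seen:
            raise SchemaError(f"row {rowno}: duplicate stay_id {stay.stay_id!r}")
        seen.add(stay.stay_id)
        cohort.append(stay)
    return cohort


def write_stays(
    cohort: Iterable[StayPair], path: str | Path, fmt: str | None = None
) -> Path:
    """Write a cohort to a CSV or JSONL stay file (inverse of :func:`read_stays`).

    Output is deterministic for a fixed cohort: columns in schema order,
    multi-valued code columns sorted and ";"-joined.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("csv", "jsonl"):
        raise SchemaError(f"unsupported stay file format {fmt!r}")
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as handle:
            writer = csv.DictWriter(handle, fieldnames=STAY_COLUMNS)
            writer.writeheader()
            for stay in cohort:
                writer.writerow(_row_from_stay(stay, lists=False))
    else:
        with path.open("w", encoding="utf-8") as handle:
            for stay in cohort:
                handle.write(
                    json.dumps(_row_from_stay(stay, lists=True), sort_keys=False)
                )
                handle.write("\n")
    return path
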
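"""Coding-error audit: classify false negatives and false positives into
the nine-type taxonomy by diffing the coded record against what complete
coding of the gold standard would contain, then tabulate counts, per-stay
multiplicities, code-system-family shares and per-center comparisons.

Shares are computed over error *instances* with exact rational
arithmetic; rounding happens only at display time.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .records import CepsbError, StayPair, analyzable, classify_gold
from .coding import (
    ANAEMIA_DX,
    COMPLICATION_DX,
    EP_MAIN_DX,
    EP_PROCEDURES,
    ERROR_GROUP,
    ErrorGroup,
    ErrorType,
    TAXONOMY_ORDER,
    expected_complication_codes,
    is_delivery_code,
)
from .engine import AdminFilter, DEFAULT_ADMIN_FILTER, DetectionAlgorithm, apply
from .validity import proportions_pvalue, round_half_up

__all__ = [
    "ErrorRecord",
    "AuditSummary",
    "classify_stay_errors",
    "audit",
    "group_shares",
    "format_audit_table",
]

#: A stay can accumulate at most this many audited errors.
MAX_ERRORS_PER_STAY = 2


@dataclass(frozen=True, slots=True)
class ErrorRecord:
    """One classified coding error on one stay."""

    stay_id: str
    error_type: ErrorType
    direction: str  # "FN" or "FP"

    def __post_init__(self) -> None:
        if self.direction not in ("FN", "FP"):
            raise ValueError("direction must be 'FN' or 'FP'")
        if (self.error_type is ErrorType.EXCESS_DX) != (self.direction == "FP"):
            raise ValueError(
                "excess diagnoses occur only on false positives; all other "
                "error types only on false negatives"
            )

    @property
    def group(self) -> ErrorGroup:
        return ERROR_GROUP[self.error_type]


def classify_stay_errors(
    stay: StayPair,
    direction: str,
    admin_filter: AdminFilter = DEFAULT_ADMIN_FILTER,
) -> list[ErrorRecord]:
    """Coding errors explaining why *stay* is a false negative or false
    positive.

    The record is diffed against the codes complete coding of the gold
    standard would carry.  A false-negative stay is checked, in taxonomy
    order, for: an empty record; a delivery code as main diagnosis; a main
    diagnosis outside the EP set; a missing expected associated diagnosis
    (post-haemorrhagic anaemia); missing or substituted complication
    codes; a missing or non-specific EP procedure; administrative fields
    outside the eligibility filter.  A false positive is checked for
    unsupported EP or complication codes.  At most two errors are
    reported per stay.
    """
    if direction not in ("FN", "FP"):
        raise ValueError("direction must be 'FN' or 'FP'")
    gold = stay.gold
    if not gold.record_available:
        raise CepsbError("excluded stays are not audited")
    is_case = classify_gold(gold)
    if direction == "FN" and not is_case:
        raise CepsbError(f"stay {stay.stay_id} is not a gold case; cannot be FN")
    if direction == "FP" and is_case:
        raise CepsbError(f"stay {stay.stay_id} is a gold case; cannot be FP")

    hdd = stay.hdd
    found: list[ErrorRecord] = []

    if direction == "FP":
        expected_main_is_ep = gold.alternative_diagnosis.value == "uncomplicated_ep"
        unsupported_dx = (
            hdd.main_diagnosis in EP_MAIN_DX and not expected_main_is_ep
        ) or bool(hdd.associated_diagnoses & COMPLICATION_DX)
        if unsupported_dx:
            found.append(
                ErrorRecord(stay.stay_id, ErrorType.EXCESS_DX, "FP")
            )
        return found

    # False negative: diff against complete coding of the gold record.
    if hdd.is_uncoded:
        return [ErrorRecord(stay.stay_id, ErrorType.UNCODED_STAY, "FN")]

    main = hdd.main_diagnosis
    if main is not None and is_delivery_code(main):
        found.append(ErrorRecord(stay.stay_id, ErrorType.DELIVERY_CODE_USED, "FN"))
    elif main not in EP_MAIN_DX:
        found.append(ErrorRecord(stay.stay_id, ErrorType.INCORRECT_PRINCIPAL_DX, "FN"))

    if ANAEMIA_DX not in hdd.associated_diagnoses:
        found.append(ErrorRecord(stay.stay_id, ErrorType.ABSENT_ASSOCIATED_DX, "FN"))

    expected = expected_complication_codes(gold)
    missing = expected - hdd.associated_diagnoses
    if missing:
        extras = hdd.associated_diagnoses - expected - {ANAEMIA_DX}
        error_type = (
            ErrorType.INCORRECT_COMPLICATION_CODE
            if extras
            else ErrorType.ABSENT_COMPLICATION_CODE
        )
        found.append(ErrorRecord(stay.stay_id, error_type, "FN"))

    if hdd.procedures.isdisjoint(EP_PROCEDURES):
        found.append(ErrorRecord(stay.stay_id, ErrorType.ABSENT_EP_PROCEDURE, "FN"))

    if not admin_filter.matches(stay):
        found.append(ErrorRecord(stay.stay_id, ErrorType.ADMIN_ERROR, "FN"))

    return found[:MAX_ERRORS_PER_STAY]


def group_shares(
    type_counts: Mapping[ErrorType, int]
) -> dict[ErrorGroup, Fraction]:
    """Share of error instances per code-system family, as exact fractions
    summing to 1 (empty when there are no errors)."""
    total = sum(type_counts.values())
    if total == 0:
        return {}
    shares: dict[ErrorGroup, Fraction] = {}
    for error_type, count in type_counts.items():
        group = ERROR_GROUP[error_type]
        shares[group] = shares.get(group, Fraction(0)) + Fraction(count, total)
    return shares


@dataclass(frozen=True, slots=True)
class AuditSummary:
    """Tabulated coding errors behind one algorithm's misclassifications."""

    algorithm: str
    records: tuple[ErrorRecord, ...]
    per_type: Mapping[ErrorType, int]
    per_center: Mapping[ErrorType, Mapping[str, int]]
    center_pvalues: Mapping[ErrorType, float]
    multiplicity: Mapping[int, int]  # errors-per-stay -> number of stays
    shares: Mapping[ErrorGroup, Fraction]
    n_fn_stays: int
    n_fp_stays: int

    @property
    def n_instances(self) -> int:
        return len(self.records)


def audit(
    cohort: Iterable[StayPair],
    algorithm: DetectionAlgorithm,
    admin_filter: AdminFilter = DEFAULT_ADMIN_FILTER,
) -> AuditSummary:
    """Classify every false negative and false positive of *algorithm* on
    *cohort* and tabulate the errors."""
    stays = analyzable(cohort)
    outcome = apply(algorithm, stays)
    centers = sorted({s.admin.center for s in stays})

    records: list[ErrorRecord] = []
    n_fn = n_fp = 0
    center_of: dict[str, str] = {}
    # Eligible denominators per center for the between-center tests.
    positives = {c: 0 for c in centers}
    negatives = {c: 0 for c in centers}
    for stay in stays:
        center_of[stay.stay_id] = stay.admin.center
        is_case = classify_gold(stay.gold)
        flagged = outcome.predictions[stay.stay_id]
        if is_case:
            positives[stay.admin.center] += 1
        else:
            negatives[stay.admin.center] += 1
        if is_case and not flagged:
            n_fn += 1
            records.extend(classify_stay_errors(stay, "FN", admin_filter))
        elif flagged and not is_case:
            n_fp += 1
            records.extend(classify_stay_errors(stay, "FP", admin_filter))

    per_type = {t: 0 for t in TAXONOMY_ORDER}
    per_center = {t: {c: 0 for c in centers} for t in TAXONOMY_ORDER}
    per_stay: dict[str, int] = {}
    for record in records:
        per_type[record.error_type] += 1
        per_center[record.error_type][center_of[record.stay_id]] += 1
        per_stay[record.stay_id] = per_stay.get(record.stay_id, 0) + 1

    multiplicity: dict[int, int] = {}
    for count in per_stay.values():
        multiplicity[count] = multiplicity.get(count, 0) + 1

    center_pvalues: dict[ErrorType, float] = {}
    if len(centers) == 2:
        a, b = centers
        for error_type in TAXONOMY_ORDER:
            denom = negatives if error_type is ErrorType.EXCESS_DX else positives
            if denom[a] == 0 or denom[b] == 0:
                continue
            p, _ = proportions_pvalue(
                per_center[error_type][a],
                denom[a],
                per_center[error_type][b],
                denom[b],
            )
            center_pvalues[error_type] = p

    return AuditSummary(
        algorithm=algorithm.name,
        records=tuple(records),
        per_type=per_type,
        per_center=per_center,
        center_pvalues=center_pvalues,
        multiplicity=multiplicity,
        shares=group_shares(per_type),
        n_fn_stays=n_fn,
        n_fp_stays=n_fp,
    )


def format_audit_table(summary: AuditSummary, fmt: str = "md") -> str:
    """Render the audit as a Markdown or CSV table (one row per error
    type, with per-center counts and comparison p-values), followed by the
    group shares."""
    centers = sorted(
        next(iter(summary.per_center.values())).keys()
    ) if summary.per_center else []
    header = ["error_type", "total", *[f"center_{c}" for c in centers], "p_value"]
    rows: list[list[str]] = []
    for error_type in TAXONOMY_ORDER:
        total = summary.per_type.get(error_type, 0)
        cells = [error_type.value, str(total)]
        cells += [str(summary.per_center[error_type][c]) for c in centers]
        p = summary.center_pvalues.get(error_type)
        cells.append("" if p is None else f"{round_half_up(p, 2)}")
        rows.append(cells)
    share_rows = [
        [f"share_{group.value}", f"{round_half_up(float(share) * 100.0)}%"]
        for group, share in sorted(summary.shares.items(), key=lambda kv: kv[0].value)
    ]
    if fmt == "csv":
        buffer = io.StringIO()
        writer = csv.writer(buffer, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)
        writer.writerows(share_rows)
        return buffer.getvalue()
    if fmt == "md":
        lines = [
            "| " + " | ".join(header) + " |",
            "| " + " | ".join("---" for _ in header) + " |",
        ]
        lines += ["| " + " | ".join(r) + " |" for r in rows]
        lines.append("")
        for name, value in share_rows:
            lines.append(f"- {name}: {value}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown table format {fmt!r}")
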
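"""Data-driven algorithm construction: screen every code occurring in the
cohort against the gold standard, keep the codes that are both
statistically associated and strongly predictive, and assemble them into
a two-clause detection algorithm.

Per code the 2x2 table is

    a = code present & case        b = present & non-case
    c = code absent  & case        d = absent  & non-case

with code-level LR+ = [a/(a+c)] / [b/(b+d)].  When a = 0 or b = 0 the
Haldane-Anscombe correction adds 0.5 to all four cells before computing
the ratio.  The association p-value comes from a two-sided Fisher exact
test on the *uncorrected* table (a chi-square variant with Yates
correction is available behind ``test="chi2"``).  A code is selected when
p < alpha and LR+ > lr_threshold, both strict.  No multiple-testing
correction is applied: the selection rule is a fixed published procedure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .records import CepsbError, Code, StayPair, analyzable, classify_gold
from .engine import (
    AdminFilter,
    CodeClause,
    DetectionAlgorithm,
    Scope,
    apply as engine_apply,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CodeScreenResult",
    "Selection",
    "screen_codes",
    "select_codes",
    "build_algorithm",
    "write_screen_report",
]


@dataclass(slots=True)
class CodeScreenResult:
    """Screening statistics of one (code, scope) pair."""

    code: Code
    scope: Scope  # ANY_DX or PROCEDURE
    a: int
    b: int
    c: int
    d: int
    lr_plus: float
    p_value: float
    selected: bool = False

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True, slots=True)
class Selection:
    """Selected codes, partitioned by scope."""

    dx_codes: frozenset[Code] = frozenset()
    procedure_codes: frozenset[Code] = frozenset()


def _corrected_lr_plus(a: int, b: int, c: int, d: int) -> float:
    """Code-level LR+ with Haldane-Anscombe 0.5 on all cells when a zero
    cell would make the ratio degenerate."""
    af, bf, cf, df = float(a), float(b), float(c), float(d)
    if a == 0 or b == 0:
        af, bf, cf, df = af + 0.5, bf + 0.5, cf + 0.5, df + 0.5
    return (af / (af + cf)) / (bf / (bf + df))


def screen_codes(
    cohort: Iterable[StayPair],
    gold: Mapping[str, bool] | None = None,
    *,
    test: str = "fisher",
    min_count: int = 1,
    restrict_to: DetectionAlgorithm | None = None,
) -> list[CodeScreenResult]:
    """Screen every distinct (code, scope) occurring in the cohort.

    Diagnosis codes are screened in any position (main or associated),
    procedures in the procedure set.  *gold* defaults to the gold-standard
    classification of each analyzable stay.  ``min_count`` drops codes
    occurring fewer times; ``restrict_to`` screens only the stays flagged
    positive by a prior algorithm (off by default — screening the whole
    cohort is what allows sensitivity to improve).
    """
    if test not in ("fisher", "chi2"):
        raise ValueError(f"unknown association test {test!r}")
    stays = analyzable(cohort)
    if restrict_to is not None:
        flagged = engine_apply(restrict_to, stays).predictions
        stays = [s for s in stays if flagged[s.stay_id]]
    if gold is None:
        gold = {s.stay_id: classify_gold(s.gold) for s in stays}
    labels = [gold[s.stay_id] for s in stays]
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise CepsbError(
            "screening requires at least one gold-positive and one "
            "gold-negative stay"
        )

    occurrences: dict[tuple[Scope, Code], list[int]] = {}
    for stay, is_case in zip(stays, labels):
        for code in stay.hdd.all_diagnoses():
            occurrences.setdefault((Scope.ANY_DX, code), [0, 0])[0 if is_case else 1] += 1
        for code in stay.hdd.procedures:
            occurrences.setdefault((Scope.PROCEDURE, code), [0, 0])[0 if is_case else 1] += 1

    results: list[CodeScreenResult] = []
    for (scope, code), (a, b) in sorted(
        occurrences.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        if a + b < min_count:
            continue
        c, d = n_pos - a, n_neg - b
        if test == "fisher":
            p = float(stats.fisher_exact([[a, b], [c, d]]).pvalue)
        else:
            p = float(
                stats.chi2_contingency([[a, b], [c, d]], correction=True).pvalue
            )
        results.append(
            CodeScreenResult(
                code=code,
                scope=scope,
                a=a,
                b=b,
                c=c,
                d=d,
                lr_plus=_corrected_lr_plus(a, b, c, d),
                p_value=p,
            )
        )
    return results


def select_codes(
    results: Sequence[CodeScreenResult],
    alpha: float = 0.05,
    lr_threshold: float = 4.0,
) -> Selection:
    """Keep codes with p < alpha and LR+ > lr_threshold (both strict) and
    partition them by scope.  Marks ``selected`` on the inputs."""
    dx: set[Code] = set()
    procs: set[Code] = set()
    for result in results:
        result.selected = result.p_value < alpha and result.lr_plus > lr_threshold
        if not result.selected:
            continue
        if result.scope is Scope.PROCEDURE:
            procs.add(result.code)
        else:
            dx.add(result.code)
    if not dx:
        warnings.warn("no diagnosis code selected", stacklevel=2)
    if not procs:
        warnings.warn("no procedure code selected", stacklevel=2)
    return Selection(dx_codes=frozenset(dx), procedure_codes=frozenset(procs))


def build_algorithm(
    selection: Selection,
    admin: AdminFilter | None = None,
    name: str = "derived",
) -> DetectionAlgorithm:
    """Assemble a two-clause algorithm (any-position diagnosis clause AND
    procedure clause) from a non-empty selection."""
    if not selection.dx_codes or not selection.procedure_codes:
        raise CepsbError(
            "cannot build an algorithm from an empty selection partition"
        )
    return DetectionAlgorithm(
        name=name,
        admin=admin or AdminFilter(),
        clauses=(
            CodeClause(scope=Scope.ANY_DX, codes=selection.dx_codes),
            CodeClause(scope=Scope.PROCEDURE, codes=selection.procedure_codes),
        ),
    )


def write_screen_report(
    results: Sequence[CodeScreenResult], path: str | Path
) -> Path:
    """Screening report CSV: code, scope, 2x2 cells, LR+, p, selected."""
    import csv

    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(
            ["code", "scope", "a", "b", "c", "d", "lr_plus", "p_value", "selected"]
        )
        for r in results:
            writer.writerow(
                [
                    r.code.value,
                    r.scope.value,
                    r.a,
                    r.b,
                    r.c,
                    r.d,
                    repr(r.lr_plus),
                    repr(r.p_value),
                    str(r.selected).lower(),
                ]
            )
    return path
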
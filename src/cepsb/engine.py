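"""Declarative detection algorithms over coded discharge records.

An algorithm is an administrative eligibility filter plus a conjunction of
code-set clauses; a clause is satisfied when at least one of its codes is
present in the scoped position of the record (main diagnosis only,
associated position only, any diagnosis position, or procedures).  The two
built-in algorithms ship as packaged YAML files.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .records import (
    CepsbError,
    Code,
    CodeSystem,
    StayPair,
    analyzable,
    parse_code,
)

__all__ = [
    "Scope",
    "CodeClause",
    "AdminFilter",
    "DEFAULT_ADMIN_FILTER",
    "DetectionAlgorithm",
    "builtin_predefined",
    "builtin_pragmatic",
    "evaluate",
    "apply",
    "ApplyResult",
    "load_algorithm",
    "save_algorithm",
]


class Scope(str, Enum):
    """Record position a clause is matched against."""

    MAIN_DX = "MAIN_DX"
    ASSOC_DX = "ASSOC_DX"
    ANY_DX = "ANY_DX"
    PROCEDURE = "PROCEDURE"


_SCOPE_SYSTEM = {
    Scope.MAIN_DX: CodeSystem.ICD10,
    Scope.ASSOC_DX: CodeSystem.ICD10,
    Scope.ANY_DX: CodeSystem.ICD10,
    Scope.PROCEDURE: CodeSystem.CCAM,
}


@dataclass(frozen=True, slots=True)
class CodeClause:
    """A scoped disjunction: satisfied when any of its codes is present."""

    scope: Scope
    codes: frozenset[Code]

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", frozenset(self.codes))
        if not self.codes:
            raise ValueError("a clause needs at least one code")
        system = _SCOPE_SYSTEM[self.scope]
        for code in self.codes:
            if code.system is not system:
                raise ValueError(
                    f"clause with scope {self.scope.value} requires "
                    f"{system.value} codes, got {code.value}"
                )


@dataclass(frozen=True, slots=True)
class AdminFilter:
    """Administrative eligibility filter; age bounds are inclusive."""

    sex: str = "F"
    age_min: int = 18
    age_max: int = 45
    year: int = 2012
    unit: str = "gynecology"

    def __post_init__(self) -> None:
        if self.age_min > self.age_max:
            raise ValueError("age_min must not exceed age_max")

    def matches(self, stay: StayPair) -> bool:
        admin = stay.admin
        return (
            admin.sex == self.sex
            and self.age_min <= admin.age <= self.age_max
            and admin.year == self.year
            and admin.unit == self.unit
        )


DEFAULT_ADMIN_FILTER = AdminFilter()


@dataclass(frozen=True, slots=True)
class DetectionAlgorithm:
    """Admin filter AND conjunction of code clauses."""

    name: str
    admin: AdminFilter
    clauses: tuple[CodeClause, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "clauses", tuple(self.clauses))
        if not self.clauses:
            raise ValueError("an algorithm needs at least one clause")

    def same_rules(self, other: "DetectionAlgorithm") -> bool:
        """Structural equality ignoring the name."""
        return self.admin == other.admin and self.clauses == other.clauses


def _scope_codes(stay: StayPair, scope: Scope) -> frozenset[Code]:
    hdd = stay.hdd
    if scope is Scope.MAIN_DX:
        return frozenset() if hdd.main_diagnosis is None else frozenset({hdd.main_diagnosis})
    if scope is Scope.ASSOC_DX:
        return hdd.associated_diagnoses
    if scope is Scope.ANY_DX:
        return hdd.all_diagnoses()
    return hdd.procedures


def evaluate(alg: DetectionAlgorithm, stay: StayPair) -> bool:
    """True iff the admin filter passes and every clause is satisfied."""
    if not alg.admin.matches(stay):
        return False
    return all(
        not clause.codes.isdisjoint(_scope_codes(stay, clause.scope))
        for clause in alg.clauses
    )


@dataclass(frozen=True, slots=True)
class ApplyResult:
    """Verdicts for every analyzable stay plus the ids excluded for a
    missing medical record."""

    predictions: Mapping[str, bool]
    excluded: tuple[str, ...]


def apply(alg: DetectionAlgorithm, cohort: Iterable[StayPair]) -> ApplyResult:
    """Evaluate *alg* on every analyzable stay of the cohort.

    Verdicts are order-independent; stays without a medical record are
    reported separately rather than classified."""
    stays = list(cohort)
    kept = analyzable(stays)
    kept_ids = {s.stay_id for s in kept}
    excluded = tuple(s.stay_id for s in stays if s.stay_id not in kept_ids)
    predictions = {s.stay_id: evaluate(alg, s) for s in kept}
    return ApplyResult(predictions=predictions, excluded=excluded)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _algorithm_from_dict(data: Mapping) -> DetectionAlgorithm:
    try:
        admin = AdminFilter(
            sex=str(data["admin"]["sex"]),
            age_min=int(data["admin"]["age_min"]),
            age_max=int(data["admin"]["age_max"]),
            year=int(data["admin"]["year"]),
            unit=str(data["admin"]["unit"]),
        )
        clauses = tuple(
            CodeClause(
                scope=Scope(str(c["scope"])),
                codes=frozenset(
                    parse_code(str(v), _SCOPE_SYSTEM[Scope(str(c["scope"]))])
                    for v in c["codes"]
                ),
            )
            for c in data["clauses"]
        )
        return DetectionAlgorithm(name=str(data["name"]), admin=admin, clauses=clauses)
    except (KeyError, TypeError) as exc:
        raise CepsbError(f"malformed algorithm definition: {exc}") from exc


def _algorithm_to_dict(alg: DetectionAlgorithm) -> dict:
    return {
        "name": alg.name,
        "admin": {
            "sex": alg.admin.sex,
            "age_min": alg.admin.age_min,
            "age_max": alg.admin.age_max,
            "year": alg.admin.year,
            "unit": alg.admin.unit,
        },
        "clauses": [
            {
                "scope": clause.scope.value,
                "codes": sorted(code.value for code in clause.codes),
            }
            for clause in alg.clauses
        ],
    }


def load_algorithm(path: str | Path) -> DetectionAlgorithm:
    """Load an algorithm from a YAML (or JSON) definition file."""
    with Path(path).open(encoding="utf-8") as handle:
        return _algorithm_from_dict(yaml.safe_load(handle))


def save_algorithm(alg: DetectionAlgorithm, path: str | Path) -> Path:
    """Write an algorithm definition file; round-trips with
    :func:`load_algorithm`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        yaml.safe_dump(_algorithm_to_dict(alg), handle, sort_keys=False)
    return path


def _load_builtin(name: str) -> DetectionAlgorithm:
    resource = importlib.resources.files("cepsb").joinpath(f"data/{name}.yaml")
    return _algorithm_from_dict(yaml.safe_load(resource.read_text(encoding="utf-8")))


def builtin_predefined(*, complication_any_position: bool = False) -> DetectionAlgorithm:
    """The guideline-based algorithm: EP main diagnosis AND complication
    code AND EP-specific procedure, under the default admin filter.

    By default the complication clause is matched against the
    associated-diagnosis position only; pass
    ``complication_any_position=True`` to accept the complication in any
    diagnosis position.
    """
    alg = _load_builtin("predefined")
    if complication_any_position:
        clauses = tuple(
            replace(c, scope=Scope.ANY_DX) if c.scope is Scope.ASSOC_DX else c
            for c in alg.clauses
        )
        alg = replace(alg, clauses=clauses)
    return alg


def builtin_pragmatic() -> DetectionAlgorithm:
    """The practice-based algorithm: EP/haemorrhage code in any diagnosis
    position AND an EP-related procedure or massive transfusion."""
    return _load_builtin("pragmatic")
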
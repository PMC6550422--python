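"""Truth-labeled synthetic cohorts and coding-error injection.

The generator produces stay cohorts with *exact* per-center stay and case
counts (prevalence is fixed by count, never Bernoulli-sampled), ages from
a truncated normal and stay durations from a moment-matched log-normal.
Every stay receives the coded record that a perfectly compliant coder
would produce (:func:`ideal_coding`), so that with zero injected errors
the guideline-based detection algorithm attains sensitivity and
specificity 1.0 by construction.

Coding errors are then injected independently per (stay, error type) with
configurable probabilities, truncated at ``max_errors_per_stay``, and the
injections are returned as a ground-truth :class:`ErrorLog` so the audit
stage can be tested against a known answer.

Randomness: a single seeded NumPy generator, consumed in documented
(center, stay, draw) order, makes every output reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import (
    AdminData,
    AlternativeDiagnosis,
    CepsbError,
    HDDRecord,
    MedicalRecordAbstract,
    StayPair,
    classify_gold,
)
from .coding import (
    ALT_MAIN_DX,
    ANAEMIA_DX,
    COMPLICATION_DX,
    CYST_SURGERY_PROC,
    DELIVERY_DX,
    EP_MAIN_DX,
    EP_PROCEDURES,
    NON_EP_GYN_DX,
    NONSPECIFIC_SALPINGECTOMY,
    SITE_MAIN_DX,
    WRONG_COMPLICATION_DX,
    ErrorType,
    TAXONOMY_ORDER,
    ccam,
    expected_complication_codes,
    icd10,
)

__all__ = [
    "CohortConfig",
    "ErrorInjectionModel",
    "ErrorLog",
    "ideal_coding",
    "generate_cohort",
    "inject_errors",
    "calibrate_default_model",
    "DEFAULT_ERROR_TALLIES",
]


# --- Clinical mix of the generator (not part of the public config) --------

#: Complication profiles of a case: (tubal_rupture, hemoperitoneum>=500,
#: active_bleeding) with sampling weights.  Every case has at least one
#: complication.
COMPLICATION_PROFILES: tuple[tuple[tuple[bool, bool, bool], float], ...] = (
    ((True, True, True), 0.25),
    ((True, True, False), 0.15),
    ((False, True, False), 0.30),
    ((False, True, True), 0.10),
    ((False, False, True), 0.15),
    ((True, False, False), 0.05),
)

#: Site of implantation weights for cases (overwhelmingly tubal).
SITE_WEIGHTS: tuple[tuple[str, float], ...] = (
    ("tubal", 0.92),
    ("unspecified", 0.04),
    ("other", 0.02),
    ("ovarian", 0.01),
    ("abdominal", 0.01),
)

#: Final-diagnosis mix of the non-case stays.
ALT_WEIGHTS: tuple[tuple[AlternativeDiagnosis, float], ...] = (
    (AlternativeDiagnosis.SPONTANEOUS_ABORTION, 0.28),
    (AlternativeDiagnosis.OVARIAN_CYST_RUPTURE, 0.17),
    (AlternativeDiagnosis.IUP_METRORRHAGIA, 0.20),
    (AlternativeDiagnosis.UNCOMPLICATED_EP, 0.25),
    (AlternativeDiagnosis.PELVIC_INFECTION, 0.07),
    (AlternativeDiagnosis.OTHER, 0.03),
)

#: Fraction of uncomplicated ectopic pregnancies managed surgically
#: (these stays legitimately carry an EP main diagnosis and an EP
#: procedure code, which is what limits the specificity of the
#: practice-based algorithm).
SURGICAL_UNCOMPLICATED_EP = 0.18

#: Fraction of ovarian-cyst ruptures explored by laparoscopy.
OPERATED_CYST_RUPTURE = 0.5


@dataclass(frozen=True, slots=True)
class CohortConfig:
    """Calibration targets of the synthetic cohort."""

    n_stays_per_center: Mapping[str, int] = field(
        default_factory=lambda: {"A": 230, "B": 140}
    )
    cepsb_per_center: Mapping[str, int] = field(
        default_factory=lambda: {"A": 28, "B": 24}
    )
    excluded_per_center: Mapping[str, int] = field(
        default_factory=lambda: {"A": 0, "B": 0}
    )
    age_mean: float = 32.0
    age_sd: float = 6.6
    duration_mean: float = 2.21
    duration_sd: float = 1.7
    year: int = 2012
    seed: int = 0

    def __post_init__(self) -> None:
        for center, n in self.n_stays_per_center.items():
            if n < 0:
                raise CepsbError(f"negative stay count for center {center}")
            k = self.cepsb_per_center.get(center, 0)
            if k < 0 or k > n:
                raise CepsbError(
                    f"center {center}: case count {k} must lie in [0, {n}]"
                )
            if self.excluded_per_center.get(center, 0) < 0:
                raise CepsbError(f"negative excluded count for center {center}")
        if self.age_sd < 0 or self.duration_sd < 0:
            raise CepsbError("standard deviations must be non-negative")
        if self.duration_mean <= 0:
            raise CepsbError("duration_mean must be positive")

    @property
    def n_total(self) -> int:
        return sum(self.n_stays_per_center.values())

    @property
    def n_cases(self) -> int:
        return sum(
            self.cepsb_per_center.get(c, 0) for c in self.n_stays_per_center
        )

    def to_dict(self) -> dict:
        return {
            "n_stays_per_center": dict(self.n_stays_per_center),
            "cepsb_per_center": dict(self.cepsb_per_center),
            "excluded_per_center": dict(self.excluded_per_center),
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "duration_mean": self.duration_mean,
            "duration_sd": self.duration_sd,
            "year": self.year,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        return cls(**dict(data))


_MODEL_FIELDS: dict[ErrorType, str] = {
    ErrorType.INCORRECT_PRINCIPAL_DX: "p_incorrect_principal_dx",
    ErrorType.ABSENT_ASSOCIATED_DX: "p_absent_associated_dx",
    ErrorType.ABSENT_COMPLICATION_CODE: "p_absent_complication_code",
    ErrorType.INCORRECT_COMPLICATION_CODE: "p_incorrect_complication_code",
    ErrorType.ABSENT_EP_PROCEDURE: "p_absent_ep_procedure",
    ErrorType.ADMIN_ERROR: "p_admin_error",
    ErrorType.UNCODED_STAY: "p_uncoded_stay",
    ErrorType.DELIVERY_CODE_USED: "p_delivery_code",
    ErrorType.EXCESS_DX: "p_excess_dx",
}


@dataclass(frozen=True, slots=True)
class ErrorInjectionModel:
    """Per-type injection probabilities.

    The eight false-negative-side types apply to gold-positive stays; the
    excess type applies to gold-negative stays.  Per stay the types are
    drawn independently in taxonomy order and truncated at
    ``max_errors_per_stay``.
    """

    p_incorrect_principal_dx: float = 0.0
    p_absent_associated_dx: float = 0.0
    p_absent_complication_code: float = 0.0
    p_incorrect_complication_code: float = 0.0
    p_absent_ep_procedure: float = 0.0
    p_admin_error: float = 0.0
    p_uncoded_stay: float = 0.0
    p_delivery_code: float = 0.0
    p_excess_dx: float = 0.0
    max_errors_per_stay: int = 2

    def __post_init__(self) -> None:
        for error_type, name in _MODEL_FIELDS.items():
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise CepsbError(f"{name} must lie in [0, 1], got {p}")
        if self.max_errors_per_stay < 1:
            raise CepsbError("max_errors_per_stay must be >= 1")

    def probability(self, error_type: ErrorType) -> float:
        return getattr(self, _MODEL_FIELDS[error_type])

    def to_dict(self) -> dict:
        data = {name: getattr(self, name) for name in _MODEL_FIELDS.values()}
        data["max_errors_per_stay"] = self.max_errors_per_stay
        return data

    @classmethod
    def from_dict(cls, data: Mapping) -> "ErrorInjectionModel":
        return cls(**dict(data))


@dataclass(frozen=True, slots=True)
class ErrorLog:
    """Ground-truth record of injected errors: (stay_id, error_type) pairs
    in injection order."""

    entries: tuple[tuple[str, ErrorType], ...] = ()

    def by_stay(self) -> dict[str, tuple[ErrorType, ...]]:
        grouped: dict[str, list[ErrorType]] = {}
        for stay_id, error_type in self.entries:
            grouped.setdefault(stay_id, []).append(error_type)
        return {k: tuple(v) for k, v in grouped.items()}

    def type_counts(self) -> dict[ErrorType, int]:
        counts = {t: 0 for t in TAXONOMY_ORDER}
        for _, error_type in self.entries:
            counts[error_type] += 1
        return counts

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Ideal coding
# ---------------------------------------------------------------------------


def ideal_coding(gold: MedicalRecordAbstract, site: str = "tubal") -> HDDRecord:
    """The coded record a fully compliant coder would produce for *gold*.

    Cases receive the site-specific EP main diagnosis, one complication
    code per documented complication plus the post-haemorrhagic anaemia
    code, and the laparoscopic EP salpingectomy procedure.  Non-cases
    receive the main diagnosis of their final diagnosis; only surgically
    managed uncomplicated ectopic pregnancies and operated cyst ruptures
    carry a procedure code.  Non-cases never carry a complication code, so
    complete coding can never produce a false positive for the
    guideline-based algorithm.
    """
    if not gold.record_available:
        # Excluded stays still exist in files; give them a neutral record.
        return HDDRecord(main_diagnosis=icd10("R102"))
    if classify_gold(gold):
        if site not in SITE_MAIN_DX:
            raise CepsbError(f"unknown site of pregnancy {site!r}")
        assoc = set(expected_complication_codes(gold))
        assoc.add(ANAEMIA_DX)
        return HDDRecord(
            main_diagnosis=SITE_MAIN_DX[site],
            associated_diagnoses=frozenset(assoc),
            procedures=frozenset({ccam("JJFC001")}),
        )
    alt = gold.alternative_diagnosis
    procedures: set = set()
    if alt is AlternativeDiagnosis.UNCOMPLICATED_EP and gold.laparoscopy_performed:
        procedures.add(ccam("JJFC001"))
    elif alt is AlternativeDiagnosis.OVARIAN_CYST_RUPTURE and gold.laparoscopy_performed:
        procedures.add(CYST_SURGERY_PROC)
    return HDDRecord(
        main_diagnosis=ALT_MAIN_DX[alt], procedures=frozenset(procedures)
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _choice(rng: np.random.Generator, items: Sequence, weights: Sequence[float]):
    total = float(sum(weights))
    probs = [w / total for w in weights]
    index = int(rng.choice(len(items), p=probs))
    return items[index]


def _draw_age(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Normal(mean, sd) truncated to [18, 45] by rejection, rounded."""
    if sd == 0.0:
        return int(round(min(45.0, max(18.0, mean))))
    while True:
        x = rng.normal(mean, sd)
        if 18.0 <= x <= 45.0:
            return int(round(x))


def _duration_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given mean and SD."""
    if sd == 0.0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _draw_case_gold(rng: np.random.Generator) -> tuple[MedicalRecordAbstract, str]:
    profiles = [p for p, _ in COMPLICATION_PROFILES]
    weights = [w for _, w in COMPLICATION_PROFILES]
    rupture, big_hemo, bleeding = _choice(rng, profiles, weights)
    site = _choice(
        rng, [s for s, _ in SITE_WEIGHTS], [w for _, w in SITE_WEIGHTS]
    )
    if big_hemo:
        hemo = float(round(rng.uniform(500.0, 1500.0)))
    else:
        hemo = float(round(rng.uniform(50.0, 450.0)))
    gold = MedicalRecordAbstract(
        record_available=True,
        pregnancy_test_positive=True,
        ep_confirmed_histology=True,
        laparoscopy_performed=True,
        tubal_rupture=rupture,
        hemoperitoneum_cc=hemo,
        active_bleeding=bleeding,
        alternative_diagnosis=AlternativeDiagnosis.NONE,
    )
    return gold, site


def _draw_control_gold(rng: np.random.Generator) -> MedicalRecordAbstract:
    alt = _choice(rng, [a for a, _ in ALT_WEIGHTS], [w for _, w in ALT_WEIGHTS])
    pregnant = alt in (
        AlternativeDiagnosis.SPONTANEOUS_ABORTION,
        AlternativeDiagnosis.IUP_METRORRHAGIA,
        AlternativeDiagnosis.UNCOMPLICATED_EP,
    )
    ep = alt is AlternativeDiagnosis.UNCOMPLICATED_EP
    if alt is AlternativeDiagnosis.UNCOMPLICATED_EP:
        laparoscopy = bool(rng.random() < SURGICAL_UNCOMPLICATED_EP)
        hemo = float(round(rng.uniform(0.0, 300.0)))
    elif alt is AlternativeDiagnosis.OVARIAN_CYST_RUPTURE:
        laparoscopy = bool(rng.random() < OPERATED_CYST_RUPTURE)
        hemo = float(round(rng.uniform(0.0, 450.0)))
    else:
        laparoscopy = False
        hemo = 0.0
    return MedicalRecordAbstract(
        record_available=True,
        pregnancy_test_positive=pregnant,
        ep_confirmed_histology=ep,
        laparoscopy_performed=laparoscopy,
        tubal_rupture=False,
        hemoperitoneum_cc=hemo,
        active_bleeding=False,
        alternative_diagnosis=alt,
    )


def generate_cohort(cfg: CohortConfig) -> list[StayPair]:
    """Generate an error-free, truth-labeled cohort.

    Deterministic for a fixed ``cfg.seed``; per-center stay, case and
    excluded counts are exact.  Case positions within each center are a
    seeded permutation.
    """
    rng = np.random.default_rng(cfg.seed)
    mu, sigma = _duration_params(cfg.duration_mean, cfg.duration_sd)
    cohort: list[StayPair] = []
    for center in sorted(cfg.n_stays_per_center):
        n = cfg.n_stays_per_center[center]
        k = cfg.cepsb_per_center.get(center, 0)
        case_positions = set(int(i) for i in rng.permutation(n)[:k])
        for i in range(n):
            age = _draw_age(rng, cfg.age_mean, cfg.age_sd)
            duration = float(round(max(0.0, rng.lognormal(mu, sigma)), 2))
            if i in case_positions:
                gold, site = _draw_case_gold(rng)
            else:
                gold = _draw_control_gold(rng)
                site = "tubal"
            admin = AdminData(
                stay_id=f"{center}{i + 1:04d}",
                center=center,
                sex="F",
                age=age,
                year=cfg.year,
                unit="gynecology",
                duration=duration,
            )
            cohort.append(
                StayPair(admin=admin, gold=gold, hdd=ideal_coding(gold, site))
            )
        for j in range(cfg.excluded_per_center.get(center, 0)):
            age = _draw_age(rng, cfg.age_mean, cfg.age_sd)
            duration = float(round(max(0.0, rng.lognormal(mu, sigma)), 2))
            gold = MedicalRecordAbstract(record_available=False)
            admin = AdminData(
                stay_id=f"{center}X{j + 1:03d}",
                center=center,
                sex="F",
                age=age,
                year=cfg.year,
                unit="gynecology",
                duration=duration,
            )
            cohort.append(StayPair(admin=admin, gold=gold, hdd=ideal_coding(gold)))
    return cohort


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------


def _applicable(stay: StayPair, error_type: ErrorType, n_injected: int) -> bool:
    """Whether *error_type* can act on the stay in its current state.

    Applicability keeps injected types distinguishable by the audit: a
    type never fires when an earlier mutation already removed its target
    (e.g. no wrong-complication substitution after the complication codes
    were deleted, no record emptying once the stay already carries an
    error).
    """
    hdd = stay.hdd
    if error_type is ErrorType.INCORRECT_PRINCIPAL_DX:
        return hdd.main_diagnosis in EP_MAIN_DX
    if error_type is ErrorType.ABSENT_ASSOCIATED_DX:
        return ANAEMIA_DX in hdd.associated_diagnoses
    if error_type is ErrorType.ABSENT_COMPLICATION_CODE:
        return not hdd.associated_diagnoses.isdisjoint(COMPLICATION_DX)
    if error_type is ErrorType.INCORRECT_COMPLICATION_CODE:
        return not hdd.associated_diagnoses.isdisjoint(COMPLICATION_DX)
    if error_type is ErrorType.ABSENT_EP_PROCEDURE:
        return not hdd.procedures.isdisjoint(EP_PROCEDURES)
    if error_type is ErrorType.ADMIN_ERROR:
        return True
    if error_type is ErrorType.UNCODED_STAY:
        return n_injected == 0 and not hdd.is_uncoded
    if error_type is ErrorType.DELIVERY_CODE_USED:
        return hdd.main_diagnosis in EP_MAIN_DX
    if error_type is ErrorType.EXCESS_DX:
        return True
    raise AssertionError(error_type)


def _mutate(
    stay: StayPair, error_type: ErrorType, rng: np.random.Generator
) -> StayPair:
    hdd = stay.hdd
    if error_type is ErrorType.INCORRECT_PRINCIPAL_DX:
        new_hdd = replace(hdd, main_diagnosis=NON_EP_GYN_DX)
    elif error_type is ErrorType.ABSENT_ASSOCIATED_DX:
        new_hdd = replace(
            hdd, associated_diagnoses=hdd.associated_diagnoses - {ANAEMIA_DX}
        )
    elif error_type is ErrorType.ABSENT_COMPLICATION_CODE:
        new_hdd = replace(
            hdd, associated_diagnoses=hdd.associated_diagnoses - COMPLICATION_DX
        )
    elif error_type is ErrorType.INCORRECT_COMPLICATION_CODE:
        present = sorted(
            (hdd.associated_diagnoses & COMPLICATION_DX), key=lambda c: c.value
        )
        victim = present[int(rng.integers(len(present)))]
        new_hdd = replace(
            hdd,
            associated_diagnoses=(hdd.associated_diagnoses - {victim})
            | {WRONG_COMPLICATION_DX},
        )
    elif error_type is ErrorType.ABSENT_EP_PROCEDURE:
        specific = hdd.procedures & EP_PROCEDURES
        if ccam("JJFC001") in specific:
            new_procs = (hdd.procedures - {ccam("JJFC001")}) | {
                NONSPECIFIC_SALPINGECTOMY
            }
        else:
            new_procs = hdd.procedures - EP_PROCEDURES
        new_hdd = replace(hdd, procedures=new_procs)
    elif error_type is ErrorType.ADMIN_ERROR:
        if rng.random() < 0.5:
            return replace(stay, admin=replace(stay.admin, unit="maternity"))
        return replace(stay, admin=replace(stay.admin, age=48))
    elif error_type is ErrorType.UNCODED_STAY:
        new_hdd = HDDRecord()
    elif error_type is ErrorType.DELIVERY_CODE_USED:
        new_hdd = replace(hdd, main_diagnosis=DELIVERY_DX)
    elif error_type is ErrorType.EXCESS_DX:
        new_hdd = HDDRecord(
            main_diagnosis=icd10("O001"),
            associated_diagnoses=hdd.associated_diagnoses | {icd10("O081")},
            procedures=hdd.procedures | {ccam("JJFC001")},
        )
    else:  # pragma: no cover
        raise AssertionError(error_type)
    return replace(stay, hdd=new_hdd)


def inject_errors(
    cohort: Iterable[StayPair], model: ErrorInjectionModel, seed: int
) -> tuple[list[StayPair], ErrorLog]:
    """Inject coding errors into an (ideally coded) cohort.

    For each analyzable stay, the applicable error types are drawn
    independently in taxonomy order with their configured probabilities,
    stopping once ``max_errors_per_stay`` errors fired.  False-negative
    error types act on gold-positive stays; the excess type acts on
    gold-negative stays.  Returns the mutated cohort (input untouched)
    and the ground-truth log, both reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    mutated: list[StayPair] = []
    entries: list[tuple[str, ErrorType]] = []
    for stay in cohort:
        if not stay.gold.record_available:
            mutated.append(stay)
            continue
        is_case = classify_gold(stay.gold)
        n_injected = 0
        for error_type in TAXONOMY_ORDER:
            if n_injected >= model.max_errors_per_stay:
                break
            if is_case != (error_type is not ErrorType.EXCESS_DX):
                continue
            p = model.probability(error_type)
            if p == 0.0 or not _applicable(stay, error_type, n_injected):
                continue
            if rng.random() < p:
                stay = _mutate(stay, error_type, rng)
                entries.append((stay.stay_id, error_type))
                n_injected += 1
        mutated.append(stay)
    return mutated, ErrorLog(entries=tuple(entries))


#: Per-type error tallies observed in the two-center audit that the
#: default model is calibrated to reproduce in expectation.
DEFAULT_ERROR_TALLIES: dict[ErrorType, int] = {
    ErrorType.INCORRECT_PRINCIPAL_DX: 3,
    ErrorType.ABSENT_ASSOCIATED_DX: 19,
    ErrorType.ABSENT_COMPLICATION_CODE: 11,
    ErrorType.INCORRECT_COMPLICATION_CODE: 2,
    ErrorType.ABSENT_EP_PROCEDURE: 7,
    ErrorType.ADMIN_ERROR: 2,
    ErrorType.UNCODED_STAY: 1,
    ErrorType.DELIVERY_CODE_USED: 1,
    ErrorType.EXCESS_DX: 3,
}


def calibrate_default_model(cfg: CohortConfig | None = None) -> ErrorInjectionModel:
    """Model whose marginal per-type probabilities equal the observed
    tallies divided by the eligible stratum size (gold positives for the
    false-negative types, gold negatives for the excess type)."""
    cfg = cfg or CohortConfig()
    positives = cfg.n_cases
    negatives = cfg.n_total - positives
    if positives == 0 or negatives == 0:
        raise CepsbError("calibration requires both cases and non-cases")
    kwargs: dict[str, float] = {}
    for error_type, tally in DEFAULT_ERROR_TALLIES.items():
        stratum = negatives if error_type is ErrorType.EXCESS_DX else positives
        if tally > stratum:
            raise CepsbError(
                f"cohort too small to calibrate {error_type.value}: "
                f"tally {tally} exceeds eligible stratum of {stratum} stays"
            )
        kwargs[_MODEL_FIELDS[error_type]] = tally / stratum
    return ErrorInjectionModel(**kwargs)
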
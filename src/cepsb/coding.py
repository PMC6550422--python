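"""Reference code sets and the coding-error taxonomy.

Central place for the ICD-10 / CCAM code groups that the detection
algorithms, the ideal-coding function and the error audit all agree on,
plus the nine-member coding-error taxonomy and its grouping into
code-system families.
"""

from __future__ import annotations

from enum import Enum

from .records import (
    AlternativeDiagnosis,
    Code,
    CodeSystem,
    MedicalRecordAbstract,
    parse_code,
)

__all__ = [
    "icd10",
    "ccam",
    "EP_MAIN_DX",
    "COMPLICATION_DX",
    "EP_PROCEDURES",
    "SITE_MAIN_DX",
    "ALT_MAIN_DX",
    "ANAEMIA_DX",
    "WRONG_COMPLICATION_DX",
    "NON_EP_GYN_DX",
    "DELIVERY_DX",
    "NONSPECIFIC_SALPINGECTOMY",
    "CYST_SURGERY_PROC",
    "is_delivery_code",
    "expected_complication_codes",
    "ErrorType",
    "ErrorGroup",
    "ERROR_GROUP",
    "FN_ERROR_TYPES",
    "TAXONOMY_ORDER",
]


def icd10(value: str) -> Code:
    return parse_code(value, CodeSystem.ICD10)


def ccam(value: str) -> Code:
    return parse_code(value, CodeSystem.CCAM)


#: Ectopic-pregnancy main-diagnosis codes, by site of implantation.
SITE_MAIN_DX: dict[str, Code] = {
    "tubal": icd10("O001"),
    "abdominal": icd10("O000"),
    "ovarian": icd10("O002"),
    "other": icd10("O008"),
    "unspecified": icd10("O009"),
}

#: All EP main-diagnosis codes.
EP_MAIN_DX: frozenset[Code] = frozenset(SITE_MAIN_DX.values())

#: Complication codes accepted in associated-diagnosis position:
#: post-abortive/EP haemorrhage, hemoperitoneum, transfusion, shock,
#: pelvic-organ damage.
COMPLICATION_DX: frozenset[Code] = frozenset(
    icd10(v) for v in ("O081", "K661", "Z513", "O083", "O086")
)

#: EP-specific surgical procedure codes (salpingectomy / salpingotomy /
#: abdominal-EP extraction, by laparotomy or laparoscopy).
EP_PROCEDURES: frozenset[Code] = frozenset(
    ccam(v) for v in ("JJFA001", "JJFC001", "JQGA001", "JJPC001", "JJPA001")
)

#: Non-specific sibling of the laparoscopic EP salpingectomy code: a
#: plain total salpingectomy, not marked as performed for an EP.
NONSPECIFIC_SALPINGECTOMY: Code = ccam("JJFC006")

#: Acute post-haemorrhagic anaemia: the benign associated diagnosis that
#: complete coding adds to every severe-bleeding stay.
ANAEMIA_DX: Code = icd10("D62")

#: A syntactically valid but clinically wrong complication code
#: (haemorrhage, not elsewhere classified) used when a complication is
#: miscoded.
WRONG_COMPLICATION_DX: Code = icd10("R58")

#: Non-EP gynecological code (abnormal uterine bleeding, unspecified)
#: substituted for the main diagnosis by the principal-diagnosis error.
NON_EP_GYN_DX: Code = icd10("N939")

#: Single-delivery code written as main diagnosis by the delivery error.
DELIVERY_DX: Code = icd10("O80")

#: Adnexal surgery code used for operated ovarian-cyst ruptures.
CYST_SURGERY_PROC: Code = ccam("JJFC002")

#: Main-diagnosis codes of the non-CEPSB differential diagnoses.
ALT_MAIN_DX: dict[AlternativeDiagnosis, Code] = {
    AlternativeDiagnosis.SPONTANEOUS_ABORTION: icd10("O039"),
    AlternativeDiagnosis.OVARIAN_CYST_RUPTURE: icd10("N832"),
    AlternativeDiagnosis.IUP_METRORRHAGIA: icd10("O200"),
    AlternativeDiagnosis.UNCOMPLICATED_EP: icd10("O001"),
    AlternativeDiagnosis.PELVIC_INFECTION: icd10("N739"),
    AlternativeDiagnosis.OTHER: icd10("R102"),
    AlternativeDiagnosis.NONE: icd10("R102"),
}

_DELIVERY_ROOTS = ("O80", "O81", "O82", "O83", "O84")


def is_delivery_code(code: Code) -> bool:
    """True for delivery codes (roots O80-O84, with or without subcode)."""
    return code.system is CodeSystem.ICD10 and code.value[:3] in _DELIVERY_ROOTS


def expected_complication_codes(gold: MedicalRecordAbstract) -> frozenset[Code]:
    """Complication codes that complete coding of *gold* must carry:
    pelvic-organ damage for tubal rupture, hemoperitoneum for >= 500 cc,
    post-EP haemorrhage for active bleeding."""
    expected = set()
    if gold.tubal_rupture:
        expected.add(icd10("O086"))
    if gold.hemoperitoneum_cc >= 500.0:
        expected.add(icd10("K661"))
    if gold.active_bleeding:
        expected.add(icd10("O081"))
    return frozenset(expected)


class ErrorType(str, Enum):
    """The nine coding-error types, in audit-table order."""

    INCORRECT_PRINCIPAL_DX = "incorrect_principal_dx"
    ABSENT_ASSOCIATED_DX = "absent_associated_dx"
    ABSENT_COMPLICATION_CODE = "absent_complication_code"
    INCORRECT_COMPLICATION_CODE = "incorrect_complication_code"
    ABSENT_EP_PROCEDURE = "absent_ep_procedure"
    ADMIN_ERROR = "admin_error"
    UNCODED_STAY = "uncoded_stay"
    DELIVERY_CODE_USED = "delivery_code_used"
    EXCESS_DX = "excess_dx"


#: Error types that cause false negatives (all but the excess type).
FN_ERROR_TYPES: tuple[ErrorType, ...] = tuple(
    t for t in ErrorType if t is not ErrorType.EXCESS_DX
)

#: Sampling / tabulation order of the taxonomy.
TAXONOMY_ORDER: tuple[ErrorType, ...] = tuple(ErrorType)


class ErrorGroup(str, Enum):
    """Code-system family of an error type."""

    ICD10_MISUSE = "ICD10_MISUSE"
    CCAM_MISUSE = "CCAM_MISUSE"
    ADMIN = "ADMIN"
    UNCODED = "UNCODED"
    DELIVERY = "DELIVERY"


#: Fixed mapping from error type to code-system family.
ERROR_GROUP: dict[ErrorType, ErrorGroup] = {
    ErrorType.INCORRECT_PRINCIPAL_DX: ErrorGroup.ICD10_MISUSE,
    ErrorType.ABSENT_ASSOCIATED_DX: ErrorGroup.ICD10_MISUSE,
    ErrorType.ABSENT_COMPLICATION_CODE: ErrorGroup.ICD10_MISUSE,
    ErrorType.INCORRECT_COMPLICATION_CODE: ErrorGroup.ICD10_MISUSE,
    ErrorType.EXCESS_DX: ErrorGroup.ICD10_MISUSE,
    ErrorType.ABSENT_EP_PROCEDURE: ErrorGroup.CCAM_MISUSE,
    ErrorType.ADMIN_ERROR: ErrorGroup.ADMIN,
    ErrorType.UNCODED_STAY: ErrorGroup.UNCODED,
    ErrorType.DELIVERY_CODE_USED: ErrorGroup.DELIVERY,
}
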
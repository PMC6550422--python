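"""Independent test oracles.

These deliberately re-derive results from first principles (exhaustive
enumeration, brute force, exact integer arithmetic) without touching the
code paths they are used to check.
"""

from math import comb

from cepsb.coding import ErrorType, TAXONOMY_ORDER


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Sums the probability of every table with the observed margins whose
    probability does not exceed the observed table's, using exact integer
    arithmetic for the comparisons.
    """
    r1, c1 = a + b, a + c
    n = a + b + c + d
    c2 = n - c1
    lo, hi = max(0, r1 - c2), min(r1, c1)
    n_obs = comb(c1, a) * comb(c2, r1 - a)
    total = comb(n, r1)
    acc = 0
    for x in range(lo, hi + 1):
        w = comb(c1, x) * comb(c2, r1 - x)
        if w <= n_obs:
            acc += w
    return acc / total


def brute_force_verdict(alg, stay) -> bool:
    """Membership-table evaluation of a detection algorithm on one stay."""
    admin = stay.admin
    filt = alg.admin
    admin_ok = (
        admin.sex == filt.sex
        and filt.age_min <= admin.age <= filt.age_max
        and admin.year == filt.year
        and admin.unit == filt.unit
    )
    if not admin_ok:
        return False
    main = stay.hdd.main_diagnosis
    field_contents = {
        "MAIN_DX": set() if main is None else {main},
        "ASSOC_DX": set(stay.hdd.associated_diagnoses),
        "ANY_DX": set(stay.hdd.associated_diagnoses) | (set() if main is None else {main}),
        "PROCEDURE": set(stay.hdd.procedures),
    }
    # explicit (clause, code) membership table
    satisfied = []
    for clause in alg.clauses:
        hits = [code in field_contents[clause.scope.value] for code in clause.codes]
        satisfied.append(any(hits))
    return all(satisfied)


# Sequential injection process on a gold-positive ideally coded stay:
# probability that each error type is realized, accounting for the
# documented applicability rules and the truncation at two errors per
# stay, by exact enumeration of all fire/skip branches.

_CASE_TYPES = tuple(t for t in TAXONOMY_ORDER if t is not ErrorType.EXCESS_DX)


def _applicable(error_type: ErrorType, fired: frozenset, n: int) -> bool:
    if error_type is ErrorType.INCORRECT_COMPLICATION_CODE:
        return ErrorType.ABSENT_COMPLICATION_CODE not in fired
    if error_type is ErrorType.UNCODED_STAY:
        return n == 0
    if error_type is ErrorType.DELIVERY_CODE_USED:
        return (
            ErrorType.INCORRECT_PRINCIPAL_DX not in fired
            and ErrorType.UNCODED_STAY not in fired
        )
    return True


def case_type_probabilities(model) -> dict[ErrorType, float]:
    """Exact marginal realization probability of each false-negative-side
    error type on one gold-positive stay under *model*."""
    marginals = {t: 0.0 for t in _CASE_TYPES}

    def recurse(index: int, prob: float, fired: frozenset, n: int) -> None:
        if index == len(_CASE_TYPES) or n >= model.max_errors_per_stay:
            return
        error_type = _CASE_TYPES[index]
        p = model.probability(error_type)
        if p == 0.0 or not _applicable(error_type, fired, n):
            recurse(index + 1, prob, fired, n)
            return
        marginals[error_type] += prob * p
        recurse(index + 1, prob * p, fired | {error_type}, n + 1)
        recurse(index + 1, prob * (1.0 - p), fired, n)

    recurse(0, 1.0, frozenset(), 0)
    return marginals
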
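"""Diagnostic-accuracy statistics: confusion matrices, sensitivity and
specificity with 95% confidence intervals, the positive likelihood ratio
with a log-method interval, and two-center comparisons.

Interval conventions
--------------------
Proportions use the Wald (normal-approximation) interval by default,
clipped to [0, 1]; a Wilson interval is available behind ``method``.
The positive likelihood ratio uses the log-method interval

    exp( ln LR+  +/- 1.96 * sqrt(1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn)) ).

Displayed values round half-up, one decimal; underlying values keep full
precision.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .records import CepsbError, StayPair, analyzable, classify_gold
from .engine import DetectionAlgorithm, apply

__all__ = [
    "Z_95",
    "round_half_up",
    "ConfusionMatrix",
    "Estimate",
    "LRPlusEstimate",
    "ValidityReport",
    "confusion",
    "sensitivity_ci",
    "specificity_ci",
    "positive_lr_ci",
    "proportions_pvalue",
    "compare_centers",
    "center_confusions",
    "validity_report",
    "format_validity_table",
]

#: Two-sided 95% normal quantile as conventionally used in the interval
#: formulas (1.96, not the exact quantile).
Z_95 = 1.96


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero at *ndigits* decimals (display rule)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class DegenerateMetricError(CepsbError):
    """The requested metric is undefined for this confusion matrix."""


@dataclass(frozen=True, slots=True)
class ConfusionMatrix:
    """2x2 cross-tabulation of algorithm verdicts against the gold standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def gold_positives(self) -> int:
        return self.tp + self.fn

    @property
    def gold_negatives(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive_tests(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True, slots=True)
class Estimate:
    """A proportion with its 95% confidence interval, all in [0, 1]."""

    point: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.point <= self.upper):
            raise ValueError("interval must bracket the point estimate")

    def as_percent(self) -> tuple[float, float, float]:
        """(point, lower, upper) in percent, rounded half-up to 1 decimal."""
        return (
            round_half_up(100.0 * self.point),
            round_half_up(100.0 * self.lower),
            round_half_up(100.0 * self.upper),
        )


@dataclass(frozen=True, slots=True)
class LRPlusEstimate:
    """Positive likelihood ratio with its 95% CI.

    When ``fp == 0`` the ratio is infinite; ``corrected_point`` then
    carries a finite estimate with 0.5 added to all four cells.  When
    ``tp == 0`` the ratio is 0 and the interval is undefined (NaN bounds).
    """

    point: float
    lower: float
    upper: float
    corrected_point: float | None = None

    @property
    def defined_ci(self) -> bool:
        return not (math.isnan(self.lower) or math.isnan(self.upper))


@dataclass(frozen=True, slots=True)
class ValidityReport:
    """One detection-validity table row."""

    algorithm: str
    n_positive_tests: int
    sensitivity: Estimate
    specificity: Estimate
    lr_plus: LRPlusEstimate
    false_positives: int
    false_negatives: int


def confusion(
    predictions: Mapping[str, bool], gold_labels: Mapping[str, bool]
) -> ConfusionMatrix:
    """Cross-tabulate per-stay verdicts against gold labels.

    Both mappings must cover exactly the same stay ids; a mismatch raises
    with the differing ids listed.
    """
    missing = set(gold_labels) - set(predictions)
    extra = set(predictions) - set(gold_labels)
    if missing or extra:
        raise CepsbError(
            "prediction/gold id mismatch: "
            f"missing predictions for {sorted(missing)}, "
            f"unexpected predictions for {sorted(extra)}"
        )
    tp = fp = fn = tn = 0
    for stay_id, is_case in gold_labels.items():
        flagged = predictions[stay_id]
        if is_case and flagged:
            tp += 1
        elif is_case:
            fn += 1
        elif flagged:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _wald(successes: int, total: int) -> Estimate:
    p = successes / total
    half = Z_95 * math.sqrt(p * (1.0 - p) / total)
    return Estimate(point=p, lower=max(0.0, p - half), upper=min(1.0, p + half))


def _proportion_ci(successes: int, total: int, method: str) -> Estimate:
    if method == "wald":
        return _wald(successes, total)
    if method == "wilson":
        from statsmodels.stats.proportion import proportion_confint

        lower, upper = proportion_confint(successes, total, method="wilson")
        return Estimate(point=successes / total, lower=float(lower), upper=float(upper))
    raise ValueError(f"unknown CI method {method!r}")


def sensitivity_ci(cm: ConfusionMatrix, method: str = "wald") -> Estimate:
    """tp / (tp + fn) with its 95% CI."""
    if cm.gold_positives == 0:
        raise DegenerateMetricError("sensitivity undefined: no gold positives")
    return _proportion_ci(cm.tp, cm.gold_positives, method)


def specificity_ci(cm: ConfusionMatrix, method: str = "wald") -> Estimate:
    """tn / (tn + fp) with its 95% CI (upper bound clipped at 1)."""
    if cm.gold_negatives == 0:
        raise DegenerateMetricError("specificity undefined: no gold negatives")
    return _proportion_ci(cm.tn, cm.gold_negatives, method)


def positive_lr_ci(cm: ConfusionMatrix) -> LRPlusEstimate:
    """Sensitivity / (1 - specificity) with the log-method 95% CI."""
    if cm.gold_negatives == 0:
        raise DegenerateMetricError("LR+ undefined: no gold negatives")
    if cm.gold_positives == 0:
        raise DegenerateMetricError("LR+ undefined: no gold positives")
    sens = cm.tp / cm.gold_positives
    if cm.tp == 0:
        return LRPlusEstimate(point=0.0, lower=math.nan, upper=math.nan)
    if cm.fp == 0:
        corrected = ((cm.tp + 0.5) / (cm.gold_positives + 1.0)) / (
            (cm.fp + 0.5) / (cm.gold_negatives + 1.0)
        )
        return LRPlusEstimate(
            point=math.inf, lower=math.nan, upper=math.nan, corrected_point=corrected
        )
    point = sens / (cm.fp / cm.gold_negatives)
    se_log = math.sqrt(
        1.0 / cm.tp - 1.0 / cm.gold_positives + 1.0 / cm.fp - 1.0 / cm.gold_negatives
    )
    return LRPlusEstimate(
        point=point,
        lower=math.exp(math.log(point) - Z_95 * se_log),
        upper=math.exp(math.log(point) + Z_95 * se_log),
    )


def proportions_pvalue(k1: int, n1: int, k2: int, n2: int) -> tuple[float, str]:
    """Two-sided p-value comparing two proportions k1/n1 vs k2/n2.

    Uses the Fisher exact test when any expected cell count is below 5,
    otherwise the chi-square test without continuity correction.  Returns
    ``(p, test_name)``.
    """
    if n1 <= 0 or n2 <= 0:
        raise DegenerateMetricError("cannot compare empty groups")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    n = n1 + n2
    col1, col2 = k1 + k2, n - (k1 + k2)
    if col1 == 0 or col2 == 0:
        return 1.0, "degenerate"
    expected_min = min(
        r * c / n for r in (n1, n2) for c in (col1, col2)
    )
    if expected_min < 5.0:
        return float(stats.fisher_exact(table).pvalue), "fisher"
    result = stats.chi2_contingency(table, correction=False)
    return float(result.pvalue), "chi2"


def compare_centers(
    cm_a: ConfusionMatrix, cm_b: ConfusionMatrix, metric: str
) -> tuple[float, str]:
    """Two-sided p-value for a between-center difference in sensitivity or
    specificity."""
    if metric == "sensitivity":
        if cm_a.gold_positives == 0 or cm_b.gold_positives == 0:
            raise DegenerateMetricError("sensitivity undefined for a center")
        return proportions_pvalue(
            cm_a.tp, cm_a.gold_positives, cm_b.tp, cm_b.gold_positives
        )
    if metric == "specificity":
        if cm_a.gold_negatives == 0 or cm_b.gold_negatives == 0:
            raise DegenerateMetricError("specificity undefined for a center")
        return proportions_pvalue(
            cm_a.tn, cm_a.gold_negatives, cm_b.tn, cm_b.gold_negatives
        )
    raise ValueError(f"unknown metric {metric!r}")


def center_confusions(
    cohort: Iterable[StayPair], algorithm: DetectionAlgorithm
) -> dict[str, ConfusionMatrix]:
    """Per-center confusion matrices for *algorithm* on *cohort*."""
    stays = analyzable(cohort)
    result: dict[str, ConfusionMatrix] = {}
    for center in sorted({s.admin.center for s in stays}):
        subset = [s for s in stays if s.admin.center == center]
        outcome = apply(algorithm, subset)
        labels = {s.stay_id: classify_gold(s.gold) for s in subset}
        result[center] = confusion(outcome.predictions, labels)
    return result


def validity_report(
    cohort: Iterable[StayPair],
    algorithm: DetectionAlgorithm,
    method: str = "wald",
) -> tuple[ValidityReport, ConfusionMatrix]:
    """Apply *algorithm* to *cohort* and compute the full validity row."""
    stays = analyzable(cohort)
    if not stays:
        raise CepsbError("empty cohort: nothing to validate")
    outcome = apply(algorithm, stays)
    labels = {s.stay_id: classify_gold(s.gold) for s in stays}
    cm = confusion(outcome.predictions, labels)
    report = ValidityReport(
        algorithm=algorithm.name,
        n_positive_tests=cm.n_positive_tests,
        sensitivity=sensitivity_ci(cm, method),
        specificity=specificity_ci(cm, method),
        lr_plus=positive_lr_ci(cm),
        false_positives=cm.fp,
        false_negatives=cm.fn,
    )
    return report, cm


_TABLE_HEADER = (
    "algorithm",
    "positive_tests",
    "sensitivity_pct",
    "sensitivity_ci",
    "specificity_pct",
    "specificity_ci",
    "lr_plus",
    "lr_plus_ci",
    "false_positives",
    "false_negatives",
)


def _report_cells(report: ValidityReport) -> tuple[str, ...]:
    se, se_lo, se_hi = report.sensitivity.as_percent()
    sp, sp_lo, sp_hi = report.specificity.as_percent()
    lr = report.lr_plus
    if math.isinf(lr.point):
        lr_point = "inf"
        lr_ci = f"corrected {round_half_up(lr.corrected_point)}"
    elif lr.point == 0.0:
        lr_point, lr_ci = "0.0", "undefined"
    else:
        lr_point = f"{round_half_up(lr.point)}"
        lr_ci = f"{round_half_up(lr.lower)}-{round_half_up(lr.upper)}"
    return (
        report.algorithm,
        str(report.n_positive_tests),
        f"{se}",
        f"{se_lo}-{se_hi}",
        f"{sp}",
        f"{sp_lo}-{sp_hi}",
        lr_point,
        lr_ci,
        str(report.false_positives),
        str(report.false_negatives),
    )


def format_validity_table(
    reports: Sequence[ValidityReport], fmt: str = "md"
) -> str:
    """Render validity rows as a Markdown or CSV table."""
    rows = [_report_cells(r) for r in reports]
    if fmt == "csv":
        buffer = io.StringIO()
        writer = csv.writer(buffer, lineterminator="\n")
        writer.writerow(_TABLE_HEADER)
        writer.writerows(rows)
        return buffer.getvalue()
    if fmt == "md":
        lines = [
            "| " + " | ".join(_TABLE_HEADER) + " |",
            "| " + " | ".join("---" for _ in _TABLE_HEADER) + " |",
        ]
        lines += ["| " + " | ".join(row) + " |" for row in rows]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown table format {fmt!r}")


def write_validity_table(
    reports: Sequence[ValidityReport], path: str | Path, fmt: str = "csv"
) -> Path:
    path = Path(path)
    path.write_text(format_validity_table(reports, fmt), encoding="utf-8")
    return path
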
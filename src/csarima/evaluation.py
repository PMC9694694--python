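"""RMSE per predicted postprandial period, cohort aggregation, and paired tests.

Accuracy is measured as the root-mean-squared error between the PH-step-ahead
predictions and the CGM targets over the evaluable pairs of each PP.
Aggregation follows the clinical-reporting convention: per-subject median
over that subject's PPs, then cohort median and [25th, 75th] percentiles over
the subject medians.  Method comparison is normality-gated: Shapiro–Wilk on
the paired differences chooses between a paired t-test and a Wilcoxon
signed-rank test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class EvaluationResult:
    """Per-PP RMSEs with subject-level and cohort-level summaries."""

    per_pp_rmse: dict[tuple, float]  # (subject, meal_index, ph) -> mg/dL
    per_subject_median: dict[tuple, float]  # (subject, ph) -> mg/dL
    cohort_median_iqr: dict[int, tuple[float, float, float]]  # ph -> (median, q1, q3)
    pairwise_tests: dict[tuple, tuple[str, float, bool]] = field(default_factory=dict)


def rmse_pp(pairs) -> float:
    """Root-mean-squared error over a PP's (target, prediction) pairs, mg/dL."""
    pairs = list(pairs)
    if not pairs:
        raise EvaluationError("RMSE of an empty pair list is undefined")
    targets = np.array([p[0] for p in pairs], dtype=float)
    preds = np.array([p[1] for p in pairs], dtype=float)
    return float(np.sqrt(np.mean((targets - preds) ** 2)))


def aggregate(per_pp: dict[tuple, float]) -> EvaluationResult:
    """Summarize per-PP RMSEs keyed by (subject, meal_index, ph_minutes).

    Per-subject medians are taken over that subject's PPs; the cohort line is
    the median and [q1, q3] (linear interpolation between order statistics)
    over subject medians, per horizon.
    """
    if not per_pp:
        raise EvaluationError("nothing to aggregate")
    subjects = sorted({k[0] for k in per_pp})
    phs = sorted({k[2] for k in per_pp})
    per_subject: dict[tuple, float] = {}
    for subject in subjects:
        for ph in phs:
            values = sorted(
                v
                for (s, _meal, p), v in per_pp.items()
                if s == subject and p == ph
            )
            if values:
                per_subject[(subject, ph)] = float(np.median(values))
    cohort: dict[int, tuple[float, float, float]] = {}
    for ph in phs:
        meds = [v for (s, p), v in per_subject.items() if p == ph]
        if meds:
            q1, med, q3 = np.percentile(meds, [25, 50, 75])  # linear interpolation
            cohort[ph] = (float(med), float(q1), float(q3))
    return EvaluationResult(
        per_pp_rmse=dict(per_pp),
        per_subject_median=per_subject,
        cohort_median_iqr=cohort,
    )


def compare_methods(a, b, alpha: float = 0.05) -> tuple[str, float, bool]:
    """Normality-gated paired comparison of two methods' per-subject medians.

    Shapiro–Wilk at ``alpha`` on the paired differences gates the choice:
    accepted normality -> paired t-test; rejected -> Wilcoxon signed-rank.
    Returns ``(test_name, p_value, significant_at_alpha)``.  Identical
    vectors return ``("degenerate", 1.0, False)`` by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise EvaluationError("paired vectors must be 1-D and of equal length")
    if a.size < 3:
        raise EvaluationError("need at least 3 pairs")
    diffs = a - b
    if np.allclose(diffs, 0.0):
        return ("degenerate", 1.0, False)
    try:
        normal = stats.shapiro(diffs).pvalue > alpha
    except ValueError:  # e.g. constant non-zero differences
        normal = False
    if normal:
        name = "paired_t"
        p = float(stats.ttest_rel(a, b).pvalue)
    else:
        name = "wilcoxon"
        p = float(stats.wilcoxon(a, b).pvalue)
    if math.isnan(p):
        return ("degenerate", 1.0, False)
    return (name, p, p < alpha)
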
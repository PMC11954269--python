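"""Two-arm statistical comparison of costs and length of stay.

Every comparison row reports per-arm mean / sample SD / min / max, a Welch
two-sample t-test (unequal variances) and a Mann-Whitney U test (normal
approximation with tie correction), both two-sided.

Percent-difference conventions (documented per row type):

* activity, macro-group, category, case-time and LOS rows use
  (larger - smaller) / larger x 100 — the relative saving of the cheaper arm;
* the total row uses (first arm - second arm) / second arm x 100 — the
  relative excess of the first arm over the second, signed.

Degenerate zero-variance samples follow an explicit convention: p = 1 when
the means are equal (no evidence of a difference), and the smallest
positive float when the means differ with zero variance in both arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .costing import CostBreakdown, _value_table
from .errors import DomainError
from .pathway import Cohort, Patient, ProcessMap

_P_ZERO = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class ComparisonRow:
    """One row of a two-arm comparison table."""

    label: str
    arm_a: str
    arm_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    min_a: float
    min_b: float
    max_a: float
    max_b: float
    p_welch: float
    p_mannwhitney: float
    percent_difference: float


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return float(np.mean(x)), sd, float(np.min(x)), float(np.max(x))


def welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value with the zero-variance convention."""
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return 1.0 if np.mean(a) == np.mean(b) else _P_ZERO
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant samples
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value (asymptotic, tie-corrected)."""
    if np.var(a) == 0.0 and np.var(b) == 0.0 and np.mean(a) == np.mean(b):
        return 1.0  # every observation tied: no evidence either way
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on heavy ties
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def mannwhitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """The U statistic of the first sample (pairs won + half ties)."""
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").statistic)


def _percent_difference(mean_a: float, mean_b: float, label: str) -> float:
    if label == "total":
        if mean_b == 0:
            return float("nan")
        return (mean_a - mean_b) / mean_b * 100.0
    larger = max(mean_a, mean_b)
    if larger == 0:
        return 0.0
    return abs(mean_a - mean_b) / larger * 100.0


def _build_row(label: str, arm_a: str, arm_b: str, a: np.ndarray, b: np.ndarray) -> ComparisonRow:
    mean_a, sd_a, min_a, max_a = _moments(a)
    mean_b, sd_b, min_b, max_b = _moments(b)
    if a.size < 2 or b.size < 2:
        pw = pmw = float("nan")  # means still reported
    else:
        pw, pmw = welch_p(a, b), mannwhitney_p(a, b)
    return ComparisonRow(
        label=label, arm_a=arm_a, arm_b=arm_b, n_a=int(a.size), n_b=int(b.size),
        mean_a=mean_a, mean_b=mean_b, sd_a=sd_a, sd_b=sd_b,
        min_a=min_a, min_b=min_b, max_a=max_a, max_b=max_b,
        p_welch=pw, p_mannwhitney=pmw,
        percent_difference=_percent_difference(mean_a, mean_b, label),
    )


def compare_arms(
    breakdowns: Sequence[CostBreakdown],
    process_map: ProcessMap,
    grouping: str = "summary",
    arms: tuple[str, str] | None = None,
) -> list[ComparisonRow]:
    """Row-by-row two-arm comparison of per-patient costs.

    ``grouping`` is 'summary' (macro groups, console roll-up, case time,
    kit, total — the comparative cost table layout), 'activity',
    'macro_group' or 'category'.  With more than two arms pass the pair to
    compare explicitly.
    """
    if arms is None:
        if len(process_map.arms) != 2:
            raise DomainError("process map has more than two arms; pass arms=(a, b)")
        arms = (process_map.arms[0], process_map.arms[1])
    arm_a, arm_b = arms
    values = _value_table(breakdowns, process_map, grouping)
    labels = [c for c in values.columns if c not in ("patient_id", "arm")]
    rows = []
    for label in labels:
        a = values.loc[values["arm"] == arm_a, label].to_numpy(dtype=float)
        b = values.loc[values["arm"] == arm_b, label].to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            raise DomainError(f"comparison of {label!r}: both arms must be non-empty")
        rows.append(_build_row(label, arm_a, arm_b, a, b))
    return rows


@dataclass
class LearningCurveResult:
    """Early/late within-arm comparison around a proficiency case index."""

    arm: str
    split_after: int
    rows: list[ComparisonRow]  # arm_a = early phase, arm_b = late phase
    total_delta: float  # early mean total - late mean total (EUR saved)

    def delta(self, label: str) -> float:
        for row in self.rows:
            if row.label == label:
                return row.mean_a - row.mean_b
        raise KeyError(label)


def learning_curve_split(
    breakdowns: Sequence[CostBreakdown],
    cohort: Cohort,
    arm: str,
    split_after: int,
) -> LearningCurveResult:
    """Compare the first ``split_after`` cases of an arm against the rest.

    Cases are split on enrollment order (``case_index``): early cases have
    case_index <= split_after.  The total delta is the mean early total
    minus the mean late total — positive when proficiency reduced costs.
    """
    arm_patients = cohort.arm_patients(arm)
    if not 0 < split_after < len(arm_patients):
        raise DomainError(
            f"split_after={split_after} out of range for arm {arm!r} (n={len(arm_patients)})"
        )
    early_ids = {p.id for p in arm_patients if p.case_index <= split_after}
    late_ids = {p.id for p in arm_patients if p.case_index > split_after}
    values = _value_table(
        [bd for bd in breakdowns if bd.patient_id in early_ids | late_ids],
        cohort.process_map,
        "summary",
    )
    labels = [c for c in values.columns if c not in ("patient_id", "arm")]
    rows = []
    for label in labels:
        a = values.loc[values["patient_id"].isin(early_ids), label].to_numpy(dtype=float)
        b = values.loc[values["patient_id"].isin(late_ids), label].to_numpy(dtype=float)
        rows.append(_build_row(label, "early", "late", a, b))
    result = LearningCurveResult(arm=arm, split_after=split_after, rows=rows, total_delta=0.0)
    result.total_delta = result.delta("total")
    return result


def compare_los(
    patients: Sequence[Patient], arms: tuple[str, str]
) -> ComparisonRow | None:
    """Two-arm comparison of post-operative length of stay (days).

    Returns None with a warning when an arm has no recorded LOS (the row is
    omitted rather than fabricated).
    """
    arm_a, arm_b = arms
    a = np.array([p.postop_los_days for p in patients
                  if p.arm == arm_a and p.postop_los_days is not None], dtype=float)
    b = np.array([p.postop_los_days for p in patients
                  if p.arm == arm_b and p.postop_los_days is not None], dtype=float)
    if a.size == 0 or b.size == 0:
        warnings.warn("length-of-stay comparison omitted: no LOS recorded in at least one arm")
        return None
    return _build_row("postop_los_days", arm_a, arm_b, a, b)


def comparison_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a flat table (one row per label)."""
    return pd.DataFrame([r.__dict__ for r in rows])
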
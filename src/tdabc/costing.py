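"""Capacity cost rates and the per-patient cost equation.

The cost of a patient's procedure is

    C_pt = sum_i  beta_i * sum_j  X_{j|i} * CCR_j   +   y

where ``beta_i`` is the chrono-analysed duration of activity *i* (minutes),
``X_{j|i}`` the quantity of resource *j* staffed on activity *i*, ``CCR_j``
the capacity cost rate of resource *j* (EUR/min), and ``y`` the directly
attributed costs (the surgical kit).  The CCR divides a resource's period
cost by its practical capacity — the stated fraction (default 80%) of its
theoretical capacity.

All arithmetic is carried in full floating-point precision; rounding to
cents happens only in exported tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CrossReferenceError, DomainError
from .pathway import Activity, Cohort, Patient, ProcessMap, Resource

CATEGORIES = ("personnel", "platform", "operating_room", "consumable")


@dataclass(frozen=True)
class CapacityCostRate:
    """EUR per minute of practical capacity for one resource."""

    resource_id: str
    ccr: float


def compute_ccr(resource: Resource) -> CapacityCostRate:
    """CCR = period_cost / (theoretical_capacity x practical_fraction).

    Only defined for time-allocated (non-consumable) resources.
    """
    if resource.is_consumable:
        raise DomainError(
            f"resource {resource.id!r} is a consumable; it has no capacity cost rate"
        )
    if not resource.theoretical_capacity or resource.theoretical_capacity <= 0:
        raise DomainError(f"resource {resource.id!r} has no positive capacity")
    practical = resource.theoretical_capacity * resource.practical_fraction
    return CapacityCostRate(resource.id, resource.period_cost / practical)


def compute_rates(process_map: ProcessMap) -> dict[str, CapacityCostRate]:
    """CCRs for every non-consumable resource in the registry."""
    return {
        rid: compute_ccr(res)
        for rid, res in process_map.resources.items()
        if not res.is_consumable
    }


def staffed_rate(
    activity: Activity,
    rates: Mapping[str, CapacityCostRate],
    arm: str,
    process_map: ProcessMap | None = None,
) -> float:
    """Sum over staffed resources of quantity x CCR (EUR per minute of activity)."""
    total = 0.0
    for rid, qty in activity.resolved_staffing(arm).items():
        rate = rates.get(rid)
        if rate is None:
            raise CrossReferenceError(
                f"activity {activity.id!r}: no capacity cost rate for resource {rid!r}"
            )
        total += qty * rate.ccr
    return total


def activity_cost(
    activity: Activity,
    duration: float,
    rates: Mapping[str, CapacityCostRate],
    arm: str,
) -> float:
    """Time-allocated cost of one activity: duration x sum_j staffing_j x CCR_j."""
    return duration * staffed_rate(activity, rates, arm)


@dataclass
class CostBreakdown:
    """Per-patient cost decomposition.

    ``per_activity`` holds the time-allocated cost of each recorded
    activity; ``per_category`` folds the same euros by resource category and
    adds consumables (= ``direct_total``); ``total`` is C_pt.
    """

    patient_id: str
    arm: str
    per_activity: dict[str, float] = field(default_factory=dict)
    per_category: dict[str, float] = field(default_factory=dict)
    direct_total: float = 0.0
    total: float = 0.0

    @property
    def case_time_cost(self) -> float:
        """Time-allocated cost of the whole case (total minus consumables)."""
        return self.total - self.direct_total

    def macro_group_costs(self, process_map: ProcessMap) -> dict[str, float]:
        out: dict[str, float] = {}
        for act in process_map.activities:
            if act.id in self.per_activity:
                out[act.macro_group] = out.get(act.macro_group, 0.0) + self.per_activity[act.id]
        return out

    def console_cost(self, process_map: ProcessMap) -> float:
        return sum(
            self.per_activity.get(act.id, 0.0) for act in process_map.console_activities()
        )


def patient_cost(
    patient: Patient,
    durations: Mapping[str, float],
    process_map: ProcessMap,
    rates: Mapping[str, CapacityCostRate],
    exclude: Iterable[str] = (),
) -> CostBreakdown:
    """Evaluate the cost equation for one patient.

    ``durations`` maps activity id -> observed minutes; activities without a
    duration contribute nothing.  ``exclude`` drops named activities from
    the breakdown (used to keep the lymph-node-dissection step out of the
    main comparison while retaining it for the subgroup analysis).
    """
    excluded = set(exclude)
    bd = CostBreakdown(patient_id=patient.id, arm=patient.arm)
    per_category = {c: 0.0 for c in CATEGORIES}
    for act in process_map.activities:
        if act.id in excluded or act.id not in durations:
            continue
        duration = durations[act.id]
        cost = 0.0
        for rid, qty in act.resolved_staffing(patient.arm).items():
            rate = rates.get(rid)
            if rate is None:
                raise CrossReferenceError(
                    f"activity {act.id!r}: no capacity cost rate for resource {rid!r}"
                )
            part = duration * qty * rate.ccr
            cost += part
            per_category[process_map.resources[rid].category] += part
        bd.per_activity[act.id] = cost
    bd.direct_total = float(sum(patient.direct_costs.values()))
    per_category["consumable"] += bd.direct_total
    bd.per_category = per_category
    bd.total = sum(bd.per_activity.values()) + bd.direct_total
    return bd


def cost_cohort(
    cohort: Cohort,
    rates: Mapping[str, CapacityCostRate],
    exclude: Iterable[str] = (),
) -> list[CostBreakdown]:
    """Cost every patient of a validated cohort."""
    return [
        patient_cost(p, cohort.durations[p.id], cohort.process_map, rates, exclude)
        for p in cohort.patients
    ]


# ---------------------------------------------------------------------------
# tabular views


def breakdown_frame(
    breakdowns: Sequence[CostBreakdown], process_map: ProcessMap
) -> pd.DataFrame:
    """Tidy per-patient cost table.

    One row per (patient, activity) plus one ``__direct__`` row per patient
    carrying the consumable total; columns patient_id, arm, activity_id,
    macro_group, category ('time_allocated'/'consumable'), cost_eur.
    """
    groups = {a.id: a.macro_group for a in process_map.activities}
    rows = []
    for bd in breakdowns:
        for aid, cost in bd.per_activity.items():
            rows.append((bd.patient_id, bd.arm, aid, groups[aid], "time_allocated", cost))
        rows.append((bd.patient_id, bd.arm, "__direct__", "direct", "consumable", bd.direct_total))
    return pd.DataFrame(
        rows, columns=["patient_id", "arm", "activity_id", "macro_group", "category", "cost_eur"]
    )


def _value_table(
    breakdowns: Sequence[CostBreakdown],
    process_map: ProcessMap,
    grouping: str,
) -> pd.DataFrame:
    """Per-patient values of each row label under a grouping.

    grouping: 'activity' | 'macro_group' | 'category' | 'summary'.
    'summary' mirrors the comparative cost table: macro groups in map
    order, console roll-up, case time, kit (consumables) and total.
    """
    rows: list[dict] = []
    for bd in breakdowns:
        entry: dict = {"patient_id": bd.patient_id, "arm": bd.arm}
        if grouping == "activity":
            entry.update(bd.per_activity)
        elif grouping == "macro_group":
            entry.update(bd.macro_group_costs(process_map))
        elif grouping == "category":
            entry.update(bd.per_category)
        elif grouping == "summary":
            entry.update(bd.macro_group_costs(process_map))
            entry["surgery_console"] = bd.console_cost(process_map)
            entry["case_time"] = bd.case_time_cost
            entry["kit"] = bd.direct_total
            entry["total"] = bd.total
        else:
            raise DomainError(f"unknown grouping {grouping!r}")
        rows.append(entry)
    df = pd.DataFrame(rows).fillna(0.0)

    if grouping == "activity":
        order = [a for a in process_map.activity_ids if a in df.columns]
    elif grouping == "macro_group":
        order = [g for g in MACRO_ORDER if g in df.columns]
    elif grouping == "category":
        order = [c for c in CATEGORIES if c in df.columns]
    else:
        order = [g for g in MACRO_ORDER if g in df.columns]
        order += ["surgery_console", "case_time", "kit", "total"]
    return df[["patient_id", "arm", *order]]


MACRO_ORDER = ("room_setup", "anesthesia", "prep_positioning", "surgery", "other")


def cohort_summary(
    breakdowns: Sequence[CostBreakdown],
    process_map: ProcessMap,
    grouping: str = "summary",
) -> pd.DataFrame:
    """Mean / sample SD (n-1) / min / max per row label and arm.

    Returns a long table with columns label, arm, n, mean, sd, min, max.
    Single-patient groups report sd 0 and are flagged by n = 1; empty
    groups are omitted with a warning.
    """
    values = _value_table(breakdowns, process_map, grouping)
    labels = [c for c in values.columns if c not in ("patient_id", "arm")]
    rows = []
    for label in labels:
        for arm in process_map.arms:
            x = values.loc[values["arm"] == arm, label].to_numpy(dtype=float)
            if x.size == 0:
                warnings.warn(f"summary: no patients in arm {arm!r} for {label!r}; omitted")
                continue
            sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
            rows.append(
                {
                    "label": label,
                    "arm": arm,
                    "n": int(x.size),
                    "mean": float(np.mean(x)),
                    "sd": sd,
                    "min": float(np.min(x)),
                    "max": float(np.max(x)),
                }
            )
    return pd.DataFrame(rows, columns=["label", "arm", "n", "mean", "sd", "min", "max"])


def category_shares(
    category_totals: Mapping[str, Mapping[str, float]] | pd.DataFrame,
) -> pd.DataFrame:
    """Percentage of total cost per resource category and arm.

    Accepts either a mapping arm -> {category: mean EUR} or the output of
    :func:`cohort_summary` with grouping='category'.  Shares are reported to
    full precision; rounded to one decimal they sum to 100 +/- 0.1 per arm.
    """
    if isinstance(category_totals, pd.DataFrame):
        mapping: dict[str, dict[str, float]] = {}
        for row in category_totals.itertuples(index=False):
            mapping.setdefault(row.arm, {})[row.label] = row.mean
        category_totals = mapping

    rows = []
    for arm, cats in category_totals.items():
        total = sum(cats.values())
        if total <= 0:
            raise DomainError(f"arm {arm!r}: total cost must be > 0 to compute shares")
        for cat, value in cats.items():
            rows.append({"arm": arm, "category": cat, "cost_eur": value,
                         "share_pct": 100.0 * value / total})
    return pd.DataFrame(rows, columns=["arm", "category", "cost_eur", "share_pct"])
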
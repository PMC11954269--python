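"""Care-pathway data model and validated ingestion.

The costing engine operates on three structures:

* a **resource registry** — every costed input of the care pathway: personnel
  roles, the robotic platform, the operating room, and directly attributed
  consumables (the surgical kit).  Non-consumable resources carry a period
  cost and a theoretical capacity from which a capacity cost rate (CCR) is
  derived; consumables are attributed per patient and never time-allocated.
* a **process map** — the ordered list of micro-activities making up the
  surgical episode, each with a staffing map (resource id -> quantity, which
  may be fractional, e.g. 2.5 nurses) and a macro-group label used for
  roll-up tables.
* a **cohort** — patients plus chrono-analysis records (one observed duration
  per patient and activity, in minutes).

Arm-dependent resources
-----------------------
Arms are opaque labels and activities are shared between arms, but some
resources (the robotic platform and its rental fee) differ by arm.  A
staffing key may therefore contain the placeholder ``{arm}``, resolved
against the patient's arm at costing time; ``load_pathway`` checks that the
placeholder resolves to a registered resource for *every* arm of the map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import math

import pandas as pd
import yaml

from .errors import CrossReferenceError, ValidationError

RESOURCE_CATEGORIES = ("personnel", "platform", "operating_room", "consumable")
MACRO_GROUPS = ("room_setup", "anesthesia", "prep_positioning", "surgery", "other")

ARM_PLACEHOLDER = "{arm}"


@dataclass(frozen=True)
class Resource:
    """A costed input of the care pathway.

    ``period_cost`` is the cost (EUR) of the resource over one capacity
    period and ``theoretical_capacity`` the minutes the resource is
    nominally available in that period.  ``practical_fraction`` is the
    usable share of theoretical capacity after downtime and breaks
    (0.8 by convention).  Consumables carry no capacity: they are
    attributed directly per patient.
    """

    id: str
    name: str
    category: str
    period_cost: float = 0.0
    theoretical_capacity: float | None = None
    practical_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("resource id must be non-empty")
        if self.category not in RESOURCE_CATEGORIES:
            raise ValidationError(
                f"resource {self.id!r}: unknown category {self.category!r}; "
                f"expected one of {RESOURCE_CATEGORIES}"
            )
        if self.period_cost < 0:
            raise ValidationError(f"resource {self.id!r}: period_cost must be >= 0")
        if self.category == "consumable":
            if self.theoretical_capacity is not None:
                raise ValidationError(
                    f"consumable resource {self.id!r} must not declare a capacity"
                )
        else:
            if self.theoretical_capacity is None or self.theoretical_capacity <= 0:
                raise ValidationError(
                    f"resource {self.id!r}: theoretical_capacity must be > 0"
                )
            if not (0.0 < self.practical_fraction <= 1.0):
                raise ValidationError(
                    f"resource {self.id!r}: practical_fraction must lie in (0, 1]"
                )

    @property
    def is_consumable(self) -> bool:
        return self.category == "consumable"


@dataclass(frozen=True)
class Activity:
    """One micro-activity of the process map.

    ``staffing`` maps resource ids (possibly containing ``{arm}``) to the
    quantity of that resource present during the activity.  Quantities are
    continuous: 2.5 nurses means one nurse present half the time alongside
    two full-time nurses.  ``console_flag`` marks activities counted in the
    console-time roll-up.
    """

    id: str
    name: str
    macro_group: str
    staffing: Mapping[str, float] = field(default_factory=dict)
    console_flag: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("activity id must be non-empty")
        if self.macro_group not in MACRO_GROUPS:
            raise ValidationError(
                f"activity {self.id!r}: unknown macro_group {self.macro_group!r}; "
                f"expected one of {MACRO_GROUPS}"
            )
        object.__setattr__(self, "staffing", dict(self.staffing))
        for rid, qty in self.staffing.items():
            if not (qty > 0):
                raise ValidationError(
                    f"activity {self.id!r}: staffing quantity for {rid!r} must be > 0"
                )

    def resolved_staffing(self, arm: str) -> dict[str, float]:
        """Staffing with any ``{arm}`` placeholder substituted."""
        return {rid.replace(ARM_PLACEHOLDER, arm): q for rid, q in self.staffing.items()}


@dataclass
class ProcessMap:
    """Ordered activities, arm labels, and the resource registry."""

    activities: list[Activity]
    arms: list[str]
    resources: dict[str, Resource]

    def __post_init__(self) -> None:
        if not self.activities:
            raise ValidationError("process map must contain at least one activity")
        if not self.arms:
            raise ValidationError("process map must declare at least one arm")
        seen: set[str] = set()
        for act in self.activities:
            if act.id in seen:
                raise ValidationError(f"duplicate activity id {act.id!r}")
            seen.add(act.id)
        if len(set(self.arms)) != len(self.arms):
            raise ValidationError("arm labels must be unique")
        self._check_staffing_references()

    def _check_staffing_references(self) -> None:
        for act in self.activities:
            for raw in act.staffing:
                targets = (
                    [raw.replace(ARM_PLACEHOLDER, arm) for arm in self.arms]
                    if ARM_PLACEHOLDER in raw
                    else [raw]
                )
                for rid in targets:
                    res = self.resources.get(rid)
                    if res is None:
                        raise CrossReferenceError(
                            f"activity {act.id!r} staffs unknown resource {rid!r}"
                        )
                    if res.is_consumable:
                        raise CrossReferenceError(
                            f"activity {act.id!r} staffs consumable resource {rid!r}; "
                            "consumables are directly attributed, never time-allocated"
                        )

    @property
    def activity_ids(self) -> list[str]:
        return [a.id for a in self.activities]

    def activity(self, activity_id: str) -> Activity:
        for act in self.activities:
            if act.id == activity_id:
                return act
        raise CrossReferenceError(f"unknown activity {activity_id!r}")

    def console_activities(self) -> list[Activity]:
        return [a for a in self.activities if a.console_flag]

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "arms": list(self.arms),
            "resources": [
                {
                    "id": r.id,
                    "name": r.name,
                    "category": r.category,
                    "period_cost": r.period_cost,
                    **(
                        {}
                        if r.is_consumable
                        else {
                            "theoretical_capacity": r.theoretical_capacity,
                            "practical_fraction": r.practical_fraction,
                        }
                    ),
                }
                for r in self.resources.values()
            ],
            "activities": [
                {
                    "id": a.id,
                    "name": a.name,
                    "macro_group": a.macro_group,
                    "staffing": dict(a.staffing),
                    "console": a.console_flag,
                }
                for a in self.activities
            ],
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
        else:
            path.write_text(json.dumps(doc, indent=2))


@dataclass(frozen=True)
class Patient:
    """A patient-level observation unit.

    ``direct_costs`` maps consumable resource ids to EUR attributed directly
    to this patient's procedure (the y term of the cost equation).
    ``case_index`` is the enrollment order within the arm, used by the
    learning-curve split.  ``postop_los_days`` is the post-operative length
    of stay, kept outside the cost equation.
    """

    id: str
    arm: str
    lnd: bool = False
    case_index: int = 1
    direct_costs: Mapping[str, float] = field(default_factory=dict)
    postop_los_days: float | None = None

    def __post_init__(self) -> None:
        if self.case_index < 1:
            raise ValidationError(f"patient {self.id!r}: case_index must be >= 1")
        object.__setattr__(self, "direct_costs", dict(self.direct_costs))
        for rid, value in self.direct_costs.items():
            if value < 0:
                raise ValidationError(
                    f"patient {self.id!r}: direct cost for {rid!r} must be >= 0"
                )
        if self.postop_los_days is not None and self.postop_los_days < 0:
            raise ValidationError(f"patient {self.id!r}: postop_los_days must be >= 0")


@dataclass(frozen=True)
class ChronoRecord:
    """One timed observation: patient, activity, duration in minutes."""

    patient_id: str
    activity_id: str
    duration: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.duration):
            raise ValidationError(
                f"record ({self.patient_id!r}, {self.activity_id!r}): duration must be finite"
            )
        if self.duration < 0:
            raise ValidationError(
                f"record ({self.patient_id!r}, {self.activity_id!r}): duration must be >= 0"
            )


@dataclass
class Cohort:
    """A validated set of patients and chrono records.

    ``durations[pid][aid]`` gives the observed minutes; activities without a
    record simply contribute no time-allocated cost (they appear in the
    coverage report instead of aborting the run).
    """

    patients: list[Patient]
    records: list[ChronoRecord]
    process_map: ProcessMap

    def __post_init__(self) -> None:
        self.durations: dict[str, dict[str, float]] = {p.id: {} for p in self.patients}

    def patient(self, patient_id: str) -> Patient:
        for p in self.patients:
            if p.id == patient_id:
                return p
        raise CrossReferenceError(f"unknown patient {patient_id!r}")

    def arm_patients(self, arm: str) -> list[Patient]:
        return [p for p in self.patients if p.arm == arm]

    def coverage_report(self) -> pd.DataFrame:
        """Missing (patient, activity) pairs: loud, not fatal."""
        rows = [
            {"patient_id": p.id, "arm": p.arm, "activity_id": aid}
            for p in self.patients
            for aid in self.process_map.activity_ids
            if aid not in self.durations[p.id]
        ]
        return pd.DataFrame(rows, columns=["patient_id", "arm", "activity_id"])


def validate_chrono(
    records: Iterable[ChronoRecord],
    patients: Sequence[Patient],
    process_map: ProcessMap,
) -> Cohort:
    """Cross-check records against patients and the process map.

    Raises :class:`CrossReferenceError` for orphan patient or activity ids
    and :class:`ValidationError` for duplicate (patient, activity) pairs or
    invalid patient arms.  Missing activities are reported, not rejected.
    """
    ids = set()
    for p in patients:
        if p.id in ids:
            raise ValidationError(f"duplicate patient id {p.id!r}")
        ids.add(p.id)
        if p.arm not in process_map.arms:
            raise ValidationError(
                f"patient {p.id!r}: arm {p.arm!r} is not one of {process_map.arms}"
            )
        for rid in p.direct_costs:
            res = process_map.resources.get(rid)
            if res is None:
                raise CrossReferenceError(
                    f"patient {p.id!r}: direct cost refers to unknown resource {rid!r}"
                )
            if not res.is_consumable:
                raise ValidationError(
                    f"patient {p.id!r}: direct cost resource {rid!r} is not a consumable"
                )

    cohort = Cohort(list(patients), list(records), process_map)
    known_activities = set(process_map.activity_ids)
    for rec in cohort.records:
        if rec.patient_id not in cohort.durations:
            raise CrossReferenceError(f"record refers to unknown patient {rec.patient_id!r}")
        if rec.activity_id not in known_activities:
            raise CrossReferenceError(
                f"record for patient {rec.patient_id!r} refers to unknown "
                f"activity {rec.activity_id!r}"
            )
        per_patient = cohort.durations[rec.patient_id]
        if rec.activity_id in per_patient:
            raise ValidationError(
                f"duplicate record for ({rec.patient_id!r}, {rec.activity_id!r})"
            )
        per_patient[rec.activity_id] = rec.duration
    return cohort


# ---------------------------------------------------------------------------
# structured-text ingestion


def _build_resource(doc: Mapping) -> Resource:
    return Resource(
        id=str(doc["id"]),
        name=str(doc.get("name", doc["id"])),
        category=str(doc["category"]),
        period_cost=float(doc.get("period_cost", 0.0)),
        theoretical_capacity=(
            float(doc["theoretical_capacity"])
            if doc.get("theoretical_capacity") is not None
            else None
        ),
        practical_fraction=float(doc.get("practical_fraction", 0.8)),
    )


def load_pathway(source: str | Path | Mapping) -> ProcessMap:
    """Load a pathway configuration from YAML/JSON (path or mapping).

    Schema (top-level keys): ``arms`` — list of arm labels; ``resources`` —
    list of resource documents (id, name, category, period_cost,
    theoretical_capacity, practical_fraction); ``activities`` — ordered list
    of activity documents (id, name, macro_group, staffing, console).
    Deterministic ordering of the input document is preserved.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        text = Path(source).read_text()
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ValidationError("pathway config must be a mapping")
    for key in ("arms", "resources", "activities"):
        if key not in doc:
            raise ValidationError(f"pathway config is missing key {key!r}")

    resources: dict[str, Resource] = {}
    for rdoc in doc["resources"]:
        res = _build_resource(rdoc)
        if res.id in resources:
            raise ValidationError(f"duplicate resource id {res.id!r}")
        resources[res.id] = res

    activities = [
        Activity(
            id=str(adoc["id"]),
            name=str(adoc.get("name", adoc["id"])),
            macro_group=str(adoc["macro_group"]),
            staffing={str(k): float(v) for k, v in (adoc.get("staffing") or {}).items()},
            console_flag=bool(adoc.get("console", False)),
        )
        for adoc in doc["activities"]
    ]
    return ProcessMap(activities=activities, arms=[str(a) for a in doc["arms"]], resources=resources)


# ---------------------------------------------------------------------------
# tabular ingestion / export


def read_chrono_csv(path: str | Path) -> list[ChronoRecord]:
    """Read chrono records from CSV with headers patient_id, activity_id, duration_min."""
    df = pd.read_csv(
        path, dtype={"patient_id": str, "activity_id": str}, float_precision="round_trip"
    )
    missing = {"patient_id", "activity_id", "duration_min"} - set(df.columns)
    if missing:
        raise ValidationError(f"chrono CSV is missing columns {sorted(missing)}")
    return [
        ChronoRecord(row.patient_id, row.activity_id, float(row.duration_min))
        for row in df.itertuples(index=False)
    ]


def write_chrono_csv(records: Sequence[ChronoRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.patient_id, r.activity_id, r.duration) for r in records],
        columns=["patient_id", "activity_id", "duration_min"],
    ).to_csv(path, index=False)


def _kit_resource_for(arm: str, process_map: ProcessMap) -> str | None:
    """Consumable id carrying the kit cost: ``kit_<arm>`` if present, else ``kit``."""
    for candidate in (f"kit_{arm}", "kit"):
        res = process_map.resources.get(candidate)
        if res is not None and res.is_consumable:
            return candidate
    return None


def read_patients_csv(path: str | Path, process_map: ProcessMap) -> list[Patient]:
    """Read patients from CSV with headers
    patient_id, arm, lnd, case_index, kit_cost_eur, postop_los_days.

    The kit cost is attributed to the arm's kit consumable (``kit_<arm>``
    when registered, otherwise ``kit``).
    """
    df = pd.read_csv(
        path, dtype={"patient_id": str, "arm": str}, float_precision="round_trip"
    )
    missing = {"patient_id", "arm", "lnd", "case_index", "kit_cost_eur"} - set(df.columns)
    if missing:
        raise ValidationError(f"patients CSV is missing columns {sorted(missing)}")
    patients = []
    for row in df.itertuples(index=False):
        kit_id = _kit_resource_for(row.arm, process_map)
        kit_cost = float(row.kit_cost_eur)
        if kit_cost > 0 and kit_id is None:
            raise CrossReferenceError(
                f"patient {row.patient_id!r}: no kit consumable registered for arm {row.arm!r}"
            )
        los = getattr(row, "postop_los_days", None)
        los = None if los is None or pd.isna(los) else float(los)
        patients.append(
            Patient(
                id=row.patient_id,
                arm=row.arm,
                lnd=bool(row.lnd),
                case_index=int(row.case_index),
                direct_costs={kit_id: kit_cost} if kit_id is not None else {},
                postop_los_days=los,
            )
        )
    return patients


def write_patients_csv(patients: Sequence[Patient], path: str | Path) -> None:
    pd.DataFrame(
        [
            (
                p.id,
                p.arm,
                p.lnd,
                p.case_index,
                sum(p.direct_costs.values()),
                p.postop_los_days,
            )
            for p in patients
        ],
        columns=["patient_id", "arm", "lnd", "case_index", "kit_cost_eur", "postop_los_days"],
    ).to_csv(path, index=False)
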
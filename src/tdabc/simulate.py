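"""Synthetic-cohort generator.

Emulates two arms of chrono-analysed surgical cases: per-activity durations
drawn from truncated normal distributions whose *truncated* moments equal
the stated mean/sd (a small moment-matching solve recovers the underlying
location/scale), a constant per-arm kit cost, an optional lymph-node
dissection (LND) subgroup whose LND-activity duration is drawn separately,
an optional learning curve (multiplicative inflation of selected activities
for early cases), and per-arm length-of-stay draws.

Correlation structure
---------------------
Activities may declare a correlation ``group``.  Within one (patient,
group) a single uniform draw feeds every member activity through its own
truncated-normal quantile function (a comonotonic Gaussian-copula limit).
This emulates a per-case speed factor: a slow case is slow across all the
steps of a macro phase, which is what keeps phase-level cost dispersion at
realistic levels.  Ungrouped activities draw independently.

Determinism
-----------
One seed governs everything.  ``numpy.random.SeedSequence(seed)`` is
spawned once per arm (in arm order); within an arm, draws proceed patient
by patient in a fixed documented order (LND indicator, LND duration, LOS,
then one uniform per correlation group and one per ungrouped activity, in
process-map order).  The same spec and seed therefore yield bit-identical
cohorts on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

from .costing import CapacityCostRate, staffed_rate
from .errors import DomainError, ValidationError
from .pathway import ChronoRecord, Cohort, Patient, ProcessMap, validate_chrono


# ---------------------------------------------------------------------------
# moment-matched truncated normal


@lru_cache(maxsize=8192)
def truncnorm_underlying(
    mean: float, sd: float, lower: float = 0.0, upper: float = math.inf
) -> tuple[float, float]:
    """Location/scale of the normal whose [lower, upper] truncation has the
    requested mean and sd.

    Raises :class:`DomainError` when no such normal exists (e.g. a
    coefficient of variation >= 1 cannot be reached by a normal truncated
    at zero, whose tail limit is exponential with CV -> 1).
    """
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    if upper <= lower:
        raise ValidationError(f"infeasible truncation bounds [{lower}, {upper}]")
    if not (lower < mean < upper) and sd > 0:
        raise DomainError(f"target mean {mean} outside truncation bounds [{lower}, {upper}]")
    if sd == 0.0:
        return mean, 0.0
    if lower == -math.inf and upper == math.inf:
        return mean, sd

    def residuals(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return np.array([float(m) - mean, math.sqrt(float(v)) - sd])

    sol = optimize.least_squares(
        residuals, x0=np.array([mean, math.log(sd)]), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    mu, sigma = float(sol.x[0]), float(math.exp(sol.x[1]))
    if np.max(np.abs(sol.fun)) > 1e-6 * max(1.0, sd):
        raise DomainError(
            f"no truncated normal on [{lower}, {upper}] attains mean={mean}, sd={sd}"
        )
    return mu, sigma


def truncnorm_ppf(
    u: float | np.ndarray, mean: float, sd: float,
    lower: float = 0.0, upper: float = math.inf,
) -> float | np.ndarray:
    """Quantile of the moment-matched truncated normal.

    Evaluated directly as mu + sigma * Phi^-1(Phi(a) + u (Phi(b) - Phi(a)))
    with cached (mu, sigma); equivalent to the scipy distribution's ppf but
    without per-call distribution overhead.
    """
    mu, sigma = truncnorm_underlying(mean, sd, lower, upper)
    if sigma == 0.0:
        return mean if np.isscalar(u) else np.full_like(np.asarray(u, dtype=float), mean)
    cdf_a = ndtr((lower - mu) / sigma)
    cdf_b = ndtr((upper - mu) / sigma)
    return mu + sigma * ndtri(cdf_a + np.asarray(u) * (cdf_b - cdf_a))


# ---------------------------------------------------------------------------
# generator specification


@dataclass(frozen=True)
class DurationSpec:
    """Truncated-normal duration of one activity (minutes).

    ``group`` names an optional within-patient correlation group; member
    activities share one uniform draw per patient.
    """

    mean: float
    sd: float = 0.0
    lower: float = 0.0
    upper: float = math.inf
    group: str | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("duration sd must be >= 0")
        if self.lower < 0:
            raise ValidationError("duration truncation lower bound must be >= 0")
        if self.upper <= self.lower:
            raise ValidationError(
                f"infeasible truncation bounds [{self.lower}, {self.upper}]"
            )


@dataclass(frozen=True)
class LndSpec:
    """LND subgroup: probability of dissection and its extra operating time."""

    probability: float
    activity_id: str
    mean: float = 40.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValidationError("LND probability must lie in [0, 1]")
        if self.sd < 0:
            raise ValidationError("LND duration sd must be >= 0")


@dataclass(frozen=True)
class LearningCurveSpec:
    """Early-phase inflation of selected activities.

    With the default ``form='step'``, cases with case_index <=
    ``proficiency_after`` have the listed activities' mean (and sd) scaled
    by the corresponding factor; later cases are unaffected.  With
    ``form='linear'`` the factor decays linearly from its full value at
    case 1 to 1 at ``proficiency_after + 1``.
    """

    proficiency_after: int = 22
    mean_factors: Mapping[str, float] = field(default_factory=dict)
    sd_factors: Mapping[str, float] = field(default_factory=dict)
    form: str = "step"

    def __post_init__(self) -> None:
        if self.proficiency_after < 1:
            raise ValidationError("proficiency_after must be >= 1")
        if self.form not in ("step", "linear"):
            raise ValidationError("learning-curve form must be 'step' or 'linear'")
        object.__setattr__(self, "mean_factors", dict(self.mean_factors))
        object.__setattr__(self, "sd_factors", dict(self.sd_factors))

    def factors(self, activity_id: str, case_index: int) -> tuple[float, float]:
        fm = self.mean_factors.get(activity_id, 1.0)
        fs = self.sd_factors.get(activity_id, self.mean_factors.get(activity_id, 1.0))
        if case_index > self.proficiency_after:
            return 1.0, 1.0
        if self.form == "step":
            return fm, fs
        w = (self.proficiency_after - case_index + 1) / self.proficiency_after
        return 1.0 + (fm - 1.0) * w, 1.0 + (fs - 1.0) * w


@dataclass(frozen=True)
class ArmSpec:
    """One arm of the generator: durations, kit cost, LND, LOS, size."""

    arm: str
    n: int
    durations: Mapping[str, DurationSpec]
    kit_cost: float = 0.0
    kit_resource: str | None = None
    lnd: LndSpec | None = None
    learning_curve: LearningCurveSpec | None = None
    los_mean: float | None = None
    los_sd: float = 0.0
    los_lower: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("arm size n must be >= 1")
        if self.kit_cost < 0:
            raise ValidationError("kit cost must be >= 0")
        object.__setattr__(self, "durations", dict(self.durations))


@dataclass(frozen=True)
class GeneratorSpec:
    """Full two-(or k-)arm cohort specification."""

    arms: Sequence[ArmSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", tuple(self.arms))
        labels = [a.arm for a in self.arms]
        if len(set(labels)) != len(labels):
            raise ValidationError("arm labels in a generator spec must be unique")


# ---------------------------------------------------------------------------
# simulation


def _patient_id(arm: str, index: int) -> str:
    return f"{arm}-{index:03d}"


def simulate_cohort(
    spec: GeneratorSpec,
    process_map: ProcessMap,
    seed: int | None = None,
) -> Cohort:
    """Draw a synthetic cohort and validate it against the process map.

    Every activity listed in an arm's duration spec (plus the LND activity)
    receives a record for every patient — LND patients draw the LND
    duration, others record 0 minutes — so generated cohorts have complete
    chrono coverage by construction.
    """
    seed = spec.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    arm_seeds = root.spawn(len(spec.arms))

    patients: list[Patient] = []
    records: list[ChronoRecord] = []
    for arm_spec, arm_seed in zip(spec.arms, arm_seeds):
        rng = np.random.default_rng(arm_seed)
        # group -> member ids, preserving process-map activity order
        ordered = [aid for aid in process_map.activity_ids if aid in arm_spec.durations]
        ordered += [aid for aid in arm_spec.durations if aid not in set(ordered)]
        groups: dict[str, list[str]] = {}
        ungrouped: list[str] = []
        for aid in ordered:
            g = arm_spec.durations[aid].group
            if g is None:
                ungrouped.append(aid)
            else:
                groups.setdefault(g, []).append(aid)

        for case_index in range(1, arm_spec.n + 1):
            pid = _patient_id(arm_spec.arm, case_index)
            lnd_flag = False
            lnd_duration = 0.0
            if arm_spec.lnd is not None:
                lnd_flag = bool(rng.random() < arm_spec.lnd.probability)
                u_lnd = rng.random()  # drawn unconditionally: keeps streams aligned
                if arm_spec.lnd.sd > 0:
                    lnd_duration = float(
                        truncnorm_ppf(u_lnd, arm_spec.lnd.mean, arm_spec.lnd.sd)
                    )
                else:
                    lnd_duration = arm_spec.lnd.mean
            los = None
            if arm_spec.los_mean is not None:
                u_los = rng.random()
                los = float(
                    truncnorm_ppf(u_los, arm_spec.los_mean, arm_spec.los_sd,
                                  lower=arm_spec.los_lower)
                ) if arm_spec.los_sd > 0 else arm_spec.los_mean

            durations: dict[str, float] = {}
            for gname in groups:
                u = rng.random()
                for aid in groups[gname]:
                    durations[aid] = _draw(arm_spec, aid, case_index, u)
            for aid in ungrouped:
                u = rng.random()
                durations[aid] = _draw(arm_spec, aid, case_index, u)

            if arm_spec.lnd is not None:
                durations[arm_spec.lnd.activity_id] = lnd_duration if lnd_flag else 0.0

            direct = {}
            if arm_spec.kit_resource is not None:
                direct[arm_spec.kit_resource] = arm_spec.kit_cost
            patients.append(
                Patient(
                    id=pid, arm=arm_spec.arm, lnd=lnd_flag, case_index=case_index,
                    direct_costs=direct, postop_los_days=los,
                )
            )
            for aid in ordered:
                if aid in durations:
                    records.append(ChronoRecord(pid, aid, durations[aid]))
            if arm_spec.lnd is not None and arm_spec.lnd.activity_id not in set(ordered):
                records.append(
                    ChronoRecord(pid, arm_spec.lnd.activity_id,
                                 durations[arm_spec.lnd.activity_id])
                )
    return validate_chrono(records, patients, process_map)


def _draw(arm_spec: ArmSpec, activity_id: str, case_index: int, u: float) -> float:
    ds = arm_spec.durations[activity_id]
    mean, sd = ds.mean, ds.sd
    if arm_spec.learning_curve is not None:
        fm, fs = arm_spec.learning_curve.factors(activity_id, case_index)
        mean, sd = mean * fm, sd * fs
    if sd == 0.0:
        return mean
    return float(truncnorm_ppf(u, mean, sd, lower=ds.lower, upper=ds.upper))


# ---------------------------------------------------------------------------
# calibration from cost targets


def calibrate_durations_from_costs(
    cost_targets: Mapping[str, tuple[float, float]],
    process_map: ProcessMap,
    rates: Mapping[str, CapacityCostRate],
    arm: str,
    groups: Mapping[str, str] | None = None,
) -> dict[str, DurationSpec]:
    """Invert the activity-cost map: duration moments = cost moments / rate.

    ``cost_targets`` maps activity id -> (mean EUR, sd EUR).  The per-minute
    rate of an activity is its summed staffing x CCR for the given arm; a
    zero rate makes the inversion undefined.
    """
    groups = groups or {}
    out: dict[str, DurationSpec] = {}
    for aid, (mean_cost, sd_cost) in cost_targets.items():
        activity = process_map.activity(aid)
        rate = staffed_rate(activity, rates, arm)
        if rate <= 0:
            raise DomainError(
                f"activity {aid!r} has zero staffed cost rate; cannot calibrate durations"
            )
        out[aid] = DurationSpec(
            mean=mean_cost / rate, sd=sd_cost / rate, group=groups.get(aid)
        )
    return out


def with_platform_increment(
    base: Mapping[str, DurationSpec],
    increment: float,
    apportionment: Mapping[str, float] | None = None,
) -> dict[str, DurationSpec]:
    """Durations for a second platform: base plus a total time increment.

    The increment (minutes, default apportioned proportionally to baseline
    mean durations) models a platform that is slower overall by a stated
    total across all activities.  ``apportionment`` may override the
    proportional rule with explicit per-activity weights (summing to 1).
    """
    total = sum(ds.mean for ds in base.values())
    if apportionment is None:
        if total <= 0:
            raise DomainError("cannot apportion an increment over zero baseline time")
        apportionment = {aid: ds.mean / total for aid, ds in base.items()}
    else:
        s = sum(apportionment.values())
        if not math.isclose(s, 1.0, rel_tol=1e-9):
            raise ValidationError(f"apportionment weights must sum to 1 (got {s})")
    return {
        aid: replace(ds, mean=ds.mean + increment * apportionment.get(aid, 0.0))
        for aid, ds in base.items()
    }
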
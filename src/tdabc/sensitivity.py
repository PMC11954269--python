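"""Deterministic sensitivity suite on an arm-level affine cost model.

The model holds one baseline total per arm and a set of named parameters.
Each parameter belongs to one arm and enters that arm's total affinely:

    total_arm(v) = baseline_arm + coefficient x (v - baseline_value)

Parameter kinds map onto this uniformly: a kit cost has coefficient 1; a
per-case platform (rental) allocation has coefficient 1 (a relative change
in the annual fee is the same relative change in the per-case allocation,
by linearity of the capacity cost rate); an activity duration has
coefficient equal to the summed staffed CCRs of that activity (EUR/min).

The suite operates on baseline totals and coefficients — not re-simulated
cohorts — so every analysis is closed-form and exactly reproducible:

* one-way: each parameter swept to (1 +/- fraction) x baseline, tornado
  entries ordered by swing;
* threshold: the parameter value at which the two arm totals are equal;
* two-way frontier: the parity line in a (param_x, param_y) plane;
* scenario matrix: arm totals over a grid of relative changes in two
  parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CrossReferenceError, DomainError

DEFAULT_FRACTION = 0.30
PARITY_TOL = 1e-6


@dataclass(frozen=True)
class Parameter:
    """An affine cost-model parameter attached to one arm."""

    name: str
    arm: str
    baseline: float
    coefficient: float = 1.0
    unit: str = "EUR"


@dataclass
class CostModel:
    """Baseline arm totals plus affine parameters."""

    baselines: dict[str, float]
    parameters: dict[str, Parameter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.parameters.values():
            if p.arm not in self.baselines:
                raise CrossReferenceError(
                    f"parameter {p.name!r} refers to unknown arm {p.arm!r}"
                )

    def add(self, parameter: Parameter) -> None:
        if parameter.arm not in self.baselines:
            raise CrossReferenceError(
                f"parameter {parameter.name!r} refers to unknown arm {parameter.arm!r}"
            )
        self.parameters[parameter.name] = parameter

    def parameter(self, name: str) -> Parameter:
        try:
            return self.parameters[name]
        except KeyError:
            raise CrossReferenceError(f"unknown parameter {name!r}") from None

    def total(self, arm: str, values: Mapping[str, float] | None = None) -> float:
        """Arm total with any subset of parameters moved off baseline."""
        if arm not in self.baselines:
            raise CrossReferenceError(f"unknown arm {arm!r}")
        total = self.baselines[arm]
        if values:
            for name, v in values.items():
                p = self.parameter(name)
                if p.arm == arm:
                    total += p.coefficient * (v - p.baseline)
        return total

    def differential(
        self, arm_a: str, arm_b: str, values: Mapping[str, float] | None = None
    ) -> float:
        """total(arm_a) - total(arm_b) under the given parameter values."""
        return self.total(arm_a, values) - self.total(arm_b, values)


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the tornado diagram (cost differential at the two ends)."""

    parameter: str
    low_value: float   # differential at (1 - fraction) x baseline
    high_value: float  # differential at (1 + fraction) x baseline
    swing: float       # |high - low|


def one_way(
    model: CostModel,
    arm_a: str,
    arm_b: str,
    parameters: Sequence[str] | None = None,
    fraction: float = DEFAULT_FRACTION,
) -> list[TornadoEntry]:
    """One-way sensitivity of the cost differential (arm_a - arm_b).

    Each parameter is perturbed to (1 +/- fraction) of its baseline with
    all others held fixed.  Entries come back sorted by descending swing,
    ties broken lexicographically on the parameter name.
    """
    names = list(parameters) if parameters is not None else sorted(model.parameters)
    entries = []
    for name in names:
        p = model.parameter(name)
        low = model.differential(arm_a, arm_b, {name: (1.0 - fraction) * p.baseline})
        high = model.differential(arm_a, arm_b, {name: (1.0 + fraction) * p.baseline})
        entries.append(TornadoEntry(name, low, high, abs(high - low)))
    return sorted(entries, key=lambda e: (-e.swing, e.parameter))


@dataclass(frozen=True)
class ThresholdResult:
    """Parameter value at which the two arm totals are equal."""

    parameter: str
    parity_value: float
    feasible: bool


def threshold(model: CostModel, parameter: str, arm_a: str, arm_b: str) -> ThresholdResult:
    """Closed-form cost-parity solve for one affine parameter.

    The parity value is flagged infeasible when it would require a negative
    parameter value (costs and durations are non-negative) or when the
    parameter has no effect on the differential.
    """
    p = model.parameter(parameter)
    sign = 1.0 if p.arm == arm_a else -1.0
    slope = sign * p.coefficient
    diff0 = model.differential(arm_a, arm_b)
    if slope == 0.0:
        return ThresholdResult(parameter, float("nan"), feasible=False)
    value = p.baseline - diff0 / slope
    return ThresholdResult(parameter, value, feasible=value >= 0.0)


def threshold_bisect(
    evaluate: Callable[[float], float],
    lo: float,
    hi: float,
    tol: float = PARITY_TOL,
    max_iter: int = 200,
) -> float:
    """Bisection fallback for any monotone differential evaluator.

    ``evaluate`` returns the cost differential at a parameter value; the
    root must be bracketed by [lo, hi].
    """
    f_lo, f_hi = evaluate(lo), evaluate(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise DomainError("threshold_bisect: parity is not bracketed by [lo, hi]")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = evaluate(mid)
        if abs(f_mid) <= tol:
            return mid
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class FrontierLine:
    """Cost-parity line param_y = intercept + slope x param_x.

    ``cheaper_above`` names the arm that is cheaper for points above the
    line (param_y larger than parity).
    """

    param_x: str
    param_y: str
    intercept: float
    slope: float
    cheaper_above: str
    cheaper_below: str

    def parity_y(self, x: float) -> float:
        return self.intercept + self.slope * x


def two_way_frontier(
    model: CostModel, param_x: str, param_y: str, arm_a: str, arm_b: str
) -> FrontierLine:
    """Locus of (param_x, param_y) values with equal arm totals.

    Both parameters must carry a nonzero coefficient and sit in different
    arms (two parameters of the same arm shift the same total and admit no
    between-arm trade-off).
    """
    px, py = model.parameter(param_x), model.parameter(param_y)
    if px.coefficient == 0.0 or py.coefficient == 0.0:
        raise DomainError("two_way_frontier: both coefficients must be nonzero")
    if px.arm == py.arm:
        raise DomainError(
            "two_way_frontier: parameters belong to the same arm; the parity "
            "locus degenerates (no between-arm trade-off)"
        )
    sx = 1.0 if px.arm == arm_a else -1.0
    sy = 1.0 if py.arm == arm_a else -1.0
    diff0 = model.differential(arm_a, arm_b)
    # diff(x, y) = diff0 + sx cx (x - bx) + sy cy (y - by) = 0
    slope = -(sx * px.coefficient) / (sy * py.coefficient)
    intercept = py.baseline - diff0 / (sy * py.coefficient) - slope * px.baseline
    # above the line: y > parity  =>  diff has the sign of sy * cy
    above_sign = sy * py.coefficient
    cheaper_above = arm_b if above_sign > 0 else arm_a
    cheaper_below = arm_a if above_sign > 0 else arm_b
    return FrontierLine(param_x, param_y, intercept, slope, cheaper_above, cheaper_below)


def scenario_matrix(
    model: CostModel,
    arm: str,
    param_rows: str,
    param_cols: str,
    row_changes: Sequence[float] = (0.30, 0.20, 0.10, 0.0, -0.10, -0.20, -0.30),
    col_changes: Sequence[float] = (-0.30, -0.20, -0.10, 0.0, 0.10, 0.20, 0.30),
) -> pd.DataFrame:
    """Arm totals over a grid of relative changes in two parameters.

    Rows sweep ``param_rows`` (kit cost by convention, +30% at the top down
    to -30%), columns sweep ``param_cols`` (rental fee, -30% on the left up
    to +30%).  The (0, 0) node reproduces the baseline total exactly.
    """
    if not row_changes or not col_changes:
        raise DomainError("scenario_matrix: grids must be non-empty")
    pr, pc = model.parameter(param_rows), model.parameter(param_cols)
    grid = np.empty((len(row_changes), len(col_changes)))
    for i, dr in enumerate(row_changes):
        for j, dc in enumerate(col_changes):
            grid[i, j] = model.total(
                arm,
                {param_rows: (1.0 + dr) * pr.baseline, param_cols: (1.0 + dc) * pc.baseline},
            )
    index = pd.Index([f"{param_rows}{d:+.0%}" for d in row_changes], name=param_rows)
    columns = pd.Index([f"{param_cols}{d:+.0%}" for d in col_changes], name=param_cols)
    return pd.DataFrame(grid, index=index, columns=columns)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.parameter, e.low_value, e.high_value, e.swing) for e in entries],
        columns=["parameter", "diff_low_eur", "diff_high_eur", "swing_eur"],
    )
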
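"""Per-activity time equations.

Each activity's observed duration is modelled as a baseline (intercept)
plus additive indicator effects of patient-level covariates — here the
platform arm and whether lymph-node dissection (LND) was performed.  The
fit is ordinary least squares per activity, independently; an effect is
flagged significant when its two-sided p-value falls below the screening
threshold (0.05 by default, unadjusted).  Non-significant effects are
still reported, just flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CrossReferenceError
from .pathway import Cohort, Patient

SCREEN_ALPHA = 0.05


@dataclass(frozen=True)
class CovariateEffect:
    """One additive effect: minutes added when the indicator is active."""

    coefficient: float
    p_value: float
    std_error: float
    significant: bool
    conf_low: float = float("nan")
    conf_high: float = float("nan")


@dataclass
class TimeEquation:
    """intercept + sum of active covariate effects, in minutes.

    Effect names follow ``arm[<label>]`` for platform indicators (the first
    arm of the map is the reference level) and the bare field name for
    boolean covariates such as ``lnd``.
    """

    activity_id: str
    intercept: float
    effects: dict[str, CovariateEffect] = field(default_factory=dict)
    intercept_se: float = float("nan")


def _design_matrix(
    patients: Sequence[Patient], covariates: Sequence[str], reference_arm: str
) -> pd.DataFrame:
    cols: dict[str, list[float]] = {}
    for cov in covariates:
        if cov == "arm":
            arms = sorted({p.arm for p in patients})
            for arm in arms:
                if arm == reference_arm:
                    continue
                cols[f"arm[{arm}]"] = [1.0 if p.arm == arm else 0.0 for p in patients]
        elif cov == "lnd":
            cols["lnd"] = [1.0 if p.lnd else 0.0 for p in patients]
        else:
            raise CrossReferenceError(f"unknown covariate {cov!r}")
    return pd.DataFrame(cols, index=[p.id for p in patients])


def fit_time_equations(
    cohort: Cohort,
    covariates: Sequence[str] = ("arm", "lnd"),
    alpha: float = SCREEN_ALPHA,
) -> dict[str, TimeEquation]:
    """OLS fit of duration on indicator covariates, one model per activity.

    Covariates constant in the cohort (a single arm, no LND patients) make
    the design singular for that term; the term is skipped with a warning.
    Activities with no recorded durations are skipped entirely.
    """
    reference_arm = cohort.process_map.arms[0]
    patients = cohort.patients
    design_all = _design_matrix(patients, covariates, reference_arm)

    # drop constant columns (singular design) once, with a warning
    kept = []
    for col in design_all.columns:
        if design_all[col].nunique() < 2:
            warnings.warn(f"time equations: covariate {col!r} is constant; effect skipped")
        else:
            kept.append(col)
    design_all = design_all[kept]

    equations: dict[str, TimeEquation] = {}
    for act in cohort.process_map.activities:
        y, rows = [], []
        for i, p in enumerate(patients):
            d = cohort.durations[p.id].get(act.id)
            if d is not None:
                y.append(d)
                rows.append(i)
        if not rows:
            warnings.warn(f"time equations: no records for activity {act.id!r}; skipped")
            continue
        y_arr = np.asarray(y, dtype=float)
        X = design_all.iloc[rows]
        # re-check constancy within the subset actually observed
        usable = [c for c in X.columns if X[c].nunique() >= 2]
        X = X[usable]
        exog = sm.add_constant(X, has_constant="add")
        res = sm.OLS(y_arr, exog).fit()
        conf = res.conf_int(alpha=0.05)
        effects = {}
        for name in usable:
            effects[name] = CovariateEffect(
                coefficient=float(res.params[name]),
                p_value=float(res.pvalues[name]),
                std_error=float(res.bse[name]),
                significant=bool(res.pvalues[name] < alpha),
                conf_low=float(conf.loc[name, 0]),
                conf_high=float(conf.loc[name, 1]),
            )
        equations[act.id] = TimeEquation(
            activity_id=act.id,
            intercept=float(res.params["const"]),
            effects=effects,
            intercept_se=float(res.bse["const"]),
        )
    return equations


def predict_duration(equation: TimeEquation, patient: Patient) -> float:
    """Deterministic evaluation of a fitted time equation for one patient.

    Negative predictions are clipped to zero with a warning (durations are
    non-negative by construction; a negative sum signals extrapolation
    outside the observed covariate space).
    """
    value = equation.intercept
    for name, eff in equation.effects.items():
        if name.startswith("arm[") and name.endswith("]"):
            if patient.arm == name[4:-1]:
                value += eff.coefficient
        elif name == "lnd":
            if patient.lnd:
                value += eff.coefficient
        else:
            raise CrossReferenceError(f"unknown covariate {name!r} in time equation")
    if value < 0:
        warnings.warn(
            f"time equation {equation.activity_id!r}: negative prediction "
            f"{value:.2f} min clipped to 0"
        )
        return 0.0
    return value


def equations_frame(equations: Mapping[str, TimeEquation]) -> pd.DataFrame:
    """Exportable table: activity_id, term, estimate_min, std_error, p_value, significant."""
    rows = []
    for eq in equations.values():
        rows.append((eq.activity_id, "intercept", eq.intercept, eq.intercept_se, np.nan, True))
        for name, eff in eq.effects.items():
            rows.append(
                (eq.activity_id, name, eff.coefficient, eff.std_error, eff.p_value, eff.significant)
            )
    return pd.DataFrame(
        rows,
        columns=["activity_id", "term", "estimate_min", "std_error", "p_value", "significant"],
    )
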
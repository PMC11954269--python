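"""Shared fixtures: a tiny two-arm pathway for unit tests and a seeded
trial-scale simulated cohort reused across the comparison tests."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import tdabc
from tdabc import fixtures

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


TINY_CONFIG = {
    "arms": ["alpha", "beta"],
    "resources": [
        {"id": "nurse", "name": "Nurse", "category": "personnel",
         "period_cost": 48000, "theoretical_capacity": 100000,
         "practical_fraction": 0.8},  # CCR 0.6 EUR/min
        {"id": "surgeon", "name": "Surgeon", "category": "personnel",
         "period_cost": 240000, "theoretical_capacity": 100000,
         "practical_fraction": 0.8},  # CCR 3.0 EUR/min
        {"id": "kit", "name": "Kit", "category": "consumable"},
    ],
    "activities": [
        {"id": "prep", "name": "Prep", "macro_group": "prep_positioning",
         "staffing": {"nurse": 2}},
        {"id": "surgery", "name": "Surgery", "macro_group": "surgery",
         "staffing": {"nurse": 2, "surgeon": 1}, "console": True},
    ],
}


@pytest.fixture()
def tiny_map() -> tdabc.ProcessMap:
    return tdabc.load_pathway(TINY_CONFIG)


@pytest.fixture()
def tiny_rates(tiny_map):
    return tdabc.compute_rates(tiny_map)


@pytest.fixture(scope="session")
def reference_map() -> tdabc.ProcessMap:
    return fixtures.reference_pathway()


@pytest.fixture(scope="session")
def reference_rates(reference_map):
    return tdabc.compute_rates(reference_map)


@pytest.fixture(scope="session")
def trial_cohort(reference_map, reference_rates):
    """One seeded 50+50 cohort from the calibrated generator."""
    spec = fixtures.reference_generator_spec(
        process_map=reference_map, rates=reference_rates, seed=20230310
    )
    return tdabc.simulate_cohort(spec, reference_map)


@pytest.fixture(scope="session")
def trial_breakdowns(trial_cohort, reference_rates):
    """Main-analysis cost breakdowns (LND step excluded, analysed separately)."""
    return tdabc.cost_cohort(trial_cohort, reference_rates, exclude=("lnd",))
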
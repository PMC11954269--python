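"""Synthetic-cohort generator: determinism, moments, calibration."""

from __future__ import annotations

import io
import math

import numpy as np
import pytest

import tdabc
from tdabc import DomainError, ValidationError
from tdabc.simulate import (
    ArmSpec,
    DurationSpec,
    GeneratorSpec,
    LearningCurveSpec,
    LndSpec,
    truncnorm_ppf,
    truncnorm_underlying,
)

FLAT_CONFIG = {
    "arms": ["a", "b"],
    "resources": [
        {"id": "nurse", "category": "personnel", "period_cost": 48000,
         "theoretical_capacity": 100000}
    ],
    "activities": [
        {"id": "prep", "macro_group": "prep_positioning", "staffing": {"nurse": 2}},
        {"id": "surgery", "macro_group": "surgery", "staffing": {"nurse": 2}},
    ],
}


@pytest.fixture()
def flat_map():
    return tdabc.load_pathway(FLAT_CONFIG)


class TestTruncatedNormal:
    @pytest.mark.parametrize(
        "mean, sd, lower", [(100.0, 20.0, 0.0), (15.0, 12.0, 0.0), (5.0, 4.0, 0.0)]
    )
    def test_moment_matching(self, mean, sd, lower):
        """The truncated distribution itself carries the stated moments,
        even when truncation at zero bites."""
        u = (np.arange(200_000) + 0.5) / 200_000
        x = truncnorm_ppf(u, mean, sd, lower=lower)
        assert np.min(x) >= lower
        assert np.mean(x) == pytest.approx(mean, rel=1e-3)
        assert np.std(x) == pytest.approx(sd, rel=5e-3)

    def test_unbounded_case_is_the_normal_itself(self):
        mu, sigma = truncnorm_underlying(10.0, 2.0, -math.inf, math.inf)
        assert (mu, sigma) == (10.0, 2.0)

    def test_infeasible_moments_rejected(self):
        # CV >= 1 is unreachable for a normal truncated at zero
        with pytest.raises(DomainError):
            truncnorm_underlying(10.0, 12.0, 0.0)

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ValidationError):
            DurationSpec(mean=10.0, sd=1.0, lower=5.0, upper=4.0)


class TestSimulateCohort:
    def _spec(self, sd=5.0, seed=42, group=None, **kwargs):
        durations = {
            "prep": DurationSpec(30.0, sd, group=group),
            "surgery": DurationSpec(110.0, sd, group=group),
        }
        return GeneratorSpec(
            arms=[ArmSpec("a", 20, durations, **kwargs),
                  ArmSpec("b", 20, durations, **kwargs)],
            seed=seed,
        )

    def test_zero_sd_reproduces_means_exactly(self, flat_map):
        cohort = tdabc.simulate_cohort(self._spec(sd=0.0), flat_map)
        for p in cohort.patients:
            assert cohort.durations[p.id] == {"prep": 30.0, "surgery": 110.0}

    def test_same_seed_bit_identical_csv(self, flat_map):
        outs = []
        for _ in range(2):
            cohort = tdabc.simulate_cohort(self._spec(), flat_map)
            buf = io.StringIO()
            tdabc.write_chrono_csv(cohort.records, buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_different_seed_differs(self, flat_map):
        c1 = tdabc.simulate_cohort(self._spec(seed=1), flat_map)
        c2 = tdabc.simulate_cohort(self._spec(seed=2), flat_map)
        assert c1.durations != c2.durations

    def test_case_index_assigned_in_draw_order(self, flat_map):
        cohort = tdabc.simulate_cohort(self._spec(), flat_map)
        for arm in ("a", "b"):
            assert [p.case_index for p in cohort.arm_patients(arm)] == list(range(1, 21))

    def test_durations_non_negative(self, flat_map):
        spec = self._spec(sd=25.0, seed=9)  # heavy dispersion: truncation active
        cohort = tdabc.simulate_cohort(spec, flat_map)
        assert all(r.duration >= 0 for r in cohort.records)

    def test_kit_cost_constant_within_arm(self, trial_cohort):
        for arm, kit in (("davinci", 3498.03), ("hugo", 1586.00)):
            costs = {sum(p.direct_costs.values()) for p in trial_cohort.arm_patients(arm)}
            assert costs == {kit}

    def test_lnd_patients_get_lnd_minutes_others_zero(self, trial_cohort):
        for p in trial_cohort.patients:
            d = trial_cohort.durations[p.id]["lnd"]
            if p.lnd:
                assert d > 0
            else:
                assert d == 0.0

    def test_comonotonic_group_shares_case_speed(self, flat_map):
        """Within a correlation group, a patient slow on one step is slow on
        the others: correlation 1 across member activities."""
        spec = self._spec(sd=10.0, group="phase", seed=3)
        cohort = tdabc.simulate_cohort(spec, flat_map)
        prep = np.array([cohort.durations[p.id]["prep"] for p in cohort.patients])
        surg = np.array([cohort.durations[p.id]["surgery"] for p in cohort.patients])
        assert np.corrcoef(prep, surg)[0, 1] > 0.99

    def test_learning_curve_inflates_early_cases_only(self, flat_map):
        lc = LearningCurveSpec(proficiency_after=10, mean_factors={"surgery": 1.5})
        spec = GeneratorSpec(
            arms=[ArmSpec("a", 30, {"surgery": DurationSpec(100.0, 0.0)},
                          learning_curve=lc)],
            seed=0,
        )
        pm = tdabc.load_pathway({**FLAT_CONFIG, "arms": ["a"]})
        cohort = tdabc.simulate_cohort(spec, pm)
        for p in cohort.patients:
            expected = 150.0 if p.case_index <= 10 else 100.0
            assert cohort.durations[p.id]["surgery"] == pytest.approx(expected)


class TestCalibration:
    def test_duration_moments_are_cost_moments_over_rate(self, flat_map):
        rates = tdabc.compute_rates(flat_map)  # every activity at 1.2 EUR/min
        specs = tdabc.calibrate_durations_from_costs(
            {"prep": (50.0 * 1.2, 0.0), "surgery": (60.0, 12.0)}, flat_map, rates, "a"
        )
        assert specs["prep"].mean == pytest.approx(50.0)
        assert specs["prep"].sd == 0.0
        assert specs["surgery"].mean == pytest.approx(50.0)
        assert specs["surgery"].sd == pytest.approx(10.0)

    def test_zero_rate_rejected(self, flat_map):
        rates = {"nurse": tdabc.CapacityCostRate("nurse", 0.0)}
        with pytest.raises(DomainError):
            tdabc.calibrate_durations_from_costs(
                {"prep": (10.0, 1.0)}, flat_map, rates, "a"
            )

    def test_fixture_mean_total_converges_to_published(self, reference_map, reference_rates):
        """Law of large numbers: at 5,000 patients per arm the simulated da
        Vinci mean total lands within 1% of the published 4,979.21 EUR."""
        from tdabc import fixtures

        spec = fixtures.reference_generator_spec(
            n=5000, process_map=reference_map, rates=reference_rates, seed=77
        )
        cohort = tdabc.simulate_cohort(spec, reference_map)
        bds = tdabc.cost_cohort(cohort, reference_rates, exclude=("lnd",))
        totals = [bd.total for bd in bds if bd.arm == "davinci"]
        assert np.mean(totals) == pytest.approx(4979.21, rel=0.01)

    def test_replicate_means_unbiased(self, reference_map, reference_rates):
        """Across replicates the simulated macro-group cost means are
        unbiased for the calibration targets (|bias| < 2 SE)."""
        from tdabc import fixtures

        n_rep = 40
        means = {"room_setup": [], "anesthesia": []}
        for seed in range(n_rep):
            spec = fixtures.reference_generator_spec(
                process_map=reference_map, rates=reference_rates, seed=5000 + seed
            )
            cohort = tdabc.simulate_cohort(spec, reference_map)
            bds = tdabc.cost_cohort(cohort, reference_rates, exclude=("lnd",))
            summ = tdabc.cohort_summary(bds, reference_map, "macro_group")
            for label in means:
                means[label].append(
                    summ[(summ.label == label) & (summ.arm == "davinci")]["mean"].iloc[0]
                )
        for label, (target, *_rest) in (
            ("room_setup", fixtures.MACRO_COSTS["davinci"]["room_setup"]),
            ("anesthesia", fixtures.MACRO_COSTS["davinci"]["anesthesia"]),
        ):
            x = np.array(means[label])
            se = x.std(ddof=1) / np.sqrt(n_rep)
            assert abs(x.mean() - target) < 2 * se, label


def test_end_to_end_orderings_hold_across_replicates(reference_map, reference_rates):
    """Generator -> costing -> comparison reproduces the qualitative result
    in essentially every trial-scale replicate: the da Vinci arm costs more
    in total but less in case time."""
    from tdabc import fixtures

    ok = 0
    n_rep = 30
    for seed in range(n_rep):
        spec = fixtures.reference_generator_spec(
            process_map=reference_map, rates=reference_rates, seed=300_000 + seed
        )
        cohort = tdabc.simulate_cohort(spec, reference_map)
        bds = tdabc.cost_cohort(cohort, reference_rates, exclude=("lnd",))
        dv = [b for b in bds if b.arm == "davinci"]
        hugo = [b for b in bds if b.arm == "hugo"]
        total_ok = np.mean([b.total for b in dv]) > np.mean([b.total for b in hugo])
        case_ok = np.mean([b.case_time_cost for b in dv]) < np.mean(
            [b.case_time_cost for b in hugo]
        )
        ok += total_ok and case_ok
    assert ok == n_rep
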
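"""Costing engine: CCRs, the cost equation, conservation and oracle checks."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tdabc
from tdabc import CapacityCostRate, DomainError
from tdabc.costing import staffed_rate


class TestCapacityCostRate:
    def test_worked_example(self):
        res = tdabc.Resource("or", "OR", "operating_room",
                             period_cost=96_000, theoretical_capacity=200_000)
        assert tdabc.compute_ccr(res).ccr == pytest.approx(0.60)

    def test_zero_cost_gives_zero_rate(self):
        res = tdabc.Resource("r", "R", "personnel",
                             period_cost=0, theoretical_capacity=1000)
        assert tdabc.compute_ccr(res).ccr == 0.0

    def test_full_practical_fraction_is_identity(self):
        res = tdabc.Resource("r", "R", "personnel", period_cost=500,
                             theoretical_capacity=1000, practical_fraction=1.0)
        assert tdabc.compute_ccr(res).ccr == pytest.approx(500 / 1000)

    def test_consumable_has_no_rate(self):
        kit = tdabc.Resource("kit", "Kit", "consumable")
        with pytest.raises(DomainError, match="consumable"):
            tdabc.compute_ccr(kit)


class TestActivityCost:
    RATES = {"nurse": CapacityCostRate("nurse", 1.0),
             "surgeon": CapacityCostRate("surgeon", 3.0)}

    def _activity(self, staffing):
        return tdabc.Activity("act", "Act", "surgery", staffing=staffing)

    def test_zero_duration_costs_nothing(self):
        act = self._activity({"nurse": 2})
        assert tdabc.activity_cost(act, 0.0, self.RATES, "a") == 0.0

    def test_staffing_times_rate(self):
        act = self._activity({"nurse": 2, "surgeon": 1})
        assert tdabc.activity_cost(act, 10.0, self.RATES, "a") == pytest.approx(50.0)

    @given(beta=st.floats(0, 500), ccr=st.floats(0, 10))
    def test_fractional_staffing(self, beta, ccr):
        # 2.5 nurses on prep-and-positioning: cost = 2.5 x beta x CCR
        act = self._activity({"nurse": 2.5})
        rates = {"nurse": CapacityCostRate("nurse", ccr)}
        assert tdabc.activity_cost(act, beta, rates, "a") == pytest.approx(2.5 * beta * ccr)

    def test_missing_rate_names_resource(self):
        act = self._activity({"surgeon": 1})
        with pytest.raises(tdabc.CrossReferenceError, match="surgeon"):
            tdabc.activity_cost(act, 1.0, {}, "a")


class TestPatientCost:
    def test_no_records_no_direct_cost_is_zero(self, tiny_map, tiny_rates):
        p = tdabc.Patient("p", "alpha")
        bd = tdabc.patient_cost(p, {}, tiny_map, tiny_rates)
        assert bd.total == 0.0 and bd.per_activity == {}

    def test_one_activity_plus_direct(self, tiny_map):
        # surgery staffed at summed rate 5 EUR/min: 10 min x 5 + 100 = 150
        rates = {"nurse": CapacityCostRate("nurse", 1.0),
                 "surgeon": CapacityCostRate("surgeon", 3.0)}
        p = tdabc.Patient("p", "alpha", direct_costs={"kit": 100.0})
        bd = tdabc.patient_cost(p, {"surgery": 10.0}, tiny_map, rates)
        assert bd.total == pytest.approx(150.0)
        assert bd.direct_total == pytest.approx(100.0)
        assert bd.per_category["consumable"] == pytest.approx(100.0)

    def test_conservation(self, trial_breakdowns):
        """Category, activity and direct euros all add to the same total."""
        for bd in trial_breakdowns:
            total = bd.total
            assert sum(bd.per_category.values()) == pytest.approx(total, rel=1e-12)
            assert sum(bd.per_activity.values()) + bd.direct_total == pytest.approx(
                total, rel=1e-12
            )

    @given(lam=st.floats(0.0, 20.0))
    def test_linearity_in_durations(self, tiny_map, tiny_rates, lam):
        p = tdabc.Patient("p", "beta", direct_costs={"kit": 77.0})
        base = {"prep": 12.0, "surgery": 55.0}
        bd1 = tdabc.patient_cost(p, base, tiny_map, tiny_rates)
        bd2 = tdabc.patient_cost(
            p, {k: lam * v for k, v in base.items()}, tiny_map, tiny_rates
        )
        assert bd2.case_time_cost == pytest.approx(lam * bd1.case_time_cost, abs=1e-9)
        assert bd2.direct_total == bd1.direct_total

    def test_exclusion_drops_activity_cost(self, tiny_map, tiny_rates):
        p = tdabc.Patient("p", "alpha")
        full = tdabc.patient_cost(p, {"prep": 10, "surgery": 10}, tiny_map, tiny_rates)
        part = tdabc.patient_cost(
            p, {"prep": 10, "surgery": 10}, tiny_map, tiny_rates, exclude=("surgery",)
        )
        assert "surgery" not in part.per_activity
        assert part.total == pytest.approx(full.total - full.per_activity["surgery"])


@st.composite
def small_instances(draw):
    """Random cohorts of <= 5 patients and <= 3 activities on <= 3 resources."""
    n_res = draw(st.integers(1, 3))
    n_act = draw(st.integers(1, 3))
    n_pat = draw(st.integers(1, 5))
    money = st.floats(0, 1000)
    resources = [
        {"id": f"r{i}", "category": "personnel",
         "period_cost": draw(money), "theoretical_capacity": draw(st.floats(100, 1e5)),
         "practical_fraction": draw(st.floats(0.1, 1.0))}
        for i in range(n_res)
    ]
    activities = [
        {"id": f"a{i}", "macro_group": "other",
         "staffing": {f"r{j}": draw(st.floats(0.1, 4)) for j in range(n_res)}}
        for i in range(n_act)
    ]
    cfg = {"arms": ["x"], "resources": resources + [{"id": "kit", "category": "consumable"}],
           "activities": activities}
    durations = [
        {f"a{i}": draw(st.floats(0, 300)) for i in range(n_act) if draw(st.booleans())}
        for _ in range(n_pat)
    ]
    directs = [draw(money) for _ in range(n_pat)]
    return cfg, durations, directs


class TestBruteForceOracle:
    @given(instance=small_instances())
    def test_matches_triple_loop_accumulation(self, instance):
        """Engine totals equal an independent sum over (patient, activity,
        resource) triples built straight from the configuration."""
        cfg, durations, directs = instance
        pm = tdabc.load_pathway(cfg)
        rates = tdabc.compute_rates(pm)
        for k, (durs, y) in enumerate(zip(durations, directs)):
            patient = tdabc.Patient(f"p{k}", "x", direct_costs={"kit": y})
            bd = tdabc.patient_cost(patient, durs, pm, rates)
            expected = y
            for adoc in cfg["activities"]:
                if adoc["id"] not in durs:
                    continue
                for rdoc in cfg["resources"]:
                    if rdoc["id"] in adoc["staffing"]:
                        ccr = rdoc["period_cost"] / (
                            rdoc["theoretical_capacity"] * rdoc["practical_fraction"]
                        )
                        expected += durs[adoc["id"]] * adoc["staffing"][rdoc["id"]] * ccr
            assert bd.total == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestCohortSummary:
    def test_single_patient_flagged(self, tiny_map, tiny_rates):
        p = tdabc.Patient("p", "alpha", direct_costs={"kit": 10.0})
        bd = tdabc.patient_cost(p, {"prep": 10.0}, tiny_map, tiny_rates)
        with pytest.warns(UserWarning):  # beta arm empty: omitted loudly
            summ = tdabc.cohort_summary([bd], tiny_map, "summary")
        row = summ[(summ.label == "total") & (summ.arm == "alpha")].iloc[0]
        assert row["n"] == 1 and row["sd"] == 0.0

    def test_constant_kit_cost_has_zero_sd(self, trial_breakdowns, reference_map):
        summ = tdabc.cohort_summary(trial_breakdowns, reference_map, "summary")
        kit = summ[summ.label == "kit"]
        assert (kit["sd"] == 0.0).all()
        assert set(kit["mean"].round(2)) == {3498.03, 1586.00}

    def test_sample_sd_uses_n_minus_one(self, tiny_map, tiny_rates):
        values = [10.0, 20.0, 40.0]
        bds = [
            tdabc.patient_cost(
                tdabc.Patient(f"p{i}", "alpha"), {"prep": v}, tiny_map, tiny_rates
            )
            for i, v in enumerate(values)
        ]
        with pytest.warns(UserWarning):
            summ = tdabc.cohort_summary(bds, tiny_map, "summary")
        row = summ[(summ.label == "total") & (summ.arm == "alpha")].iloc[0]
        expected = np.std([1.2 * v for v in values], ddof=1)  # prep rate 1.2 EUR/min
        assert row["sd"] == pytest.approx(expected)

    def test_means_track_generator_targets(self, trial_breakdowns, reference_map):
        """Simulated per-group means stay within 3 standard errors of the
        calibration targets (CLT bound on the generator's own parameters)."""
        from tdabc.fixtures import CASE_TIME_COST, MACRO_COSTS, TOTAL_COST

        summ = tdabc.cohort_summary(trial_breakdowns, reference_map, "summary")
        for arm in ("davinci", "hugo"):
            for label, (target, sd) in {
                "room_setup": MACRO_COSTS[arm]["room_setup"][:2],
                "anesthesia": MACRO_COSTS[arm]["anesthesia"][:2],
                "case_time": (CASE_TIME_COST[arm], 350.0),
                "total": (TOTAL_COST[arm], 350.0),
            }.items():
                row = summ[(summ.label == label) & (summ.arm == arm)].iloc[0]
                se = sd / np.sqrt(row["n"])
                assert abs(row["mean"] - target) < 3 * se, (arm, label)


class TestCategoryShares:
    def test_published_numerators_reproduce_published_shares(self):
        shares = tdabc.category_shares(
            {
                "davinci": {"consumable": 3498.03, "personnel": 784.00,
                            "platform": 353.90, "operating_room": 343.30},
                "hugo": {"consumable": 1586.00, "personnel": 977.80,
                         "platform": 535.40, "operating_room": 412.50},
            }
        )
        lookup = shares.set_index(["arm", "category"])["share_pct"].round(1)
        assert lookup["davinci", "consumable"] == 70.3
        assert lookup["hugo", "consumable"] == 45.2

    def test_shares_sum_to_100(self, trial_breakdowns, reference_map):
        cat = tdabc.cohort_summary(trial_breakdowns, reference_map, "category")
        shares = tdabc.category_shares(cat)
        sums = shares.groupby("arm")["share_pct"].apply(lambda s: s.round(1).sum())
        assert np.allclose(sums, 100.0, atol=0.1)

    def test_single_category_is_100(self):
        shares = tdabc.category_shares({"x": {"personnel": 12.0}})
        assert shares["share_pct"].iloc[0] == pytest.approx(100.0)

    def test_zero_total_rejected(self):
        with pytest.raises(DomainError):
            tdabc.category_shares({"x": {"personnel": 0.0}})


def test_staffed_rate_resolves_arm_placeholder(reference_map, reference_rates):
    act = reference_map.activity("trocar_placement")
    r_dv = staffed_rate(act, reference_rates, "davinci")
    r_h = staffed_rate(act, reference_rates, "hugo")
    diff = reference_rates["platform_hugo"].ccr - reference_rates["platform_davinci"].ccr
    assert r_h - r_dv == pytest.approx(diff)
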
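import numpy as np
import pytest

from ocumark.markov import CohortTrace
from ocumark.outcomes import (
    CostBreakdown,
    aggregate,
    annual_ae_disutility,
    annual_injection_disutility,
    cycle_costs,
    cycle_qalys,
    discount_factor,
)
from ocumark.parameters import apply_overrides


class TestDiscountFactor:
    def test_year_zero(self):
        assert discount_factor(0, 0.03) == 1.0

    def test_year_one(self):
        assert discount_factor(1, 0.03) == pytest.approx(0.970874, abs=5e-7)

    def test_zero_rate(self):
        for t in range(20):
            assert discount_factor(t, 0.0) == 1.0

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.03)
        with pytest.raises(ValueError):
            discount_factor(1, -0.03)


class TestInjectionDisutility:
    def test_brolucizumab_year1(self, params):
        assert annual_injection_disutility(6.66, params.utilities) == pytest.approx(
            0.009117, abs=5e-7
        )

    def test_aflibercept_year1(self, params):
        assert annual_injection_disutility(7.23, params.utilities) == pytest.approx(
            0.009897, abs=5e-7
        )

    def test_zero_injections(self, params):
        assert annual_injection_disutility(0.0, params.utilities) == 0.0

    def test_per_injection_loss_is_half_day(self, params):
        # 0.5 patients x 1 day / 365.25 days per injection
        one = annual_injection_disutility(1.0, params.utilities)
        assert one == pytest.approx(0.5 / 365.25)


class TestAEDisutility:
    def test_endophthalmitis_only(self, params):
        ae = [a for a in params.adverse_events if a.name == "endophthalmitis"]
        inc = ae[0].annual_incidence["brolucizumab"]
        expected = inc * 0.3 * (0.2 * 1.0 + 0.8 * 0.125)
        got = annual_ae_disutility(ae, "brolucizumab")
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.00027, abs=2e-5)

    def test_zero_disutility_events_contribute_nothing(self, params):
        tears = [
            a for a in params.adverse_events
            if a.name in ("retinal_tear", "rpe_tear")
        ]
        assert annual_ae_disutility(tears, "brolucizumab") == 0.0

    def test_empty_list(self):
        assert annual_ae_disutility([], "brolucizumab") == 0.0


class TestCycleQalys:
    def test_whole_cohort_best_state(self, params):
        occ = np.array([1.0, 0, 0, 0, 0, 0])
        q = cycle_qalys(occ, 0.0, 0.0, params, "brolucizumab", 0.0)
        assert q["qalys"] == pytest.approx(0.92)

    def test_all_dead(self, params):
        occ = np.zeros(6)
        q = cycle_qalys(occ, 0.0, 0.0, params, "brolucizumab", 6.66)
        assert q["qalys"] == 0.0
        assert q["life_years"] == 0.0

    def test_fifty_fifty_split(self, params):
        occ = np.array([0.5, 0, 0, 0, 0, 0.5])
        q = cycle_qalys(occ, 0.0, 0.0, params, "brolucizumab", 0.0)
        assert q["qalys"] == pytest.approx(0.66)

    def test_bilateral_decrement_applies_to_alive(self, params):
        p = apply_overrides(params, {"utilities.bilateral_decrement": 0.1})
        occ = np.array([1.0, 0, 0, 0, 0, 0])
        q = cycle_qalys(occ, 0.0, 0.5, p, "brolucizumab", 0.0)
        assert q["qalys"] == pytest.approx(0.92 - 0.1 * 0.5)


class TestCycleCosts:
    def test_year1_acquisition_per_patient(self, params):
        occ = np.array([1.0, 0, 0, 0, 0, 0])
        cb = cycle_costs(occ, 1.0, 0.0, params, "brolucizumab", 6.66, "nhs")
        assert cb.acquisition == pytest.approx(680 * 6.66)  # 4528.80

    def test_year1_administration(self, params):
        occ = np.array([1.0, 0, 0, 0, 0, 0])
        cb = cycle_costs(occ, 1.0, 0.0, params, "brolucizumab", 6.66, "nhs")
        assert cb.administration == pytest.approx(247.20 * 6.66)  # 1646.35

    def test_off_treatment_only_monitoring(self, params):
        occ = np.array([0, 1.0, 0, 0, 0, 0])
        cb = cycle_costs(occ, 0.0, 0.0, params, "brolucizumab", 6.66, "nhs")
        assert cb.acquisition == 0.0
        assert cb.administration == 0.0
        assert cb.ae_management == 0.0
        assert cb.monitoring == pytest.approx(36.07)
        assert cb.total == pytest.approx(36.07)

    def test_bilateral_doubles_treated_eyes(self, params):
        occ = np.array([1.0, 0, 0, 0, 0, 0])
        uni = cycle_costs(occ, 1.0, 0.0, params, "aflibercept", 7.23, "nhs")
        bil = cycle_costs(occ, 1.0, 1.0, params, "aflibercept", 7.23, "nhs")
        assert bil.acquisition == pytest.approx(2 * uni.acquisition)
        assert bil.monitoring == pytest.approx(uni.monitoring)

    def test_vision_loss_costs_attach_to_worst_states(self, params):
        occ = np.array([0, 0, 0, 0, 0.3, 0.7])
        cb = cycle_costs(occ, 0.0, 0.0, params, "brolucizumab", 0.0, "nhs")
        assert cb.blindness == pytest.approx(7856 * 0.7)
        assert cb.low_vision == pytest.approx(1964 * 0.3)

    def test_societal_swaps_vision_loss_costs(self, params):
        occ = np.array([0, 0, 0, 0, 0.3, 0.7])
        cb = cycle_costs(occ, 0.0, 0.0, params, "brolucizumab", 0.0, "societal")
        assert cb.blindness == pytest.approx(17897 * 0.7)
        assert cb.low_vision == pytest.approx(4474 * 0.3)

    def test_unknown_perspective(self, params):
        with pytest.raises(ValueError):
            cycle_costs(np.zeros(6), 0.0, 0.0, params, "brolucizumab", 0.0, "payer")


def _toy_trace() -> CohortTrace:
    on = np.array(
        [
            [0.2, 0.3, 0.5, 0.0, 0.0, 0.0],
            [0.1, 0.3, 0.4, 0.1, 0.05, 0.05],
            [0.1, 0.2, 0.3, 0.2, 0.1, 0.05],
            [0.05, 0.15, 0.3, 0.2, 0.1, 0.1],
        ]
    )
    off = np.zeros_like(on)
    dead = 1.0 - on.sum(axis=1)
    bilateral = np.array([0.2714, 0.35, 0.42, 0.48])
    age = 75.8 + np.arange(4.0)
    return CohortTrace(
        strategy="brolucizumab", on=on, off=off, dead=dead,
        bilateral=bilateral, age=age,
    )


class TestAggregate:
    def test_all_dead_trace_is_zero(self, params):
        n = params.settings.horizon + 1
        trace = CohortTrace(
            strategy="brolucizumab",
            on=np.zeros((n, 6)),
            off=np.zeros((n, 6)),
            dead=np.ones(n),
            bilateral=np.zeros(n),
            age=75.8 + np.arange(float(n)),
        )
        outcome, costs = aggregate(trace, params, "brolucizumab")
        assert outcome.life_years == 0.0
        assert outcome.qalys == 0.0
        assert costs.total == 0.0

    def test_three_cycle_spreadsheet_oracle(self, params):
        """Hand-rolled recomputation of a 3-cycle trace, category by category."""
        p = apply_overrides(
            params,
            {"settings.horizon": 3, "settings.half_cycle_correction": False},
        )
        trace = _toy_trace()
        outcome, costs = aggregate(trace, p, "brolucizumab", "nhs")

        util = [0.92, 0.82, 0.72, 0.63, 0.53, 0.40]
        inj_by_cycle = {1: 6.66, 2: 4.84, 3: 4.84}
        inc = {ae.name: ae.annual_incidence["brolucizumab"]
               for ae in p.adverse_events}
        ae_cost_pppy = (
            inc["cataract"] * 994.00
            + inc["endophthalmitis"] * 1522.00
            + inc["intraocular_inflammation"] * 20.66
            + inc["retinal_detachment"] * 1491.00
            + inc["rpe_tear"] * 1491.00
            + inc["retinal_tear"] * 1491.00
        )
        ae_dis_pppy = (
            inc["cataract"] * 0.14 * (1 / 12)
            + inc["endophthalmitis"] * 0.30 * (0.2 + 0.8 * 1.5 / 12)
            + inc["intraocular_inflammation"] * 0.04 * (1 / 12)
            + inc["retinal_detachment"] * 0.27 * (3 / 12)
        )
        exp = {k: 0.0 for k in ("ly", "qaly", "acq", "adm", "mon", "ae",
                                "blind", "lv")}
        for t in (1, 2, 3):
            row = trace.on[t]
            alive = row.sum()
            df = 1.03 ** -t
            eyes = 1.0 + trace.bilateral[t]
            n_inj = inj_by_cycle[t]
            exp["ly"] += alive * df
            exp["qaly"] += (
                sum(row[i] * util[i] for i in range(6))
                - alive * n_inj * 0.5 / 365.25
                - alive * ae_dis_pppy
            ) * df
            exp["acq"] += 680.00 * n_inj * alive * eyes * df
            exp["adm"] += 247.20 * n_inj * alive * eyes * df
            exp["mon"] += 36.07 * alive * df
            exp["ae"] += ae_cost_pppy * alive * df
            exp["blind"] += 7856.00 * row[5] * df
            exp["lv"] += 1964.00 * row[4] * df

        assert outcome.life_years == pytest.approx(exp["ly"], abs=1e-9)
        assert outcome.qalys == pytest.approx(exp["qaly"], abs=1e-9)
        assert costs.acquisition == pytest.approx(exp["acq"], abs=1e-9)
        assert costs.administration == pytest.approx(exp["adm"], abs=1e-9)
        assert costs.monitoring == pytest.approx(exp["mon"], abs=1e-9)
        assert costs.ae_management == pytest.approx(exp["ae"], abs=1e-9)
        assert costs.blindness == pytest.approx(exp["blind"], abs=1e-9)
        assert costs.low_vision == pytest.approx(exp["lv"], abs=1e-9)
        assert costs.total == pytest.approx(sum(
            exp[k] for k in ("acq", "adm", "mon", "ae", "blind", "lv")
        ), abs=1e-6)

    def test_discounted_below_undiscounted(self, params, life_table, base_cea):
        res = base_cea.results["brolucizumab"]
        p0 = apply_overrides(
            params,
            {
                "settings.discount_rate_costs": 0.0,
                "settings.discount_rate_outcomes": 0.0,
            },
        )
        outcome0, costs0 = aggregate(res.trace, p0, "brolucizumab")
        assert res.outcomes.qalys < outcome0.qalys
        assert res.outcomes.life_years < outcome0.life_years
        assert res.costs.total < costs0.total

    def test_perspective_switch_touches_only_vision_loss(self, params, base_cea):
        res = base_cea.results["aflibercept"]
        _, soc = aggregate(res.trace, params, "aflibercept", "societal")
        nhs = res.costs
        assert soc.acquisition == pytest.approx(nhs.acquisition)
        assert soc.administration == pytest.approx(nhs.administration)
        assert soc.monitoring == pytest.approx(nhs.monitoring)
        assert soc.ae_management == pytest.approx(nhs.ae_management)
        assert soc.blindness > nhs.blindness
        assert soc.low_vision > nhs.low_vision

    def test_removing_aes_raises_qalys_lowers_costs(self, params, life_table):
        from ocumark.cea import run_strategy

        p = params.copy()
        for ae in p.adverse_events:
            ae.annual_incidence = {s: 0.0 for s in p.strategies}
        with_aes = run_strategy(params, "brolucizumab", life_table)
        without = run_strategy(p, "brolucizumab", life_table)
        assert without.outcomes.qalys > with_aes.outcomes.qalys
        assert without.costs.total < with_aes.costs.total

    def test_qalys_bounded_by_life_years(self, base_cea):
        for res in base_cea.results.values():
            assert res.outcomes.qalys <= res.outcomes.life_years * 0.92
            assert res.outcomes.qalys <= res.outcomes.life_years

    def test_single_cycle_no_discount_equals_cycle_values(self, params):
        p = apply_overrides(
            params,
            {
                "settings.horizon": 1,
                "settings.half_cycle_correction": False,
                "settings.discount_rate_costs": 0.0,
                "settings.discount_rate_outcomes": 0.0,
            },
        )
        trace = _toy_trace()
        trace = CohortTrace(
            strategy="brolucizumab",
            on=trace.on[:2], off=trace.off[:2], dead=trace.dead[:2],
            bilateral=trace.bilateral[:2], age=trace.age[:2],
        )
        outcome, costs = aggregate(trace, p, "brolucizumab", "nhs")
        row = trace.on[1]
        q = cycle_qalys(row, row.sum(), trace.bilateral[1], p, "brolucizumab", 6.66)
        cb = cycle_costs(row, row.sum(), trace.bilateral[1], p, "brolucizumab",
                         6.66, "nhs")
        assert outcome.qalys == pytest.approx(q["qalys"])
        assert costs.total == pytest.approx(cb.total)


def test_cost_breakdown_total_is_component_sum():
    cb = CostBreakdown(acquisition=1, administration=2, monitoring=3,
                       ae_management=4, blindness=5, low_vision=6)
    assert cb.total == pytest.approx(21.0)
    assert cb.as_dict()["total"] == pytest.approx(21.0)
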
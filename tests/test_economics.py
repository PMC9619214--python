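"""Incremental analysis, NMB decision rules, threshold and subgroup logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survecon.economics import (
    ArmResult,
    CEResult,
    SubgroupSpec,
    incremental_analysis,
    net_monetary_benefit,
    price_threshold_search,
    run_scenario,
    run_subgroup,
)
from survecon.survival import DistributionSpec, HRAdjustedCurve


def arm(name, cost, qaly, ly=None):
    return ArmResult(name, cost, ly if ly is not None else qaly * 1.2, qaly)


class TestIncremental:
    # printed per-arm totals of the published base case, used as inputs
    TABLE1 = {
        "us_itt": ((224575, 1.75, 2.31), (156987, 1.32, 1.81), 67588, 0.43),
        "us_cns": ((169689, 1.20, 1.57), (153224, 1.32, 1.81), 16465, -0.12),
        "china_itt": ((15748, 1.60, 2.20), (14085, 1.26, 1.76), 1663, 0.34),
        "china_cns": ((12860, 1.12, 1.53), (13365, 1.26, 1.76), -505, -0.14),
    }

    @pytest.mark.parametrize("case", TABLE1.values(), ids=TABLE1.keys())
    def test_base_case_increment_identities(self, case):
        (ca, qa, la), (cb, qb, lb), dc, dq = case
        ce = incremental_analysis(
            ArmResult("osimertinib", ca, la, qa),
            ArmResult("platinum_pemetrexed", cb, lb, qb),
        )
        assert ce.delta_cost == pytest.approx(dc)
        assert ce.delta_qaly == pytest.approx(dq)

    def test_identical_arms_undefined_icer(self):
        ce = incremental_analysis(arm("a", 100.0, 1.0), arm("b", 100.0, 1.0))
        assert ce.icer_per_qaly is None
        assert ce.delta_cost == 0.0
        # NMB still well defined
        assert ce.nmb(50000) == 0.0

    def test_negative_icer_reported_sign_and_all(self):
        ce = incremental_analysis(arm("a", 169689, 1.20), arm("b", 153224, 1.32))
        assert ce.icer_per_qaly < 0
        assert ce.dominance == "dominated"

    def test_southwest_quadrant_positive_icer(self):
        ce = incremental_analysis(arm("a", 12860, 1.12), arm("b", 13365, 1.26))
        assert ce.delta_cost < 0 and ce.delta_qaly < 0
        assert ce.icer_per_qaly > 0
        assert ce.dominance == "tradeoff"

    def test_dominant_flag(self):
        ce = incremental_analysis(arm("a", 90.0, 1.5), arm("b", 100.0, 1.0))
        assert ce.dominance == "dominant"


class TestNMB:
    def test_zero_case(self):
        assert net_monetary_benefit(0.0, 0.0, 123456.0) == 0.0

    def test_arithmetic(self):
        assert net_monetary_benefit(15748.0, 1.6, 37489.0) == pytest.approx(44234.40)

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            net_monetary_benefit(0.0, 1.0, -1.0)

    @given(
        ca=st.floats(0, 5e5),
        cb=st.floats(0, 5e5),
        qa=st.floats(0.01, 5),
        dq=st.floats(0.01, 3),
        wtp=st.floats(0, 3e5),
    )
    @settings(deadline=None, max_examples=100)
    def test_nmb_ranking_agrees_with_icer_rule(self, ca, cb, qa, dq, wtp):
        """When the intervention adds QALYs, NMB_a > NMB_b iff ICER < WTP."""
        qb = qa
        qa = qa + dq
        nmb_a = net_monetary_benefit(ca, qa, wtp)
        nmb_b = net_monetary_benefit(cb, qb, wtp)
        icer = (ca - cb) / dq
        # skip knife-edge cases where wtp*dq is absorbed in float addition
        if abs(wtp * dq - (ca - cb)) > 1e-6 * max(1.0, ca, cb):
            assert (nmb_a > nmb_b) == (icer < wtp)


class ToyPriceModel:
    """Only drug cost differs: C_a(p) = p * quantity + fixed; dE fixed."""

    def __init__(self, quantity=1000.0, other_dc=5000.0, de=0.4):
        self.quantity = quantity
        self.other_dc = other_dc
        self.de = de

    def __call__(self, price):
        a = ArmResult("a", price * self.quantity + self.other_dc, 1.0, self.de)
        b = ArmResult("b", 0.0, 1.0, 0.0)
        return incremental_analysis(a, b)

    def closed_form(self, wtp):
        return (wtp * self.de - self.other_dc) / self.quantity


class TestPriceThreshold:
    def test_matches_closed_form(self):
        toy = ToyPriceModel()
        wtp = 150000.0
        p = price_threshold_search(toy, wtp, (0.0, 1000.0))
        assert p == pytest.approx(toy.closed_form(wtp), abs=1e-3)

    def test_wtp_zero_balances_costs(self):
        toy = ToyPriceModel(other_dc=-2000.0, de=0.4)
        p = price_threshold_search(toy, 0.0, (0.0, 100.0))
        assert p * toy.quantity == pytest.approx(2000.0, abs=1.0)

    def test_no_sign_change_reports_ends(self):
        toy = ToyPriceModel(other_dc=1e9)
        with pytest.raises(ValueError, match="does not change sign"):
            price_threshold_search(toy, 1000.0, (0.0, 10.0))

    def test_self_consistency_on_fixture_model(self, china_itt_model):
        config_wtp = china_itt_model.config.wtp
        model = china_itt_model.price_model("osimertinib")
        p = price_threshold_search(model, config_wtp, (0.001, 50.0))
        assert abs(model(p).nmb(config_wtp)) < 1.0


class TestSubgroup:
    comp_pfs = DistributionSpec("weibull", (0.11, 1.25))
    comp_os = DistributionSpec("weibull", (0.0073, 1.48))

    @staticmethod
    def curve_only_evaluate(int_pfs, int_os, comp_pfs, comp_os):
        """Effect driven purely by the curves (unit utility, zero cost)."""
        from survecon.engine import ModelSettings, build_trace, life_years

        settings = ModelSettings(discount_rate_annual=0.0)
        a = build_trace(int_pfs, int_os, settings)
        b = build_trace(comp_pfs, comp_os, settings)
        return incremental_analysis(
            ArmResult("a", 0.0, life_years(a, settings), life_years(a, settings)),
            ArmResult("b", 0.0, life_years(b, settings), life_years(b, settings)),
        )

    def test_unit_hrs_reproduce_comparator(self):
        spec = SubgroupSpec("null", 1.0, 1.0)
        ce = run_subgroup(self.comp_pfs, self.comp_os, spec, self.curve_only_evaluate)
        assert ce.delta_qaly == pytest.approx(0.0, abs=1e-12)

    def test_harmful_os_hr_gives_negative_survival_increment(self):
        spec = SubgroupSpec("cns", hr_pfs=1.0, hr_os=1.19)
        ce = run_subgroup(self.comp_pfs, self.comp_os, spec, self.curve_only_evaluate)
        assert ce.delta_ly < 0

    def test_adjusted_curve_dominated_pointwise(self):
        adj = HRAdjustedCurve(self.comp_os, 1.19)
        grid = np.linspace(0.0, 60.0, 100)
        assert np.all(adj.survival(grid) <= self.comp_os.survival(grid) + 1e-12)

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            SubgroupSpec("bad", 0.0, 1.0)


class TestScenario:
    ce = incremental_analysis(arm("osi", 20000.0, 1.6), arm("pp", 14000.0, 1.26))

    def test_decision_rows_per_wtp(self):
        rows = run_scenario(self.ce, [19003.0, 37489.0, 85176.0])
        assert len(rows) == 3
        assert {r["wtp"] for r in rows} == {19003.0, 37489.0, 85176.0}

    def test_wtp_zero_prefers_cheaper(self):
        rows = run_scenario(self.ce, [0.0])
        assert rows[0]["preferred"] == "pp"

    def test_large_wtp_prefers_more_effective(self):
        rows = run_scenario(self.ce, [1e9])
        assert rows[0]["preferred"] == "osi"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            run_scenario(self.ce, [])
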
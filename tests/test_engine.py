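"""Cohort trace construction, discounting and accrual."""

import numpy as np
import pytest

from survecon.engine import (
    ModelSettings,
    accrue,
    build_trace,
    build_trace_markov,
    discount_factor,
    life_years,
    qalys,
)
from survecon.survival import DistributionSpec


class RampCurve:
    """Linear survival hitting exactly zero at t_end (months)."""

    def __init__(self, t_end):
        self.t_end = t_end

    def survival(self, t):
        return np.clip(1.0 - np.asarray(t, dtype=float) / self.t_end, 0.0, 1.0)


SETTINGS = ModelSettings()
NO_DISCOUNT = ModelSettings(discount_rate_annual=0.0)


class TestBuildTrace:
    def test_identical_curves_leave_pd_empty(self):
        spec = DistributionSpec("exponential", (0.05,))
        trace = build_trace(spec, spec, SETTINGS)
        assert np.all(trace.pd == 0.0)

    def test_first_cycle_death_closed_form(self):
        os_spec = DistributionSpec("exponential", (0.03,))
        pfs = DistributionSpec("exponential", (0.2,))
        trace = build_trace(pfs, os_spec, SETTINGS)
        u = SETTINGS.cycle_months
        assert trace.dead[1] == pytest.approx(1.0 - np.exp(-0.03 * u), rel=1e-12)
        assert u == pytest.approx(21.0 / 365.25 * 12.0)

    def test_crossing_curves_clamped_and_counted(self):
        # PFS above OS at late times: exponential PFS with lower rate
        pfs = DistributionSpec("exponential", (0.02,))
        os_spec = DistributionSpec("exponential", (0.05,))
        trace = build_trace(pfs, os_spec, SETTINGS)
        assert trace.clamp_count > 0
        assert np.all(trace.pd >= 0.0)

    def test_horizon_shorter_than_cycle_rejected(self):
        spec = DistributionSpec("exponential", (0.05,))
        with pytest.raises(ValueError):
            build_trace(spec, spec, ModelSettings(horizon_years=0.001))

    def test_conservation_and_monotone_death(self):
        pfs = DistributionSpec("loglogistic", (10.1, 1.8))
        os_spec = DistributionSpec("loglogistic", (26.8, 2.1))
        trace = build_trace(pfs, os_spec, SETTINGS)
        assert np.max(np.abs(trace.pfs + trace.pd + trace.dead - 1.0)) <= 1e-9
        assert np.all(np.diff(trace.dead) >= -1e-12)
        assert np.all(np.diff(trace.pfs) <= 1e-12)

    def test_markov_mode_agrees_for_noncrossing_curves(self):
        pfs = DistributionSpec("weibull", (0.11, 1.25))
        os_spec = DistributionSpec("weibull", (0.0073, 1.48))
        a = build_trace(pfs, os_spec, SETTINGS)
        b = build_trace_markov(pfs, os_spec, SETTINGS)
        assert np.max(np.abs(a.pfs - b.pfs)) < 1e-10
        assert np.max(np.abs(a.pd - b.pd)) < 1e-10


class TestDiscountFactor:
    def test_values(self):
        assert discount_factor(0.03, 0.0) == 1.0
        assert discount_factor(0.03, 1.0) == pytest.approx(1 / 1.03, rel=1e-12)
        assert discount_factor(0.05, 2.0) == pytest.approx(1 / 1.1025, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(0.03, -1.0)


class TestAccrue:
    def test_undiscounted_flat_stream_sums_cycles(self):
        from survecon.engine import CohortTrace

        times = np.arange(11) * NO_DISCOUNT.cycle_months
        tr = CohortTrace(times, np.ones(11), np.zeros(11), np.zeros(11))
        assert accrue(tr, {"pfs": 1.0}, NO_DISCOUNT) == pytest.approx(10.0)

    def test_mean_survival_limit(self):
        # exponential OS at 0.5/year: undiscounted LY ~ 1/lambda = 2.0
        lam_month = 0.5 / 12.0
        spec = DistributionSpec("exponential", (lam_month,))
        settings = ModelSettings(discount_rate_annual=0.0, horizon_years=60.0)
        trace = build_trace(spec, spec, settings)
        assert life_years(trace, settings) == pytest.approx(2.0, rel=0.01)

    def test_one_off_fully_conserved_when_all_die(self):
        curve = RampCurve(24.0)
        settings = ModelSettings(discount_rate_annual=0.0, horizon_years=5.0)
        trace = build_trace(curve, curve, settings)
        assert trace.dead[-1] == pytest.approx(1.0)
        total = accrue(trace, {}, settings, one_off_on_death=1000.0)
        assert total == pytest.approx(1000.0, abs=1e-9)

    def test_mismatched_stream_length_rejected(self):
        spec = DistributionSpec("exponential", (0.05,))
        trace = build_trace(spec, spec, SETTINGS)
        with pytest.raises(ValueError):
            accrue(trace, {"pfs": np.ones(3)}, SETTINGS)

    def test_discounted_totals_monotone_in_rate(self):
        spec = DistributionSpec("exponential", (0.03,))
        totals = []
        for rate in (0.0, 0.03, 0.05, 0.10):
            settings = ModelSettings(discount_rate_annual=rate)
            trace = build_trace(spec, spec, settings)
            totals.append(accrue(trace, {"pfs": 100.0}, settings))
        assert all(a > b for a, b in zip(totals, totals[1:]))

    def test_half_cycle_correction_bounded_by_one_cycle(self):
        spec = DistributionSpec("exponential", (0.05,))
        on = ModelSettings(discount_rate_annual=0.0, half_cycle_correction=True)
        off = ModelSettings(discount_rate_annual=0.0, half_cycle_correction=False)
        tr_on = build_trace(spec, spec, on)
        tr_off = build_trace(spec, spec, off)
        v_on = accrue(tr_on, {"pfs": 1.0}, on)
        v_off = accrue(tr_off, {"pfs": 1.0}, off)
        assert abs(v_on - v_off) < 1.0  # less than one cycle's worth of value

    def test_quadrature_matches_survival_area(self):
        from scipy.integrate import quad

        spec = DistributionSpec("weibull", (0.0073, 1.48))
        settings = ModelSettings(discount_rate_annual=0.0, horizon_years=20.0)
        trace = build_trace(spec, spec, settings)
        area_months, _ = quad(lambda t: spec.survival(t), 0, trace.times_months[-1], limit=400)
        ly = life_years(trace, settings)
        assert ly == pytest.approx(area_months / 12.0, rel=2e-3)


class TestQALY:
    def test_unit_utilities_equal_life_years(self):
        spec = DistributionSpec("exponential", (0.04,))
        trace = build_trace(spec, spec, NO_DISCOUNT)
        assert qalys(trace, {"pfs": 1.0, "pd": 1.0}, NO_DISCOUNT) == pytest.approx(
            life_years(trace, NO_DISCOUNT)
        )

    def test_hand_summed_weighted_total(self):
        from survecon.engine import CohortTrace

        u = NO_DISCOUNT.cycle_months
        times = np.arange(3) * u
        tr = CohortTrace(
            times,
            np.array([1.0, 0.6, 0.4]),
            np.array([0.0, 0.3, 0.4]),
            np.array([0.0, 0.1, 0.2]),
        )
        uy = NO_DISCOUNT.cycle_years
        expected = uy * (0.8 * (0.8 + 0.5) + 0.5 * (0.15 + 0.35))
        got = qalys(tr, {"pfs": 0.8, "pd": 0.5}, NO_DISCOUNT)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_utility_warns(self):
        spec = DistributionSpec("exponential", (0.04,))
        trace = build_trace(spec, spec, NO_DISCOUNT)
        with pytest.warns(UserWarning):
            qalys(trace, {"pfs": 1.2, "pd": 0.5}, NO_DISCOUNT)

    def test_ae_decrement_subtracts_once(self):
        spec = DistributionSpec("exponential", (0.04,))
        trace = build_trace(spec, spec, NO_DISCOUNT)
        base = qalys(trace, {"pfs": 1.0, "pd": 1.0}, NO_DISCOUNT)
        less = qalys(trace, {"pfs": 1.0, "pd": 1.0}, NO_DISCOUNT, ae_qaly_decrement=0.005)
        assert base - less == pytest.approx(0.005)
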
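"""Parametric survival families: evaluation, fitting, selection, HR adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survecon.reconstruct import PseudoIPD
from survecon.simulate import simulate_arm
from survecon.survival import (
    FAMILIES,
    DistributionSpec,
    FittingError,
    HRAdjustedCurve,
    SurvivalFit,
    cycle_transition_prob,
    fit_all_families,
    fit_mle,
    hr_adjusted_survival,
    median_survival,
    select_distribution,
    survival_at,
)

TRUTHS = {
    "exponential": DistributionSpec("exponential", (0.08,)),
    "weibull": DistributionSpec("weibull", (0.08, 1.4)),
    "loglogistic": DistributionSpec("loglogistic", (12.0, 2.2)),
    "lognormal": DistributionSpec("lognormal", (2.5, 0.8)),
}

# random-censoring rates giving roughly 20% censored observations
CENSOR_RATES = {
    "exponential": 0.020,
    "weibull": 0.040,
    "loglogistic": 0.018,
    "lognormal": 0.014,
}

spec_strategy = st.sampled_from(
    [
        DistributionSpec("exponential", (0.05,)),
        DistributionSpec("exponential", (0.3,)),
        DistributionSpec("weibull", (0.02, 0.8)),
        DistributionSpec("weibull", (0.05, 1.6)),
        DistributionSpec("loglogistic", (8.0, 1.2)),
        DistributionSpec("loglogistic", (20.0, 3.0)),
        DistributionSpec("lognormal", (2.0, 0.5)),
        DistributionSpec("lognormal", (3.0, 1.2)),
    ]
)


class TestSurvivalAt:
    @pytest.mark.parametrize("spec", TRUTHS.values(), ids=TRUTHS.keys())
    def test_starts_at_one(self, spec):
        assert survival_at(spec, 0.0) == pytest.approx(1.0)

    def test_weibull_closed_form(self):
        spec = DistributionSpec("weibull", (0.1, 1.5))
        assert survival_at(spec, 4.0) == pytest.approx(np.exp(-0.8), rel=1e-12)

    def test_loglogistic_median_is_scale(self):
        spec = DistributionSpec("loglogistic", (10.0, 2.0))
        assert survival_at(spec, 10.0) == pytest.approx(0.5, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival_at(TRUTHS["weibull"], -1.0)

    @given(spec=spec_strategy)
    @settings(deadline=None, max_examples=40)
    def test_monotone_and_vanishing(self, spec):
        grid = np.linspace(0.0, 600.0, 400)
        s = survival_at(spec, grid)
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 1e-12)
        assert s[-1] < 0.05
        assert np.all((s >= 0) & (s <= 1))


class TestMedian:
    def test_exponential_anchored_to_trial_median(self):
        lam = np.log(2.0) / 4.4
        assert median_survival(DistributionSpec("exponential", (lam,))) == pytest.approx(4.4)

    def test_loglogistic_scale(self):
        assert median_survival(DistributionSpec("loglogistic", (10.1, 3.7))) == 10.1

    @pytest.mark.parametrize("spec", TRUTHS.values(), ids=TRUTHS.keys())
    def test_median_agrees_with_root_of_survival(self, spec):
        from scipy.optimize import brentq

        m = median_survival(spec)
        root = brentq(lambda t: survival_at(spec, t) - 0.5, 1e-6, 1e4)
        assert m == pytest.approx(root, rel=1e-7)


class TestCycleTransitionProb:
    def test_exponential_closed_form_and_memorylessness(self):
        spec = DistributionSpec("exponential", (0.1,))
        expected = 1.0 - np.exp(-0.075)
        for t in (0.0, 3.0, 50.0):
            assert cycle_transition_prob(spec, t, 0.75) == pytest.approx(expected, rel=1e-12)

    def test_zero_length_cycle(self):
        assert cycle_transition_prob(TRUTHS["weibull"], 5.0, 0.0) == 0.0

    def test_weibull_from_survival_ratio(self):
        spec = DistributionSpec("weibull", (0.05, 2.0))
        expected = 1.0 - np.exp(-0.05 * (3.75**2 - 3.0**2))
        assert cycle_transition_prob(spec, 3.0, 0.75) == pytest.approx(expected, rel=1e-12)

    def test_absorbed_mass_warns_and_returns_one(self):
        spec = DistributionSpec("weibull", (5.0, 3.0))
        with pytest.warns(UserWarning):
            assert cycle_transition_prob(spec, 100.0, 1.0) == 1.0

    @given(spec=spec_strategy, t=st.floats(0.0, 40.0), u=st.floats(0.0, 5.0))
    @settings(deadline=None, max_examples=60)
    def test_identity_with_survival_ratio(self, spec, t, u):
        s_t = survival_at(spec, t)
        if s_t <= 1e-12:
            return
        p = cycle_transition_prob(spec, t, u)
        assert p == pytest.approx(1.0 - survival_at(spec, t + u) / s_t, abs=1e-10)
        assert 0.0 <= p <= 1.0


class TestFitMLE:
    def test_exponential_closed_form(self):
        # 10 events, total observed time 100 months -> rate exactly 0.1
        ipd = PseudoIPD(tuple([8.0] * 10 + [10.0] * 2), tuple([1] * 10 + [0] * 2))
        fit = fit_mle(ipd, "exponential")
        assert fit.spec.params[0] == pytest.approx(10.0 / 100.0, abs=1e-10)

    def test_no_events_is_an_error(self):
        with pytest.raises(FittingError):
            fit_mle(PseudoIPD((1.0, 2.0), (0, 0)), "weibull")

    def test_information_criteria_identities(self):
        fit = SurvivalFit(TRUTHS["weibull"], log_likelihood=-100.0, n_obs=50)
        assert fit.aic == pytest.approx(2 * 2 + 200.0)
        assert fit.bic == pytest.approx(2 * np.log(50) + 200.0)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_parameter_recovery_uncensored(self, family):
        truth = TRUTHS[family]
        rng = np.random.default_rng(42)
        ipd = simulate_arm(truth, 1000, np.inf, 0.0, rng)
        fit = fit_mle(ipd, family)
        rel = np.abs(np.array(fit.spec.params) - np.array(truth.params)) / np.abs(truth.params)
        assert np.all(rel <= 0.05), f"{family}: {fit.spec.params} vs {truth.params}"

    @pytest.mark.parametrize("family", FAMILIES)
    def test_parameter_recovery_with_censoring(self, family):
        truth = TRUTHS[family]
        rng = np.random.default_rng(43)
        ipd = simulate_arm(truth, 1000, np.inf, CENSOR_RATES[family], rng)
        frac_cens = 1.0 - ipd.n_events / len(ipd)
        assert 0.10 <= frac_cens <= 0.30  # the intended censoring regime
        fit = fit_mle(ipd, family)
        rel = np.abs(np.array(fit.spec.params) - np.array(truth.params)) / np.abs(truth.params)
        assert np.all(rel <= 0.10), f"{family}: {fit.spec.params} vs {truth.params}"

    def test_weibull_beats_exponential_on_shaped_data(self):
        rng = np.random.default_rng(7)
        ipd = simulate_arm(TRUTHS["weibull"], 500, np.inf, 0.0, rng)
        aic_w = fit_mle(ipd, "weibull").aic
        aic_e = fit_mle(ipd, "exponential").aic
        assert aic_w < aic_e

    def test_matches_lifelines_oracle(self):
        """Independent MLE cross-check on the same censored sample."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(11)
        ipd = simulate_arm(TRUTHS["weibull"], 400, 30.0, 0.01, rng)
        fit = fit_mle(ipd, "weibull")
        wf = lifelines.WeibullFitter().fit(np.asarray(ipd.times), np.asarray(ipd.events))
        # lifelines: S(t)=exp(-(t/lambda_)**rho_) -> lam = lambda_**-rho
        lam = wf.lambda_ ** -wf.rho_
        assert fit.spec.params[0] == pytest.approx(lam, rel=1e-3)
        assert fit.spec.params[1] == pytest.approx(wf.rho_, rel=1e-3)


class TestSelection:
    def test_sorts_by_criterion(self):
        fits = [
            SurvivalFit(TRUTHS["weibull"], -(100.0 - 4) / 2, 50),
            SurvivalFit(TRUTHS["loglogistic"], -(95.0 - 4) / 2, 50),
            SurvivalFit(TRUTHS["lognormal"], -(102.0 - 4) / 2, 50),
        ]
        ranked = select_distribution(fits, "aic")
        assert [round(f.aic) for f in ranked] == [95, 100, 102]

    def test_tie_broken_by_fewer_parameters(self):
        exp = SurvivalFit(TRUTHS["exponential"], -50.0, 50)  # k=1, aic=102
        wei = SurvivalFit(TRUTHS["weibull"], -49.0, 50)  # k=2, aic=102
        assert select_distribution([wei, exp], "aic")[0] is exp

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_distribution([], "aic")

    @pytest.mark.parametrize("family", ["exponential", "weibull", "lognormal"])
    def test_generating_family_usually_ranked_first(self, family):
        """Selection consistency where the families are statistically
        separable at n=300 (log-logistic vs lognormal are not; see the
        methods note)."""
        truth = TRUTHS[family]
        crit = "bic" if family == "exponential" else "aic"
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            ipd = simulate_arm(truth, 300, np.inf, 0.0, rng)
            ranked = select_distribution(fit_all_families(ipd), crit)
            wins += ranked[0].spec.family == family
        assert wins >= 18


class TestHRAdjustment:
    def test_identity_at_unit_hr(self):
        for mode in ("proportional_hazards", "rate_multiply"):
            assert hr_adjusted_survival(0.5, 1.0, mode) == pytest.approx(0.5)

    def test_proportional_hazards_power(self):
        assert hr_adjusted_survival(0.5, 1.19) == pytest.approx(0.5**1.19, rel=1e-12)

    def test_rate_multiply_clamps(self):
        assert hr_adjusted_survival(0.9, 1.2, "rate_multiply") == 1.0

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            hr_adjusted_survival(0.5, 0.0)

    @given(hr=st.floats(0.1, 3.0), spec=spec_strategy)
    @settings(deadline=None, max_examples=40)
    def test_adjusted_curve_stays_monotone(self, hr, spec):
        curve = HRAdjustedCurve(spec, hr)
        grid = np.linspace(0.0, 120.0, 200)
        s = curve.survival(grid)
        assert np.all(np.diff(s) <= 1e-12)
        assert s[0] == pytest.approx(1.0)
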
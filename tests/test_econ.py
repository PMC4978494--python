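"""Incremental analysis, PSA, CEAC, tornado and scenario machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hercua.econ as econ
from hercua import EconResult, ModelParameters, PsaSpec, TreatmentEffect, ceac, icer, pool


class TestIcer:
    @pytest.mark.parametrize(
        "dc,dq,expected",
        [
            (100, 2, 50),
            (73_202, 1.70, pytest.approx(43_060, abs=1.0)),
            (-10, 1, "dominant"),
            (10, -1, "dominated"),
            (0, 0, "undefined"),
        ],
    )
    def test_quadrants(self, dc, dq, expected):
        assert icer(dc, dq) == expected


class TestPool:
    def test_single_stratum_identity(self):
        r = EconResult(1.2, 300.0)
        pooled = pool([r], [1.0])
        assert pooled.delta_qalys == 1.2 and pooled.delta_cost == 300.0

    def test_pooled_icer_from_pooled_increments(self):
        rs = [EconResult(1.0, 100.0), EconResult(3.0, 100.0)]
        pooled = pool(rs, [0.5, 0.5])
        assert pooled.icer == pytest.approx(50.0)  # not mean of (100, 33.3)

    def test_weight_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pool([EconResult(1, 1)], [0.5, 0.5])
        with pytest.raises(ValueError, match="sum to 1"):
            pool([EconResult(1, 1), EconResult(2, 2)], [0.5, 0.2])

    @given(
        dq=st.lists(st.floats(min_value=0.1, max_value=5), min_size=2, max_size=5),
        dc=st.lists(st.floats(min_value=1, max_value=1e5), min_size=2, max_size=5),
        w=st.lists(st.floats(min_value=0.01, max_value=1), min_size=2, max_size=5),
    )
    def test_pooled_icer_bounded_by_strata(self, dq, dc, w):
        n = min(len(dq), len(dc), len(w))
        w = np.array(w[:n]) / np.sum(w[:n])
        rs = [EconResult(q, c) for q, c in zip(dq[:n], dc[:n])]
        icers = [r.icer for r in rs]
        pooled = pool(rs, w)
        assert min(icers) - 1e-9 <= pooled.icer <= max(icers) + 1e-9


def linear_pipeline(params: ModelParameters):
    """Cheap stand-in pipeline: increments responding linearly to the drawn
    treatment RR and drug cost, so PSA behaviour is analytically predictable."""
    rr = params.effect.rr_bc_by_age["50-59"]
    dq = 2.0 * (1.0 - rr)
    dc = params.costs.trastuzumab_drug / 10.0 + 100.0 * params.dw.treatment
    return dq, dc


class TestRunPsa:
    def test_seed_determinism(self):
        spec = PsaSpec(n_draws=50, seed=42)
        d1 = econ.run_psa(linear_pipeline, ModelParameters(), spec)
        d2 = econ.run_psa(linear_pipeline, ModelParameters(), spec)
        pd.testing.assert_frame_equal(d1, d2)
        d3 = econ.run_psa(linear_pipeline, ModelParameters(), PsaSpec(n_draws=50, seed=43))
        assert not d1.equals(d3)

    def test_zero_se_degenerates_to_deterministic(self):
        effect = TreatmentEffect(
            se_ln_rr_by_age={"<40": 0.0, "40-49": 0.0, "50-59": 0.0, ">=60": 0.0}
        )
        dw = ModelParameters().dw
        dw0 = type(dw)(alphas={k: (1e9, (1 / v - 1) * 1e9) for k, v in
                               {"treatment": 0.194, "preterminal": 0.513,
                                "terminal": 0.521, "remission_initial": 0.174,
                                "chf": 0.088}.items()})
        base = ModelParameters(effect=effect, dw=dw0)
        spec = PsaSpec(n_draws=20, seed=1, cost_se_frac=0.0, chf_se_ln=0.0)
        draws = econ.run_psa(linear_pipeline, base, spec)
        det = linear_pipeline(base)
        np.testing.assert_allclose(draws["delta_qalys"], det[0], rtol=1e-3)
        np.testing.assert_allclose(draws["delta_cost"], det[1], rtol=1e-3)

    def test_lognormal_rr_moments(self):
        """Mean drawn RR for the 50-59 band ~ exp(ln 0.56 + SE^2/2)."""
        spec = PsaSpec(n_draws=2000, seed=5)
        rng = np.random.default_rng(spec.seed)
        rrs = [
            econ.draw_parameters(ModelParameters(), spec, rng).effect.rr_bc_by_age["50-59"]
            for _ in range(spec.n_draws)
        ]
        se = 0.106
        mean_expected = 0.56 * np.exp(se**2 / 2)
        sd = 0.56 * se  # delta-method scale
        assert np.mean(rrs) == pytest.approx(mean_expected, abs=3 * sd / np.sqrt(2000))

    def test_gamma_cost_moments(self):
        spec = PsaSpec(n_draws=3000, seed=9)
        rng = np.random.default_rng(0)
        mults = [econ._gamma_mult(rng, spec.cost_se_frac) for _ in range(spec.n_draws)]
        assert np.mean(mults) == pytest.approx(1.0, abs=3 * 0.1 / np.sqrt(3000))
        assert np.std(mults) == pytest.approx(0.1, rel=0.1)


class TestCeac:
    draws = pd.DataFrame({"delta_qalys": [1.0, 1.5, 2.0], "delta_cost": [50.0, 75.0, 300.0]})

    def test_zero_threshold_positive_costs(self):
        assert ceac(self.draws, [0.0])["prob_cost_effective"].iloc[0] == 0.0

    def test_huge_threshold_positive_gains(self):
        assert ceac(self.draws, [1e9])["prob_cost_effective"].iloc[0] == 1.0

    def test_matches_direct_count(self):
        lam = 60.0
        direct = np.mean(lam * self.draws["delta_qalys"] - self.draws["delta_cost"] > 0)
        assert ceac(self.draws, [lam])["prob_cost_effective"].iloc[0] == direct

    def test_monotone_when_gains_positive(self):
        grid = np.linspace(0, 500, 40)
        probs = ceac(self.draws, grid)["prob_cost_effective"].to_numpy()
        assert np.all(np.diff(probs) >= 0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ceac(self.draws, [])
        with pytest.raises(ValueError):
            ceac(self.draws.iloc[:0], [1.0])


class TestRatioWithCi:
    def test_identical_strata_give_unit_ratio(self):
        d = pd.DataFrame({"delta_qalys": [1.0, 2.0, 3.0], "delta_cost": [10.0, 20.0, 30.0]})
        out = econ.ratio_with_ci(d, d.copy(), "delta_qalys")
        assert out["ratio"] == pytest.approx(1.0)
        assert out["ci_low"] == pytest.approx(1.0) and out["ci_high"] == pytest.approx(1.0)

    def test_interval_contains_point_for_paired_draws(self):
        rng = np.random.default_rng(3)
        base = rng.lognormal(0, 0.05, 500)
        a = pd.DataFrame({"delta_qalys": 2.0 * base, "delta_cost": 100 * base})
        b = pd.DataFrame({"delta_qalys": base, "delta_cost": 100 * base})
        out = econ.ratio_with_ci(a, b, "delta_qalys", point_a=2.0, point_b=1.0)
        assert out["ci_low"] <= out["ratio"] <= out["ci_high"]
        assert out["ratio"] == pytest.approx(2.0)

    def test_unpaired_sets_rejected(self):
        a = pd.DataFrame({"delta_qalys": [1.0], "delta_cost": [1.0]})
        b = pd.DataFrame({"delta_qalys": [1.0, 2.0], "delta_cost": [1.0, 2.0]})
        with pytest.raises(ValueError, match="paired"):
            econ.ratio_with_ci(a, b)


class TestTornado:
    def test_zero_se_parameter_has_zero_width_bar(self):
        spec = PsaSpec(cost_se_frac=0.0, chf_se_ln=0.0)
        df = econ.tornado(linear_pipeline, ModelParameters(), spec)
        cost_bar = df[df["parameter"] == "cost_trastuzumab_drug"].iloc[0]
        assert cost_bar["width"] == pytest.approx(0.0, abs=1e-9)

    def test_parameter_isolation(self):
        """Widening one parameter's SE widens only its own bar."""
        base = ModelParameters()
        narrow = econ.tornado(linear_pipeline, base, PsaSpec(cost_se_frac=0.05))
        wide = econ.tornado(linear_pipeline, base, PsaSpec(cost_se_frac=0.20))
        n = narrow.set_index("parameter")["width"]
        w = wide.set_index("parameter")["width"]
        assert w["cost_trastuzumab_drug"] > n["cost_trastuzumab_drug"]
        assert w["emr_risk_ratio"] == pytest.approx(n["emr_risk_ratio"])

    def test_sorted_by_width(self):
        df = econ.tornado(linear_pipeline, ModelParameters())
        assert np.all(np.diff(df["width"]) <= 1e-12)


class TestScenarios:
    def test_biosimilar_price_cut(self):
        p = econ.SCENARIOS["trastuzumab_cost_minus_30pct"](ModelParameters())
        assert p.costs.trastuzumab_drug == pytest.approx(67_812.50 * 0.7)
        assert round(p.costs.trastuzumab_drug) == 47_469

    def test_scenario_table_runs_all(self):
        df = econ.run_scenarios(linear_pipeline, ModelParameters())
        assert set(df["scenario"]) == set(econ.SCENARIOS)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            econ.run_scenarios(linear_pipeline, ModelParameters(), {"bogus": 42})
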
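"""Mortality-input construction, calibration and hazard-ratio conversion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hercua import (
    EmrCurve,
    LifeTable,
    SubtypeSpec,
    TreatmentEffect,
    calibrate_subtype_emr,
    convert_os_hr_to_bc_rr,
    effective_rr,
    rate_to_annual_prob,
)
from hercua.survival import implied_rs5

from conftest import flat_emr, flat_life_table


class TestRateToAnnualProb:
    @pytest.mark.parametrize(
        "rate,expected",
        [(0.0, 0.0), (0.1, 0.0951626), (5.0, 0.9932621)],
    )
    def test_closed_form(self, rate, expected):
        assert rate_to_annual_prob(rate) == pytest.approx(expected, abs=1e-5)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            rate_to_annual_prob(-0.01)

    @given(st.floats(min_value=0, max_value=30))
    def test_bounded_and_monotone(self, rate):
        p = rate_to_annual_prob(rate)
        assert 0 <= p < 1
        assert rate_to_annual_prob(rate + 0.1) > p


class TestEffectiveRr:
    @pytest.mark.parametrize(
        "base,frac,expected",
        [(0.56, 1.0, 0.56), (0.56, 0.5, 0.78), (0.56, 0.75, 0.67)],
    )
    def test_benefit_fraction_scales_hazard_reduction(self, base, frac, expected):
        assert effective_rr(base, frac) == pytest.approx(expected)

    def test_zero_fraction_is_null_effect(self):
        assert effective_rr(0.4, 0.0) == 1.0


class TestCalibrateSubtypeEmr:
    def _specs(self, proportions, rs5):
        names = ["a", "b", "c", "d"][: len(proportions)]
        return [SubtypeSpec(n, p, r) for n, p, r in zip(names, proportions, rs5)]

    def test_identical_rs5_gives_unit_multipliers(self):
        emr = flat_emr(0.05)
        specs = self._specs([0.4, 0.3, 0.2, 0.1], [0.8, 0.8, 0.8, 0.8])
        out = calibrate_subtype_emr(emr, specs)
        assert [s.emr_multiplier for s in out] == pytest.approx([1.0] * 4, abs=1e-9)

    def test_two_subtype_toy_matches_closed_form(self):
        # Overall 5-y cumulative excess hazard H = 0.2231 (S(5) = 0.80);
        # rs5 targets 0.9 / 0.7 with equal proportions solve in closed form:
        # S_1 = 0.9, S_2 = 0.7 (mean 0.8 conserved, ratio 9/7), so
        # k_i = -ln(S_i) / H.
        h_annual = 0.2231 / 5
        emr = flat_emr(h_annual)
        h5 = emr.cumulative(5)
        specs = [SubtypeSpec("s1", 0.5, 0.9), SubtypeSpec("s2", 0.5, 0.7)]
        out = calibrate_subtype_emr(emr, specs)
        k = np.array([s.emr_multiplier for s in out])
        s5 = np.exp(-k * h5)
        assert s5[0] / s5[1] == pytest.approx(0.9 / 0.7, abs=1e-9)
        assert 0.5 * s5.sum() == pytest.approx(np.exp(-h5), abs=1e-10)
        # closed-form oracle: common factor x = exp(-H)/mean(rs5), k = -ln(x rs5)/H
        x = np.exp(-h5) / 0.8
        assert k == pytest.approx(-np.log(x * np.array([0.9, 0.7])) / h5, rel=1e-6)

    @given(
        rs5=st.lists(st.floats(min_value=0.55, max_value=0.95), min_size=4, max_size=4),
        props=st.lists(st.floats(min_value=0.05, max_value=1.0), min_size=4, max_size=4),
    )
    def test_round_trip_recovers_multipliers(self, rs5, props):
        """Calibrated multipliers -> implied rs5 -> recalibration recovers the
        same multipliers (the implied rs5 set is conserving by construction)."""
        from hypothesis import assume

        emr = flat_emr(0.04)
        props = np.array(props) / np.sum(props)
        specs = [
            SubtypeSpec(f"s{i}", float(p), float(r))
            for i, (p, r) in enumerate(zip(props, rs5))
        ]
        try:
            out1 = calibrate_subtype_emr(emr, specs)
        except ValueError:
            assume(False)  # infeasible draw
        k1 = np.array([s.emr_multiplier for s in out1])
        rs5_implied = implied_rs5(emr, k1)
        specs2 = [
            SubtypeSpec(f"s{i}", float(p), float(r))
            for i, (p, r) in enumerate(zip(props, rs5_implied))
        ]
        k2 = np.array([s.emr_multiplier for s in calibrate_subtype_emr(emr, specs2)])
        np.testing.assert_allclose(k2, k1, atol=1e-6)

    def test_conservation_of_weighted_relative_survival(self, inputs):
        h5 = inputs.emr.cumulative(5)
        p = np.array([s.proportion for s in inputs.subtypes])
        k = np.array([s.emr_multiplier for s in inputs.subtypes])
        assert float(p @ np.exp(-k * h5)) == pytest.approx(np.exp(-h5), abs=1e-8)

    def test_prognosis_ordering(self, inputs):
        k = [s.emr_multiplier for s in inputs.subtypes]
        assert k == sorted(k)  # ER+/PR+ lowest excess hazard, ER-/PR- highest

    def test_infeasible_rs5_reported(self):
        emr = flat_emr(0.001)  # H5 tiny: ratio 0.9/0.2 unattainable with k > 0
        specs = [SubtypeSpec("s1", 0.5, 0.9), SubtypeSpec("s2", 0.5, 0.2)]
        with pytest.raises(ValueError, match="infeasible"):
            calibrate_subtype_emr(emr, specs)


class TestConvertOsHrToBcRr:
    def test_zero_background_mortality_limit(self):
        lt = flat_life_table(0.0)
        emr = flat_emr(0.05)
        for hr in (0.3, 0.63, 0.9):
            assert convert_os_hr_to_bc_rr(hr, lt, emr, 50, 8) == pytest.approx(hr, abs=1e-9)

    def test_always_below_hr_and_monotone_in_background(self):
        emr = flat_emr(0.05)
        hr = 0.63
        rhos = []
        for lam in (1.0, 2.0, 5.0):
            lt = flat_life_table(0.01 * lam)
            rho = convert_os_hr_to_bc_rr(hr, lt, emr, 50, 8)
            assert rho <= hr
            rhos.append(rho)
        assert rhos == sorted(rhos, reverse=True)

    def test_fixture_dilution_by_age(self, inputs):
        """Competing mortality barely dilutes the HR at young ages and
        substantially at older ages (published band pattern 0.63 -> 0.50)."""
        rho35 = convert_os_hr_to_bc_rr(0.63, inputs.life_table, inputs.emr, 35, 8)
        rho65 = convert_os_hr_to_bc_rr(0.63, inputs.life_table, inputs.emr, 65, 8)
        assert 0.60 < rho35 < 0.63
        assert 0.45 < rho65 < 0.58
        assert rho65 < rho35

    def test_infeasible_when_background_dominates(self):
        lt = flat_life_table(1.0)
        emr = flat_emr(1e-6)
        with pytest.raises(ValueError, match="infeasible"):
            convert_os_hr_to_bc_rr(0.5, lt, emr, 50, 8)


class TestContainers:
    def test_life_table_schema_round_trip(self, tmp_path, inputs):
        path = tmp_path / "lt.csv"
        inputs.life_table.to_csv(path)
        back = LifeTable.from_csv(path)
        np.testing.assert_allclose(back.rates, inputs.life_table.rates)

    def test_emr_round_trip_and_cure(self, tmp_path, inputs):
        path = tmp_path / "emr.csv"
        inputs.emr.to_csv(path)
        back = EmrCurve.from_csv(path)
        np.testing.assert_allclose(back.values, inputs.emr.values)
        assert back.rate_at(back.cure_year) == 0.0
        assert back.rate_at(back.cure_year + 10) == 0.0

    def test_life_table_rejects_gaps(self):
        with pytest.raises(ValueError, match="contiguous"):
            LifeTable(np.array([25, 27]), np.array([0.1, 0.1]))

    def test_treatment_effect_band_lookup(self):
        eff = TreatmentEffect()
        assert eff.rr_for_age(39.9) == 0.63
        assert eff.rr_for_age(45) == 0.62
        assert eff.rr_for_age(52) == 0.56
        assert eff.rr_for_age(60) == 0.50

    def test_treatment_effect_ordering_enforced(self):
        with pytest.raises(ValueError, match="non-increasing"):
            TreatmentEffect(
                rr_bc_by_age={"<40": 0.5, "40-49": 0.62, "50-59": 0.56, ">=60": 0.50}
            )
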
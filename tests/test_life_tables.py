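"""Schedule construction: adjustment ratios, former-smoker derivation,
residual mortality and the synthetic generator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quitcea.errors import ConfigurationError, DataConsistencyError
from quitcea.life_tables import (
    AGES, DISEASES,
    AdjustmentRatios, AllCauseMortalitySchedule, DiseaseMortalitySchedule,
    RelativeRiskSchedule, SyntheticTableParams,
    apply_adjustment_ratios, derive_female_rates, derive_former_smoker_rates,
    generate_synthetic_tables, load_tables, residual_matrix,
    residual_other_cause_mortality, save_tables,
)

from conftest import random_consistent_tables


class TestAdjustmentRatios:
    def test_unit_ratios_are_identity(self):
        disease, _, _ = random_consistent_tables(np.random.default_rng(0))
        out = apply_adjustment_ratios(disease, AdjustmentRatios())
        np.testing.assert_array_equal(out.probs, disease.probs)

    def test_direct_multiplication(self):
        disease = DiseaseMortalitySchedule()
        disease.probs[0, 0, 1, 0] = 0.002
        ratios = AdjustmentRatios(spatial={d: 1.2 for d in DISEASES},
                                  temporal={d: 0.9 for d in DISEASES})
        out = apply_adjustment_ratios(disease, ratios)
        assert out.probs[0, 0, 1, 0] == pytest.approx(0.00216, abs=1e-15)

    def test_elementwise_oracle(self):
        """Vectorized adjustment equals an independent per-entry loop."""
        rng = np.random.default_rng(42)
        disease, _, _ = random_consistent_tables(rng)
        ratios = AdjustmentRatios(
            spatial={d: rng.uniform(0.5, 1.5) for d in DISEASES},
            temporal={d: rng.uniform(0.5, 1.5) for d in DISEASES})
        out = apply_adjustment_ratios(disease, ratios)
        for _ in range(10):
            gi = rng.integers(2)
            ai = rng.integers(96)
            si = rng.integers(disease.n_status)
            di = rng.integers(3)
            expected = (disease.probs[gi, ai, si, di]
                        * ratios.spatial[DISEASES[di]] * ratios.temporal[DISEASES[di]])
            assert out.probs[gi, ai, si, di] == pytest.approx(min(expected, 1.0), rel=1e-14)

    def test_composition_equals_single_pass(self):
        """Applying spatial then temporal separately equals their product."""
        rng = np.random.default_rng(3)
        disease, _, _ = random_consistent_tables(rng)
        spatial = {d: rng.uniform(0.8, 1.3) for d in DISEASES}
        temporal = {d: rng.uniform(0.8, 1.3) for d in DISEASES}
        unit = {d: 1.0 for d in DISEASES}
        step1 = apply_adjustment_ratios(disease, AdjustmentRatios(spatial=spatial, temporal=unit))
        step2 = apply_adjustment_ratios(step1, AdjustmentRatios(spatial=unit, temporal=temporal))
        joint = apply_adjustment_ratios(disease, AdjustmentRatios(spatial=spatial, temporal=temporal))
        np.testing.assert_allclose(step2.probs, joint.probs, rtol=1e-14)

    def test_missing_disease_ratio_is_named(self):
        with pytest.raises(ConfigurationError, match="copd"):
            AdjustmentRatios(spatial={"lung_cancer": 1.0, "cvd": 1.0},
                             temporal={d: 1.0 for d in DISEASES})

    def test_clipping_at_one(self):
        disease = DiseaseMortalitySchedule()
        disease.probs[:, :, 1, 0] = 0.9
        ratios = AdjustmentRatios(spatial={d: 2.0 for d in DISEASES},
                                  temporal={d: 1.0 for d in DISEASES})
        out = apply_adjustment_ratios(disease, ratios)
        assert out.probs.max() == 1.0


class TestFormerSmokerDerivation:
    def test_unit_rr_makes_former_equal_never(self):
        disease, _, _ = random_consistent_tables(np.random.default_rng(1))
        rr = RelativeRiskSchedule(rr={d: (1.0,) * 5 for d in DISEASES})
        out = derive_former_smoker_rates(disease, rr)
        for k in range(5):
            np.testing.assert_array_equal(out.probs[:, :, 2 + k, :], out.probs[:, :, 0, :])

    def test_band_lookup_and_multiplication(self):
        disease = DiseaseMortalitySchedule()
        disease.probs[0, 10, 0, 0] = 0.001   # never
        disease.probs[0, 10, 1, 0] = 0.01    # current (cap not binding)
        rr = RelativeRiskSchedule(rr={
            "lung_cancer": (3.0, 2.5, 2.0, 1.5, 1.0),
            "copd": (1.0,) * 5, "cvd": (1.0,) * 5})
        out = derive_former_smoker_rates(disease, rr)
        assert rr.band_index(4) == 1  # four years since quitting -> band [3, 6)
        assert out.probs[0, 10, 2 + 1, 0] == pytest.approx(0.0025)

    def test_duration_below_one_uses_first_band(self):
        rr = RelativeRiskSchedule(rr={d: (2.0, 1.5, 1.2, 1.1, 1.0) for d in DISEASES})
        assert rr.band_index(0.2) == 0
        assert rr.band_index(40) == 4

    def test_former_capped_at_current(self):
        disease = DiseaseMortalitySchedule()
        disease.probs[0, 0, 0, 0] = 0.01
        disease.probs[0, 0, 1, 0] = 0.015  # current below never x RR
        rr = RelativeRiskSchedule(rr={"lung_cancer": (3.0, 1.0, 1.0, 1.0, 1.0),
                                      "copd": (1.0,) * 5, "cvd": (1.0,) * 5})
        out = derive_former_smoker_rates(disease, rr)
        assert out.probs[0, 0, 2, 0] == pytest.approx(0.015)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_former_rates_monotone_in_duration(self, seed):
        """Non-increasing RR bands imply former risk non-increasing in d."""
        disease, _, rr = random_consistent_tables(np.random.default_rng(seed))
        out = derive_former_smoker_rates(disease, rr)
        out.validate()
        former = out.probs[:, :, 2:, :]
        assert np.all(np.diff(former, axis=2) <= 1e-15)

    def test_empty_band_list_rejected(self):
        with pytest.raises(ConfigurationError):
            RelativeRiskSchedule(bands=())


class TestFemaleDerivation:
    def test_unit_ratio_identity(self):
        disease, _, _ = random_consistent_tables(np.random.default_rng(5))
        out = derive_female_rates(disease, AdjustmentRatios())
        np.testing.assert_array_equal(out.probs[1], out.probs[0])

    def test_lung_ratio_applied(self):
        disease = DiseaseMortalitySchedule()
        disease.probs[0, 0, 1, 0] = 0.004
        out = derive_female_rates(disease, AdjustmentRatios(female_male_lung_ratio=0.5))
        assert out.probs[1, 0, 1, 0] == pytest.approx(0.002)

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(11)
        disease, _, _ = random_consistent_tables(rng)
        ratios = AdjustmentRatios(female_male_lung_ratio=0.4,
                                  female_male_other={"copd": 0.7, "cvd": 1.1})
        out = derive_female_rates(disease, ratios)
        g = {"lung_cancer": 0.4, "copd": 0.7, "cvd": 1.1}
        for _ in range(10):
            ai, si, di = rng.integers(96), rng.integers(7), rng.integers(3)
            expected = disease.probs[0, ai, si, di] * g[DISEASES[di]]
            assert out.probs[1, ai, si, di] == pytest.approx(expected, rel=1e-14)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ConfigurationError):
            AdjustmentRatios(female_male_lung_ratio=0.0)


class TestResidualMortality:
    def test_zero_disease_gives_allcause(self):
        disease = DiseaseMortalitySchedule()
        all_cause = AllCauseMortalitySchedule(probs=np.full((2, 96), 0.02))
        res = residual_other_cause_mortality(all_cause, disease, "current")
        np.testing.assert_array_equal(res, all_cause.probs)

    def test_arithmetic(self):
        disease = DiseaseMortalitySchedule()
        disease.probs[0, 0, 1, :] = (0.002, 0.001, 0.003)
        all_cause = AllCauseMortalitySchedule(probs=np.full((2, 96), 0.010))
        res = residual_other_cause_mortality(all_cause, disease, "current")
        assert res[0, 0] == pytest.approx(0.004)

    def test_conservation_reconstructs_allcause(self):
        """residual + disease-specific sum reproduces all-cause at every key."""
        disease, all_cause, _ = random_consistent_tables(np.random.default_rng(8))
        per_status = residual_matrix(all_cause, disease)
        for si in range(disease.n_status):
            recon = per_status[:, :, si] + disease.probs[:, :, si, :].sum(axis=2)
            np.testing.assert_allclose(recon, all_cause.probs, rtol=0, atol=1e-15)

    def test_negative_residual_names_key(self):
        disease = DiseaseMortalitySchedule()
        disease.probs[1, 30, 1, 0] = 0.5
        all_cause = AllCauseMortalitySchedule(probs=np.full((2, 96), 0.01))
        with pytest.raises(DataConsistencyError, match="female.*45"):
            residual_other_cause_mortality(all_cause, disease, "current")


class TestSyntheticGenerator:
    def test_deterministic_given_seed(self):
        params = SyntheticTableParams(seed=123, jitter=0.1)
        a = generate_synthetic_tables(params)
        b = generate_synthetic_tables(params)
        np.testing.assert_array_equal(a[0].probs, b[0].probs)
        np.testing.assert_array_equal(a[1].probs, b[1].probs)
        assert a[2].rr == b[2].rr

    def test_invariants_hold(self):
        disease, all_cause, rr = generate_synthetic_tables(SyntheticTableParams())
        disease.validate()
        all_cause.validate(disease)
        # age-increasing all-cause mortality until the late-life cap
        assert np.all(np.diff(all_cause.probs, axis=1) >= 0)

    def test_zero_shares_degenerate(self):
        params = SyntheticTableParams(disease_shares=(0.0, 0.0, 0.0))
        disease, all_cause, _ = generate_synthetic_tables(params)
        assert np.all(disease.probs == 0.0)
        res = residual_other_cause_mortality(all_cause, disease, "never")
        np.testing.assert_array_equal(res, all_cause.probs)

    def test_life_expectancy_calibration(self):
        """Never-smoker life table integrates to the target LE at age 20."""
        params = SyntheticTableParams()
        _, all_cause, _ = generate_synthetic_tables(params)
        for gi, target in enumerate(params.target_le_at_20):
            q = all_cause.probs[gi, AGES >= 20][:-1]
            surv = np.concatenate([[1.0], np.cumprod(1.0 - q)])
            assert surv.sum() == pytest.approx(target, abs=1e-6)

    def test_infeasible_params_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticTableParams(disease_shares=(0.5, 0.4, 0.2))
        with pytest.raises(ConfigurationError):
            SyntheticTableParams(current_multipliers=(0.5, 1.0, 1.0))
        with pytest.raises(ConfigurationError):
            SyntheticTableParams(max_annual_prob=0.9)  # row infeasible at cap

    def test_csv_round_trip(self, tmp_path):
        disease, all_cause, rr = generate_synthetic_tables(SyntheticTableParams(seed=4))
        paths = [tmp_path / f for f in ("disease.csv", "allcause.csv", "rr.csv")]
        save_tables(disease, all_cause, rr, *paths)
        d2, a2, r2 = load_tables(*paths)
        np.testing.assert_allclose(d2.probs, disease.probs, rtol=0, atol=1e-15)
        np.testing.assert_allclose(a2.probs, all_cause.probs, rtol=0, atol=1e-15)
        assert r2.bands[:-1] == rr.bands[:-1]
        for d in DISEASES:
            np.testing.assert_allclose(r2.rr[d], rr.rr[d], rtol=1e-15)
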
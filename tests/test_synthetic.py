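import numpy as np
import pandas as pd
import pytest

from spectrum_effect.design import glp_design
from spectrum_effect.synthetic import (RECOVERY_ACTIVES, SimulationConfig,
                                       default_effect_matrix, null_benchmark,
                                       recovery_benchmark, simulate_fingerprints,
                                       simulate_pharmacology, simulate_study)


def direct_orientation(n=10):
    ids = ["WBV_5", "WBV_50", "WBV_200", "PV", "EAI",
           "RCEI", "ERI", "APTT", "PT", "MPAR"][:n]
    return {ix: "direct" for ix in ids}


def single_herb_config(**kw):
    attribution = np.zeros((13, 2))
    attribution[:, 0] = 1.0
    defaults = dict(attribution=attribution, fingerprint_noise_sd=0.0, seed=1)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestFingerprints:
    def test_noise_free_single_herb_reproduces_doses(self):
        config = single_herb_config()
        design = glp_design(9, (1, 4))
        fp = simulate_fingerprints(design, config)
        for col in fp.component_ids:
            assert fp.areas[col].tolist() == pytest.approx(list(range(1, 10)))

    def test_same_seed_same_tables(self):
        config = SimulationConfig(seed=11)
        design = glp_design(9, (1, 4))
        a = simulate_fingerprints(design, config)
        b = simulate_fingerprints(design, config)
        pd.testing.assert_frame_equal(a.areas, b.areas)

    def test_noise_free_two_herbs_exact_linear_combination(self):
        rng = np.random.default_rng(5)
        attribution = rng.uniform(0.2, 2.0, size=(13, 2))
        config = SimulationConfig(attribution=attribution,
                                  fingerprint_noise_sd=0.0, seed=2)
        design = glp_design(9, (1, 4))
        fp = simulate_fingerprints(design, config)
        doses = config.doses(design)
        _, residuals, _, _ = np.linalg.lstsq(doses, fp.areas.to_numpy(), rcond=None)
        assert np.allclose(residuals, 0.0, atol=1e-18)

    def test_dimension_mismatch_rejected(self):
        config = SimulationConfig(seed=0, n_herbs=2)
        with pytest.raises(ValueError, match="factors"):
            simulate_fingerprints(glp_design(9, (1, 2, 4)), config)

    def test_nonpositive_dose_rejected(self):
        config = SimulationConfig(seed=0, dose_offset=-5.0)
        with pytest.raises(ValueError, match="dose"):
            simulate_fingerprints(glp_design(9, (1, 4)), config)


class TestPharmacology:
    def test_null_effect_zero_noise_means_equal_baseline(self):
        config = SimulationConfig(effect_matrix=np.zeros((10, 13)),
                                  index_noise_sd=0.0,
                                  orientation=direct_orientation(), seed=3)
        study = simulate_study(config)
        means = study.pharmacology.values.groupby("group_id")[config.index_ids].mean()
        for sid in config.sample_ids:
            assert means.loc[sid].to_numpy() == pytest.approx(config.baseline)

    def test_single_active_zero_noise_forces_collinearity(self):
        B = np.zeros((10, 13))
        B[0, 3] = 2.0
        config = SimulationConfig(effect_matrix=B, index_noise_sd=0.0,
                                  fingerprint_noise_sd=0.0,
                                  orientation=direct_orientation(), seed=4)
        study = simulate_study(config)
        means = study.pharmacology.values.groupby("group_id")[config.index_ids].mean()
        s_means = means.loc[config.sample_ids, config.index_ids[0]]
        peak = study.fingerprints.areas["P4"]
        assert abs(np.corrcoef(s_means, peak)[0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_planted_effects_match_matrix_oracle(self):
        rng = np.random.default_rng(9)
        B = np.zeros((10, 13))
        B[rng.integers(0, 10, 8), rng.integers(0, 13, 8)] = rng.uniform(0.2, 1.0, 8)
        config = SimulationConfig(effect_matrix=B, index_noise_sd=0.0,
                                  orientation=direct_orientation(), seed=5)
        study = simulate_study(config)
        means = study.pharmacology.values.groupby("group_id")[config.index_ids].mean()
        expected = config.baseline[None, :] + study.fingerprints.areas.to_numpy() @ B.T
        got = means.loc[config.sample_ids].to_numpy()
        assert np.allclose(got, expected, atol=1e-10)

    def test_inverse_orientation_emits_reciprocal_of_latent(self):
        config = SimulationConfig(effect_matrix=np.zeros((10, 13)),
                                  index_noise_sd=0.0, seed=6)
        study = simulate_study(config)
        means = study.pharmacology.values.groupby("group_id")[config.index_ids].mean()
        inverse_ix = next(ix for ix, o in config.orientation.items() if o == "inverse")
        assert means.loc["S1", inverse_ix] == pytest.approx(1.0 / config.baseline[0])

    def test_control_and_model_groups_present_with_offsets(self):
        config = SimulationConfig(effect_matrix=np.zeros((10, 13)),
                                  index_noise_sd=0.0,
                                  orientation=direct_orientation(), seed=7)
        study = simulate_study(config)
        means = study.pharmacology.values.groupby("group_id")[config.index_ids].mean()
        assert means.loc["control"].iloc[0] == pytest.approx(
            config.baseline[0] + config.control_offset)
        assert means.loc["model"].iloc[0] == pytest.approx(
            config.baseline[0] + config.model_offset)


class TestStudyBundle:
    def test_truth_lists_configured_active_set(self):
        study = simulate_study(SimulationConfig(seed=1))
        assert set(study.truth.active_components) == set(RECOVERY_ACTIVES)
        union = {c for m in study.truth.per_index_actives.values() for c in m}
        assert union == set(study.truth.active_components)

    def test_two_seeds_share_design_but_not_noise(self):
        a = simulate_study(SimulationConfig(seed=1))
        b = simulate_study(SimulationConfig(seed=2))
        assert np.array_equal(a.design.levels, b.design.levels)
        assert not np.allclose(a.fingerprints.areas, b.fingerprints.areas)

    def test_fixture_bundle_byte_identical_under_same_seed(self, tmp_path):
        for d in ("one", "two"):
            simulate_study(SimulationConfig(seed=13), out_dir=tmp_path / d)
        for name in ("design.csv", "fingerprints.csv", "pharmacology.csv", "truth.json"):
            assert (tmp_path / "one" / name).read_bytes() == \
                   (tmp_path / "two" / name).read_bytes()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="nonzero attribution"):
            SimulationConfig(attribution=np.zeros((13, 2)))
        with pytest.raises(ValueError, match="at least 2"):
            SimulationConfig(n_samples=1)
        with pytest.raises(ValueError, match="effect_matrix"):
            SimulationConfig(effect_matrix=np.zeros((3, 3)))

    def test_default_effect_matrix_has_four_disjoint_blocks(self):
        B = default_effect_matrix()
        active_cols = [k for k in range(13) if B[:, k].any()]
        assert len(active_cols) == 4
        # each index row is driven by exactly one active
        assert (np.count_nonzero(B, axis=1) == 1).all()

    def test_benchmark_configs_are_reproducible(self):
        a, b = recovery_benchmark(3), recovery_benchmark(3)
        assert np.array_equal(a.effect_matrix, b.effect_matrix)
        assert a.seed == b.seed == 3
        assert not null_benchmark(0).effect_matrix.any()
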
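import numpy as np
import pandas as pd
import pytest

from spectrum_effect.preprocess import (FingerprintTable, PharmacologyPanel,
                                        cluster_fingerprints, group_means,
                                        nondimensionalize, orient, tissue_ratio)


def panel_from(rows, orientation=None):
    return PharmacologyPanel(values=pd.DataFrame(rows), orientation=orientation or {})


class TestGroupMeans:
    def test_hand_arithmetic(self):
        panel = panel_from([
            {"group_id": "S1", "animal_id": f"a{i}", "APTT": v}
            for i, v in enumerate([1.0, 2.0, 3.0])
        ], orientation={"APTT": "direct"})
        stats = group_means(panel)
        assert stats.means.loc["S1", "APTT"] == pytest.approx(2.0)
        assert stats.sds.loc["S1", "APTT"] == pytest.approx(1.0)
        assert stats.counts["S1"] == 3

    def test_single_animal_identity(self):
        panel = panel_from([{"group_id": "S1", "animal_id": "a", "PT": 12.5}],
                           orientation={"PT": "direct"})
        assert group_means(panel).means.loc["S1", "PT"] == pytest.approx(12.5)

    def test_missing_value_is_hard_error(self):
        with pytest.raises(ValueError, match="missing"):
            panel_from([{"group_id": "S1", "animal_id": "a", "PT": np.nan}],
                       orientation={"PT": "direct"})

    def test_empty_panel_rejected(self):
        panel = panel_from([{"group_id": "S1", "animal_id": "a", "PT": 1.0}],
                           orientation={"PT": "direct"})
        panel.values = panel.values.iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            group_means(panel)


class TestOrient:
    def test_direct_only_unchanged(self):
        m = pd.DataFrame({"APTT": [1.0, 2.0], "PT": [3.0, 4.0]}, index=["S1", "S2"])
        out = orient(m, {"APTT": "direct", "PT": "direct"})
        pd.testing.assert_frame_equal(out, m.astype(float))

    def test_inverse_takes_reciprocal(self):
        m = pd.DataFrame({"WBV_5": [2.0, 4.0]}, index=["S1", "S2"])
        out = orient(m, {"WBV_5": "inverse"})
        assert out["WBV_5"].tolist() == [0.5, 0.25]

    def test_involution(self):
        m = pd.DataFrame({"WBV_5": [2.0, 4.0], "PT": [1.0, 3.0]}, index=["S1", "S2"])
        omap = {"WBV_5": "inverse", "PT": "direct"}
        pd.testing.assert_frame_equal(orient(orient(m, omap), omap), m.astype(float))

    def test_zero_under_inverse_rejected(self):
        m = pd.DataFrame({"WBV_5": [0.0, 4.0]}, index=["S1", "S2"])
        with pytest.raises(ValueError, match="nonpositive"):
            orient(m, {"WBV_5": "inverse"})


class TestNondimensionalize:
    def test_hand_arithmetic(self):
        m = pd.DataFrame({"x": [2.0, 4.0, 6.0]}, index=["S1", "S2", "S3"])
        out = nondimensionalize(m, ["S1", "S2", "S3"])
        assert out.values["x"].tolist() == [0.5, 1.0, 1.5]

    def test_constant_column_becomes_ones(self):
        m = pd.DataFrame({"x": [3.0, 3.0]}, index=["S1", "S2"])
        assert nondimensionalize(m, ["S1", "S2"]).values["x"].tolist() == [1.0, 1.0]

    def test_non_reference_rows_share_divisor(self):
        m = pd.DataFrame({"x": [5.0, 5.0, 10.0]}, index=["S1", "S2", "model"])
        out = nondimensionalize(m, ["S1", "S2"])
        assert out.values.loc["model", "x"] == pytest.approx(2.0)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.uniform(1, 5, (4, 3)),
                         index=["S1", "S2", "S3", "S4"], columns=list("abc"))
        once = nondimensionalize(m, list(m.index)).values
        twice = nondimensionalize(once, list(m.index)).values
        pd.testing.assert_frame_equal(once, twice)
        assert np.allclose(once.mean(axis=0), 1.0, atol=1e-12)

    def test_zero_column_mean_rejected(self):
        m = pd.DataFrame({"x": [1.0, -1.0]}, index=["S1", "S2"])
        with pytest.raises(ValueError, match="zero column mean"):
            nondimensionalize(m, ["S1", "S2"])


class TestClusterFingerprints:
    def test_identical_samples_merge_first(self):
        areas = pd.DataFrame(
            [[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]],
            index=["S1", "S2", "S3"], columns=["P1", "P2", "P3", "P4"],
            dtype=float)
        result = cluster_fingerprints(FingerprintTable(areas), cut=5.0)
        assert result.labels["S1"] == result.labels["S2"]
        assert result.labels["S1"] != result.labels["S3"]

    def test_proportional_pair_clusters_before_anticorrelated(self):
        areas = pd.DataFrame(
            [[1, 2, 3], [2, 4, 6], [3, 2, 1]],
            index=["S1", "S2", "S3"], columns=["P1", "P2", "P3"], dtype=float)
        result = cluster_fingerprints(FingerprintTable(areas), cut=5.0)
        # d(S1,S2) = 0 (r = 1), d(S1,S3) = 2 (r = -1)
        assert result.labels["S1"] == result.labels["S2"] != result.labels["S3"]
        assert result.n_classes == 2

    def test_invariant_to_uniform_rescaling_of_a_sample(self):
        rng = np.random.default_rng(3)
        areas = pd.DataFrame(rng.uniform(1, 9, (5, 6)),
                             index=[f"S{i}" for i in range(1, 6)],
                             columns=[f"P{i}" for i in range(1, 7)])
        base = cluster_fingerprints(FingerprintTable(areas), cut=8.0)
        scaled = areas.copy()
        scaled.loc["S2"] *= 7.3
        rescaled = cluster_fingerprints(FingerprintTable(scaled), cut=8.0)
        assert base.labels == rescaled.labels

    def test_rescaled_heights_top_out_at_25(self):
        rng = np.random.default_rng(4)
        areas = pd.DataFrame(rng.uniform(1, 9, (6, 5)),
                             index=[f"S{i}" for i in range(6)],
                             columns=[f"P{i}" for i in range(5)])
        result = cluster_fingerprints(FingerprintTable(areas))
        assert result.rescaled_heights.max() == pytest.approx(25.0)

    def test_constant_sample_vector_rejected(self):
        areas = pd.DataFrame([[1.0, 1.0], [1.0, 2.0]], index=["S1", "S2"],
                             columns=["P1", "P2"])
        with pytest.raises(ValueError, match="constant"):
            cluster_fingerprints(FingerprintTable(areas))


class TestTissueRatio:
    def test_hand_values(self):
        assert tissue_ratio(3.0, 2.0).median == pytest.approx(1.5)
        assert tissue_ratio(2.0, 2.0).median == pytest.approx(1.0)
        assert tissue_ratio(0.0, 2.0).median == pytest.approx(0.0)

    def test_vector_reduced_to_quartiles(self):
        result = tissue_ratio([1.0, 2.0, 3.0, 4.0], [1.0, 1.0, 1.0, 1.0])
        assert result.median == pytest.approx(2.5)
        assert result.q1 < result.median < result.q3

    def test_zero_blood_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            tissue_ratio(1.0, 0.0)


class TestFingerprintTable:
    def test_nonpositive_area_rejected_with_coordinates(self):
        areas = pd.DataFrame([[1.0, -2.0]], index=["S1"], columns=["P1", "P2"])
        with pytest.raises(ValueError, match="P2"):
            FingerprintTable(areas)

    def test_csv_round_trip(self, tmp_path):
        areas = pd.DataFrame([[1.5, 2.5], [3.5, 4.5]], index=["S1", "S2"],
                             columns=["P1", "P2"])
        fp = FingerprintTable(areas)
        fp.to_csv(tmp_path / "fp.csv")
        back = FingerprintTable.from_csv(tmp_path / "fp.csv")
        pd.testing.assert_frame_equal(back.areas, fp.areas, check_names=False)

    def test_panel_requires_complete_orientation(self):
        with pytest.raises(ValueError, match="orientation"):
            panel_from([{"group_id": "S1", "animal_id": "a", "PT": 1.0, "XX": 2.0}],
                       orientation={"PT": "direct"})
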
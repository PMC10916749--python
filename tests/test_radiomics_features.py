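"""Discretization, first-order features and texture feature formulas."""

import numpy as np
import pytest

from petrad.grids import VolumeGrid
from petrad.radiomics import (
    ExtractionConfig,
    discretize,
    extract_all,
    feature_manifest,
    first_order_features,
    first_order_names,
    texture_names,
)
from petrad.radiomics.discretize import BinnedVolume
from petrad.radiomics.features import (
    glcm_features,
    ngldm_feature_dependence_count_nonuniformity,
    ngldm_feature_low_dep_low_gray_emphasis,
    ngtdm_features,
)
from petrad.radiomics.matrices import TextureMatrix, glcm, ngldm, ngtdm


class TestDiscretize:
    def test_constant_volume_all_level_one(self):
        vol = VolumeGrid(np.full((6, 6, 6), 4.2))
        mask = np.ones((6, 6, 6), bool)
        b = discretize(vol, mask, 32)
        assert (b.levels[mask] == 1).all()

    def test_maximum_clamped_to_top_bin(self, random_volume):
        vol, mask = random_volume
        b = discretize(vol, mask, 32)
        at_max = mask & (vol.data == vol.data[mask].max())
        assert (b.levels[at_max] == 32).all()
        assert b.levels[mask].min() >= 1

    def test_known_bin_assignment(self):
        # min=0, max=32, 32 bins: x=2.5 -> floor(2.5) + 1 = 3
        data = np.zeros((1, 1, 4))
        data[0, 0] = [0.0, 2.5, 31.0, 32.0]
        b = discretize(VolumeGrid(data), np.ones((1, 1, 4), bool), 32)
        assert list(b.levels[0, 0]) == [1, 3, 32, 32]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discretize(VolumeGrid(np.ones((4, 4, 4))), np.zeros((4, 4, 4), bool), 32)

    def test_scale_invariance(self, random_volume):
        vol, mask = random_volume
        a = discretize(vol, mask, 32).levels
        b = discretize(VolumeGrid(vol.data * 17.3), mask, 32).levels
        np.testing.assert_array_equal(a, b)


class TestFirstOrder:
    def test_count_is_79(self, random_volume):
        vol, mask = random_volume
        feats = first_order_features(vol, mask)
        assert len(feats) == 79
        assert tuple(feats) == first_order_names()

    def test_maximum(self):
        data = np.zeros((1, 1, 3))
        data[0, 0] = [1.0, 2.0, 9.0]
        feats = first_order_features(VolumeGrid(data), np.ones((1, 1, 3), bool))
        assert feats["firstorder.stat_maximum"] == 9.0
        assert feats["firstorder.stat_minimum"] == 1.0

    def test_interquartile_range_linear_interpolation(self):
        data = np.arange(1, 101, dtype=float).reshape(1, 10, 10)
        feats = first_order_features(VolumeGrid(data), np.ones((1, 10, 10), bool))
        assert feats["firstorder.stat_interquartile_range"] == pytest.approx(49.5)

    def test_moments_match_direct_formulas(self, random_volume):
        vol, mask = random_volume
        feats = first_order_features(vol, mask)
        x = vol.data[mask]
        assert feats["firstorder.stat_mean"] == pytest.approx(x.mean())
        assert feats["firstorder.stat_variance"] == pytest.approx(x.var())
        assert feats["firstorder.stat_energy"] == pytest.approx((x**2).sum())
        assert feats["firstorder.stat_root_mean_square"] == pytest.approx(
            np.sqrt((x**2).mean())
        )

    def test_morphology_voxel_counting(self):
        # a single 2x2x2 cube of 2mm voxels: volume 64 mm^3, 24 faces
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 2:4, 2:4] = True
        vol = VolumeGrid(np.ones((6, 6, 6)), (2.0, 2.0, 2.0))
        feats = first_order_features(vol, mask)
        assert feats["firstorder.morph_voxel_count"] == 8
        assert feats["firstorder.morph_volume_mm3"] == pytest.approx(64.0)
        assert feats["firstorder.morph_surface_area_mm2"] == pytest.approx(24 * 4.0)


class TestTextureFeatureFormulas:
    def _worked_ngldm(self):
        lev = np.array([[1, 1], [1, 2]], dtype=np.int32).reshape(2, 2, 1)
        return ngldm(BinnedVolume(lev, 2, lev > 0), alpha=0)

    def test_dn_worked_example(self):
        assert ngldm_feature_dependence_count_nonuniformity(self._worked_ngldm()) == 2.5

    def test_ldlgle_worked_example(self):
        val = ngldm_feature_low_dep_low_gray_emphasis(self._worked_ngldm())
        assert val == pytest.approx(0.1458333333)

    def test_dn_all_mass_one_column_equals_nz(self):
        counts = np.zeros((3, 4))
        counts[:, 2] = [5, 3, 2]  # all 10 voxels share dependence count 3
        m = TextureMatrix("ngldm", counts, 3, 10)
        assert ngldm_feature_dependence_count_nonuniformity(m) == 10.0

    def test_dn_even_split_is_nz_over_m(self):
        counts = np.zeros((1, 5))
        counts[0] = 4.0  # 20 voxels spread evenly over 5 columns
        m = TextureMatrix("ngldm", counts, 1, 20)
        assert ngldm_feature_dependence_count_nonuniformity(m) == pytest.approx(20 / 5)

    def test_ldlgle_extremes(self):
        counts = np.zeros((4, 4))
        counts[0, 0] = 7.0
        assert ngldm_feature_low_dep_low_gray_emphasis(
            TextureMatrix("ngldm", counts, 4, 7)
        ) == pytest.approx(1.0)
        counts = np.zeros((30, 30))
        counts[29, 29] = 7.0
        assert ngldm_feature_low_dep_low_gray_emphasis(
            TextureMatrix("ngldm", counts, 30, 7)
        ) < 2e-6

    def test_uniform_volume_glcm_degenerates(self):
        lev = np.ones((4, 4, 4), dtype=np.int32)
        feats = glcm_features(glcm(BinnedVolume(lev, 1, lev > 0)))
        assert feats["angular_second_moment"] == 1.0
        assert feats["contrast"] == 0.0
        assert np.isnan(feats["correlation"])

    def test_uniform_volume_ngtdm_coarseness_capped_busyness_nan(self):
        from petrad.radiomics.features import COARSENESS_CAP

        lev = np.ones((4, 4, 4), dtype=np.int32)
        feats = ngtdm_features(ngtdm(BinnedVolume(lev, 1, lev > 0)))
        assert feats["coarseness"] == COARSENESS_CAP
        assert np.isnan(feats["busyness"])


class TestExtractAll:
    def test_feature_count_conservation(self, random_volume):
        vol, mask = random_volume
        fv = extract_all(vol, mask)
        assert len(fv) == 215
        names = list(fv.index)
        assert sum(n.startswith("firstorder.") for n in names) == 79
        assert sum(not n.startswith("firstorder.") for n in names) == 136
        assert tuple(names) == feature_manifest()

    def test_manifest_contains_study_selected_features(self):
        manifest = feature_manifest()
        for required in (
            "firstorder.stat_maximum",
            "firstorder.stat_interquartile_range",
            "ngldm.dependence_count_non_uniformity",
            "ngldm.low_dependence_low_grey_level_emphasis",
        ):
            assert required in manifest

    def test_texture_family_sizes(self):
        names = texture_names()
        by_family = {}
        for n in names:
            by_family.setdefault(n.split(".")[0], []).append(n)
        assert {k: len(v) for k, v in by_family.items()} == {
            "glcm": 50, "glrlm": 32, "glszm": 16, "gldzm": 16, "ngldm": 17, "ngtdm": 5,
        }

    def test_scaling_invariance(self, random_volume):
        vol, mask = random_volume
        a = extract_all(vol, mask)
        b = extract_all(VolumeGrid(vol.data * 3.7, vol.voxel_size_mm), mask)
        # intensity-carrying features scale; everything downstream of
        # discretization or global-mean scaling must not change
        scale_free = [n for n in a.index if not n.startswith("firstorder.")]
        np.testing.assert_allclose(a[scale_free], b[scale_free], rtol=1e-9)

    def test_axis_permutation_invariance(self, rng):
        """Merged-3D texture features are invariant to axis permutation
        for isotropic voxels."""
        data = np.abs(rng.normal(1, 0.3, (10, 10, 10))) + 0.1
        mask = np.ones((10, 10, 10), bool)
        a = extract_all(VolumeGrid(data), mask)
        b = extract_all(VolumeGrid(data.transpose(1, 2, 0)), mask)
        texture = [n for n in a.index if not n.startswith("firstorder.")]
        np.testing.assert_allclose(a[texture], b[texture], rtol=1e-9)

    def test_deterministic(self, random_volume):
        vol, mask = random_volume
        pd_a = extract_all(vol, mask)
        pd_b = extract_all(vol, mask)
        assert pd_a.equals(pd_b)

    def test_empty_mask_rejected(self, random_volume):
        vol, _ = random_volume
        with pytest.raises(ValueError):
            extract_all(vol, np.zeros(vol.shape, bool))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ExtractionConfig(n_bins=1)
        with pytest.raises(ValueError):
            ExtractionConfig(aggregation="nope")
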
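"""Radiomic feature extraction: counts, analytic shapes, matrix oracles."""

import numpy as np
import pytest

from habitatomics import features as ft
from oracles import (
    glcm_brute,
    gldm_brute,
    glrlm_brute,
    glszm_brute,
    ngtdm_brute,
)


@pytest.fixture(scope="module")
def small_random():
    """Tiny discretized volume (4 levels, 5x5x5) with a ragged mask."""
    rng = np.random.default_rng(7)
    levels = rng.integers(1, 5, size=(5, 5, 5))
    mask = rng.uniform(size=(5, 5, 5)) > 0.2
    levels = np.where(mask, levels, 0)
    return levels, mask, 4


class TestCounts:
    def test_family_cardinalities(self):
        assert len(ft.SHAPE_FEATURES) == 14
        assert len(ft.FIRSTORDER_FEATURES) == 18
        counts = {k: len(v) for k, v in ft.TEXTURE_FAMILIES.items()}
        assert counts == {"glcm": 24, "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5}
        assert sum(counts.values()) == 75

    def test_original_and_wavelet_feature_totals(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 25, (12, 12, 12))
        mask = np.zeros((12, 12, 12), bool)
        mask[2:10, 2:10, 2:10] = True
        out = ft.extract_region_features(img, mask, (1, 1, 1))
        assert len(out) == 14 + 18 + 75 == 107
        outw = ft.extract_region_features(img, mask, (1, 1, 1), wavelets=True)
        assert len(outw) == 14 + 93 * 9 == 851

    def test_names_unique(self):
        names = [
            ft.qualified_name(fam, f)
            for fam, feats in ft.TEXTURE_FAMILIES.items()
            for f in feats
        ]
        names += list(ft.SHAPE_FEATURES) + list(ft.FIRSTORDER_FEATURES)
        assert len(names) == len(set(names))


class TestDiscretize:
    def test_fixed_bin_width_level_count(self):
        img = np.arange(25.0).reshape(1, 5, 5)
        lv, L = ft.discretize(img, np.ones((1, 5, 5), bool), bin_width=5.0)
        assert L == 5
        assert lv.min() == 1 and lv.max() == 5

    def test_constant_image_single_level(self):
        lv, L = ft.discretize(np.full((2, 2, 2), 3.0), np.ones((2, 2, 2), bool))
        assert L == 1
        assert set(np.unique(lv)) == {1}

    def test_monotone_mapping(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        lv, _ = ft.discretize(img, mask, bin_width=0.3)
        a, b = img.ravel(), lv.ravel()
        order = np.argsort(a)
        assert np.all(np.diff(b[order]) >= 0)

    def test_invalid_parameters(self):
        img = np.zeros((2, 2, 2))
        mask = np.ones((2, 2, 2), bool)
        with pytest.raises(ValueError):
            ft.discretize(img, mask, bin_width=0.0)
        with pytest.raises(ValueError):
            ft.discretize(img, mask, mode="fixed_bin_count", bin_count=1)


class TestShape:
    def test_sphere_mesh_volume_within_2pct(self):
        n = 33
        c = (n - 1) / 2
        g = np.indices((n, n, n))
        mask = np.sqrt(((g - c) ** 2).sum(axis=0)) <= 10
        sh = ft.shape_features(mask, (1.0, 1.0, 1.0))
        analytic = 4 / 3 * np.pi * 10**3
        assert sh["MeshVolume"] == pytest.approx(analytic, rel=0.02)
        assert sh["Sphericity"] == pytest.approx(1.0, abs=0.1)
        assert sh["Elongation"] == pytest.approx(1.0, abs=0.05)

    def test_single_voxel_volume(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        sh = ft.shape_features(mask, (1.0, 1.0, 1.0))
        assert sh["VoxelVolume"] == 1.0

    def test_single_slice_mask_planar_degenerate(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 1:4, 1:4] = True
        with pytest.warns(UserWarning, match="single-slice"):
            sh = ft.shape_features(mask, (1.0, 1.0, 1.0))
        assert np.isnan(sh["MeshVolume"])

    def test_intensity_invariance_by_construction(self):
        # shape features take no intensity argument: extraction of the same
        # mask under different images yields identical shape values
        rng = np.random.default_rng(2)
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        a = ft.extract_region_features(rng.normal(size=(8, 8, 8)), mask, (1, 1, 1), families=("shape",))
        b = ft.extract_region_features(rng.normal(size=(8, 8, 8)) * 50, mask, (1, 1, 1), families=("shape",))
        assert a == b


class TestFirstOrder:
    def test_hand_arithmetic(self):
        vals = ft.firstorder_features(
            np.array([[[1.0, 2.0], [3.0, 4.0]]]), np.ones((1, 2, 2), bool)
        )
        assert vals["Mean"] == 2.5
        assert vals["Energy"] == 30.0
        assert vals["Range"] == 3.0

    def test_constant_voxels(self):
        vals = ft.firstorder_features(np.full((1, 1, 3), 2.0), np.ones((1, 1, 3), bool))
        assert vals["Mean"] == 2.0
        assert vals["Variance"] == 0.0
        assert vals["Entropy"] == 0.0
        assert vals["Uniformity"] == 1.0

    def test_affine_transform_of_mean_and_variance(self):
        rng = np.random.default_rng(3)
        img = rng.normal(size=(6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        base = ft.firstorder_features(img, mask)
        scaled = ft.firstorder_features(3.0 * img + 7.0, mask)
        assert scaled["Mean"] == pytest.approx(3 * base["Mean"] + 7)
        assert scaled["Variance"] == pytest.approx(9 * base["Variance"])

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            ft.firstorder_features(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool))


class TestTextureOracles:
    """Vectorized matrix builders vs naive enumeration on tiny volumes."""

    def test_glcm_matrix_matches_brute_force(self, small_random):
        levels, mask, L = small_random
        for off in ft.DIRECTIONS:
            np.testing.assert_array_equal(
                ft.glcm_matrix(levels, mask, L, off), glcm_brute(levels, mask, L, off)
            )

    def test_glrlm_matrix_matches_brute_force(self, small_random):
        levels, mask, L = small_random
        for off in ft.DIRECTIONS:
            np.testing.assert_array_equal(
                ft.glrlm_matrix(levels, mask, L, off), glrlm_brute(levels, mask, L, off)
            )

    def test_glszm_matrix_matches_brute_force(self, small_random):
        levels, mask, L = small_random
        np.testing.assert_array_equal(
            ft.glszm_matrix(levels, mask, L), glszm_brute(levels, mask, L)
        )

    def test_gldm_matrix_matches_brute_force(self, small_random):
        levels, mask, L = small_random
        np.testing.assert_array_equal(
            ft.gldm_matrix(levels, mask, L), gldm_brute(levels, mask, L)
        )

    def test_ngtdm_table_matches_brute_force(self, small_random):
        levels, mask, L = small_random
        n_i, s_i = ft.ngtdm_table(levels, mask, L)
        n_b, s_b = ngtdm_brute(levels, mask, L)
        np.testing.assert_array_equal(n_i, n_b)
        np.testing.assert_allclose(s_i, s_b, atol=1e-10)

    @pytest.mark.parametrize("family", ["glcm", "glrlm", "glszm", "gldm", "ngtdm"])
    def test_every_texture_feature_from_oracle_matrices(self, small_random, family):
        """Feature values from brute-force matrices equal the package's."""
        levels, mask, L = small_random
        got = ft.texture_features(levels, mask, L, family)
        if family == "glcm":
            per_dir = [
                ft.glcm_features_single(glcm_brute(levels, mask, L, off))
                for off in ft.DIRECTIONS
            ]
            want = {k: np.mean([d[k] for d in per_dir]) for k in per_dir[0]}
        elif family == "glrlm":
            n = int(mask.sum())
            per_dir = [
                ft._run_zone_features(glrlm_brute(levels, mask, L, off), n, "run")
                for off in ft.DIRECTIONS
            ]
            want = {k: np.mean([d[k] for d in per_dir]) for k in per_dir[0]}
        elif family == "glszm":
            want = ft._run_zone_features(glszm_brute(levels, mask, L), int(mask.sum()), "zone")
        elif family == "gldm":
            want = ft.gldm_features_from_matrix(gldm_brute(levels, mask, L))
        else:
            want = ft.ngtdm_features_from_table(*ngtdm_brute(levels, mask, L))
        for k, v in want.items():
            assert got[ft.qualified_name(family, k)] == pytest.approx(v, rel=1e-10), k

    def test_checkerboard_joint_entropy_hand_enumeration(self):
        """4x4x1 two-level checkerboard along the in-plane axis offset.

        Along (1, 0, 0) every horizontal neighbour pair alternates levels:
        12 ordered pairs, all (1,2) or (2,1) -> p = 1/2 each -> H = 1 bit.
        """
        board = np.indices((4, 4, 1)).sum(axis=0) % 2 + 1
        mask = np.ones((4, 4, 1), bool)
        P = ft.glcm_matrix(board, mask, 2, (1, 0, 0))
        assert P.sum() == 24  # 12 pairs, symmetrized
        feats = ft.glcm_features_single(P)
        assert feats["JointEntropy"] == pytest.approx(1.0)
        assert feats["Contrast"] == pytest.approx(1.0)

    def test_constant_image_cluster_shade_zero(self):
        lv = np.ones((3, 3, 3), dtype=np.int64)
        mask = np.ones((3, 3, 3), bool)
        feats = ft.texture_features(lv, mask, 1, "glcm")
        assert feats["ClusterShade"] == 0.0

    def test_cluster_shade_direct_sum(self, small_random):
        """GLCM ClusterShade equals the explicit third-moment triple sum."""
        levels, mask, L = small_random
        off = (0, 0, 1)
        P = glcm_brute(levels, mask, L, off)
        p = P / P.sum()
        mu_i = sum((i + 1) * p[i, j] for i in range(L) for j in range(L))
        mu_j = sum((j + 1) * p[i, j] for i in range(L) for j in range(L))
        want = sum(
            (i + 1 + j + 1 - mu_i - mu_j) ** 3 * p[i, j]
            for i in range(L)
            for j in range(L)
        )
        got = ft.glcm_features_single(ft.glcm_matrix(levels, mask, L, off))["ClusterShade"]
        assert got == pytest.approx(want, rel=1e-10)


class TestWavelets:
    def test_eight_bands_same_shape(self):
        img = np.random.default_rng(0).normal(size=(8, 8, 8))
        bands = ft.wavelet_bank(img)
        assert len(bands) == 8
        assert set(bands) == {
            "LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"
        }
        assert all(b.shape == img.shape for b in bands.values())

    def test_perfect_reconstruction(self):
        img = np.random.default_rng(1).normal(size=(12, 10, 8))
        rec = ft.wavelet_reconstruct(ft.wavelet_bank(img))
        assert np.abs(rec - img).max() < 1e-6 * max(1.0, np.abs(img).max())

    def test_constant_input_high_pass_bands_vanish(self):
        bands = ft.wavelet_bank(np.full((8, 8, 8), 5.0))
        for name, band in bands.items():
            if "H" in name:
                assert np.abs(band).max() < 1e-10

    def test_too_small_volume_raises(self):
        with pytest.raises(ValueError):
            ft.wavelet_bank(np.zeros((4, 4, 4)))


class TestDelta:
    def test_post_minus_pre(self):
        assert ft.delta_features({"a": 3.0}, {"a": 5.0}) == {"a": 2.0}

    def test_identical_inputs_zero(self):
        pre = {"a": 1.0, "b": -2.0}
        assert all(v == 0 for v in ft.delta_features(pre, dict(pre)).values())

    def test_name_mismatch_raises(self):
        with pytest.raises(ValueError, match="b"):
            ft.delta_features({"a": 1.0}, {"b": 1.0})

    def test_planted_volume_change_recovered(self):
        """A lesion losing a planted moderate-perfusion volume shows the
        loss in the delta of that subregion's mesh volume."""
        from habitatomics.synth import HabitatChange, PhantomSpec, simulate_imaging_pair

        spec = PhantomSpec(seed=5, noise_sd=0, adc_noise_sd=0)
        pre, post = simulate_imaging_pair(spec, HabitatChange(volume_scale=(1.0, 0.5, 1.0)))
        vol_pre = int((pre.truth_perfusion.labels == 2).sum())
        vol_post = int((post.truth_perfusion.labels == 2).sum())
        f_pre = ft.shape_features(pre.truth_perfusion.labels == 2, spec.spacing_mm)
        f_post = ft.shape_features(post.truth_perfusion.labels == 2, spec.spacing_mm)
        delta = ft.delta_features(f_pre, f_post)
        planted = vol_post - vol_pre
        assert planted < 0
        assert delta["VoxelVolume"] == pytest.approx(planted, rel=1e-12)
        assert delta["MeshVolume"] == pytest.approx(planted, rel=0.35)
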
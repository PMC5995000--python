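import itertools

import numpy as np
import pytest
from skimage.feature import graycomatrix, graycoprops

from octseg.features import (
    FEATURE_NAMES,
    FeatureVector,
    attenuation_fit,
    equalize_and_median,
    extract_features,
    glcm_features,
    local_stat_filters,
    moments,
    penetration_depth,
    shannon_entropy,
    tcn_encode,
    tcn_stats,
)
from octseg.io import BScan, LayerRegion
from octseg.phantom import LayerSpec, PhantomConfig, generate_bscan
from octseg.preprocess import SurfaceProfile

AXIAL_MM = 4.9e-3


class TestAttenuation:
    def test_exact_exponential_recovered(self):
        z = np.arange(200) * AXIAL_MM
        seg = np.exp(-2.0 * 2.0 * z)
        assert attenuation_fit(seg, AXIAL_MM) == pytest.approx(2.0, abs=0.01)

    def test_constant_segment_gives_zero(self):
        assert attenuation_fit(np.full(50, 0.3), AXIAL_MM) == pytest.approx(0.0)

    def test_invariant_to_positive_scaling(self):
        z = np.arange(100) * AXIAL_MM
        seg = 0.5 * np.exp(-2.0 * 1.3 * z)
        assert attenuation_fit(7.0 * seg, AXIAL_MM) == pytest.approx(
            attenuation_fit(seg, AXIAL_MM))

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            attenuation_fit(np.ones(4), AXIAL_MM)

    def test_nonpositive_values_warn(self):
        seg = np.linspace(1.0, -0.1, 20)
        with pytest.warns(UserWarning):
            attenuation_fit(seg, AXIAL_MM)


class TestPenetrationDepth:
    def test_analytic_one_over_e_point(self):
        # I = exp(-z / 0.5mm) -> 1/e depth = 0.5 mm
        z = np.arange(300) * AXIAL_MM
        depth, reached = penetration_depth(np.exp(-z / 0.5), AXIAL_MM)
        assert reached
        assert depth == pytest.approx(0.5, abs=AXIAL_MM / 2)

    def test_increasing_segment_flags_not_reached(self):
        depth, reached = penetration_depth(np.linspace(1, 2, 50), AXIAL_MM)
        assert not reached
        assert depth == pytest.approx(49 * AXIAL_MM)

    def test_zero_start_gives_zero(self):
        assert penetration_depth(np.zeros(10), AXIAL_MM) == (0.0, True)

    def test_invariant_to_positive_scaling(self):
        z = np.arange(120) * AXIAL_MM
        seg = np.exp(-z / 0.2)
        assert penetration_depth(3.0 * seg, AXIAL_MM)[0] == pytest.approx(
            penetration_depth(seg, AXIAL_MM)[0])


class TestEqualizeAndMoments:
    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 0.4)
        np.testing.assert_array_equal(equalize_and_median(img), img)

    def test_equalization_flattens_histogram(self, rng):
        img = rng.exponential(1.0, (200, 200))
        eq = equalize_and_median(img, median_kernel=1)
        cv = lambda v: np.histogram(v, 64)[0].std() / np.histogram(v, 64)[0].mean()
        assert cv(eq) < cv(img)

    def test_symmetric_values_have_zero_skewness(self):
        skew, _ = moments(np.array([-1.0, 0.0, 1.0]))
        assert skew == pytest.approx(0.0)

    def test_normal_sample_kurtosis_three(self, rng):
        _, kurt = moments(rng.normal(size=100_000))
        assert kurt == pytest.approx(3.0, abs=0.05)

    def test_matches_brute_force_moment_formula(self):
        v = np.array([0.0, 0.0, 0.0, 1.0])
        m = v.mean()
        skew_oracle = np.mean((v - m) ** 3) / np.mean((v - m) ** 2) ** 1.5
        skew, _ = moments(v)
        assert skew == pytest.approx(skew_oracle, abs=1e-12)

    def test_zero_variance_flagged_defaults(self):
        assert moments(np.full(10, 2.0)) == (0.0, 3.0)


class TestLocalFiltersAndEntropy:
    def test_constant_region_all_zero(self):
        std_map, range_map = local_stat_filters(np.full((8, 8), 0.7))
        assert std_map.max() == pytest.approx(0.0, abs=1e-7)
        assert range_map.max() == 0.0
        assert shannon_entropy(np.full(64, 0.7)) == 0.0

    def test_checkerboard_range_is_level_difference(self):
        board = np.indices((10, 10)).sum(axis=0) % 2 * 0.6
        _, range_map = local_stat_filters(board)
        assert np.all(range_map == 0.6)

    def test_uniform_256_levels_entropy_8_bits(self):
        v = np.repeat(np.arange(256), 4)
        assert shannon_entropy(v, bins=256) == pytest.approx(8.0)


class TestTcn:
    def test_constant_image_fully_homogeneous(self):
        tcn = tcn_encode(np.full((8, 8), 0.5), epsilon=0.01)
        coarse, homog = tcn_stats(tcn)
        assert coarse == 1.0 and homog == 1.0
        # every neighbour codes "within epsilon" (t_k = 1 for all k)
        assert np.all(tcn.codes == sum(3**k for k in range(8)))

    def test_continuous_noise_zero_coarseness_at_zero_epsilon(self, rng):
        tcn = tcn_encode(rng.random((20, 20)), epsilon=0.0)
        coarse, _ = tcn_stats(tcn)
        assert coarse == 0.0

    def test_blocky_texture_is_coarser_than_fine(self):
        # 1x1 checkerboard: 4 orthogonal neighbours differ, 4 diagonal are
        # equal -> coarseness 1/2.  4x4 blocks: per block 4 corners at 4/8,
        # 8 edge pixels at 5/8, 4 interior at 8/8 -> 11/16 > 1/2.
        fine = np.indices((32, 32)).sum(axis=0) % 2 * 1.0
        blocky = np.kron(np.indices((8, 8)).sum(axis=0) % 2, np.ones((4, 4)))
        c_fine, _ = tcn_stats(tcn_encode(fine, 0.01))
        c_blocky, _ = tcn_stats(tcn_encode(blocky, 0.01))
        assert c_fine == pytest.approx(0.5, abs=0.05)
        assert c_blocky == pytest.approx(11 / 16, abs=0.05)
        assert c_blocky > c_fine

    def test_too_small_region_rejected(self):
        with pytest.raises(ValueError):
            tcn_encode(np.ones((2, 5)), 0.1)


def _glcm_oracle(region, mask, levels):
    """Brute-force symmetric horizontal co-occurrence by pair enumeration."""
    vals = region[mask]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        return 0.0, 1.0
    q = np.clip(((region - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    pm = np.zeros((levels, levels))
    rows, cols = region.shape
    for r in range(rows):
        for c in range(cols - 1):
            if mask[r, c] and mask[r, c + 1]:
                pm[q[r, c], q[r, c + 1]] += 1
                pm[q[r, c + 1], q[r, c]] += 1
    pm /= pm.sum()
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    return float(np.sum((i - j) ** 2 * pm)), float(np.sum(pm**2))


class TestGlcm:
    def test_constant_region(self):
        contrast, energy, corr = glcm_features(np.full((6, 6), 0.2))
        assert contrast == 0.0 and energy == 1.0 and np.isnan(corr)

    def test_checkerboard_contrast(self):
        board = (np.indices((8, 8)).sum(axis=0) % 2).astype(float)
        contrast, energy, _ = glcm_features(board, levels=16)
        # every horizontal pair alternates between the two extreme levels
        assert contrast == pytest.approx(15.0**2)
        assert energy == pytest.approx(0.5)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(100):
            region = rng.random((8, 8))
            mask = rng.random((8, 8)) > 0.2
            if not np.any(mask[:, :-1] & mask[:, 1:]):
                continue
            contrast, energy, _ = glcm_features(region, mask, levels=16)
            oc, oe = _glcm_oracle(region, mask, 16)
            assert contrast == pytest.approx(oc, abs=1e-9)
            assert energy == pytest.approx(oe, abs=1e-9)

    def test_matches_skimage_on_rectangular_region(self, rng):
        """Independent cross-check against scikit-image on a full mask."""
        region = rng.integers(0, 16, size=(12, 12)).astype(float)
        contrast, energy, corr = glcm_features(region / 15.0, levels=16)
        g = graycomatrix(region.astype(np.uint8), [1], [0], levels=16,
                         symmetric=True, normed=True)
        assert contrast == pytest.approx(float(graycoprops(g, "contrast")[0, 0]), abs=1e-9)
        assert energy == pytest.approx(float(graycoprops(g, "ASM")[0, 0]), abs=1e-9)
        assert corr == pytest.approx(float(graycoprops(g, "correlation")[0, 0]), abs=1e-6)

    def test_energy_bounded_by_one(self, rng):
        for _ in range(10):
            _, energy, _ = glcm_features(rng.random((6, 6)), levels=16)
            assert 0.0 < energy <= 1.0


class TestExtractFeatures:
    @pytest.fixture
    def layer_setup(self):
        cfg = PhantomConfig(
            layers=[LayerSpec.from_class("dense_collagen", 80),
                    LayerSpec.from_class("normal_myocardium", 150)],
            width_px=120, depth_px=300, surface_profile="flat",
            surface_depth_px=30, speckle_on=True, seed=11,
        )
        bscan, truth = generate_bscan(cfg)
        surface = SurfaceProfile(truth.boundaries[0])
        region = LayerRegion(bscan.id, truth.boundaries[0], truth.boundaries[1], 0)
        return bscan, region, surface

    def test_vector_has_exactly_16_entries_in_frozen_order(self, layer_setup):
        bscan, region, surface = layer_setup
        fv = extract_features(bscan, region, surface)
        assert len(fv) == 16
        assert tuple(fv.values.keys()) == FEATURE_NAMES
        assert fv.to_array().shape == (16,)

    def test_wrong_keys_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector({"att_mean": 1.0})

    def test_dist_to_surface_is_half_thickness_for_surface_layer(self, layer_setup):
        bscan, region, surface = layer_setup
        fv = extract_features(bscan, region, surface)
        expected = 40 * bscan.axial_mm_per_px  # centre of an 80-px layer
        assert fv.values["dist_to_surface"] == pytest.approx(expected, rel=1e-6)

    def test_glcm_correlation_in_metadata_not_vector(self, layer_setup):
        bscan, region, surface = layer_setup
        fv = extract_features(bscan, region, surface)
        assert "glcm_correlation" in fv.metadata
        assert "glcm_correlation" not in fv.values

    def test_attenuation_separates_phantom_layers(self):
        """Two layers differing only in attenuation separate in att_mean."""
        per_class = {2.0: [], 4.0: []}
        for seed in range(10):
            for mu in (2.0, 4.0):
                spec = LayerSpec("normal_myocardium", 260, 0.6, mu, "smooth", 0)
                cfg = PhantomConfig(layers=[spec], width_px=100, depth_px=300,
                                    surface_depth_px=30, speckle_on=True, seed=seed)
                bscan, truth = generate_bscan(cfg)
                region = LayerRegion(bscan.id, truth.boundaries[0],
                                     truth.boundaries[0] + 200, 0)
                fv = extract_features(bscan, region, SurfaceProfile(truth.boundaries[0]))
                per_class[mu].append(fv.values["att_mean"])
        gap = abs(np.mean(per_class[4.0]) - np.mean(per_class[2.0]))
        spread = max(np.std(per_class[2.0]), np.std(per_class[4.0]))
        assert gap > 3 * spread
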
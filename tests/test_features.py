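"""The 45-feature grid: histogram statistics, quantization, GLCM
counting and statistics, checked against brute-force oracles and
scikit-image."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonetex.core import ContractError, DegenerateGLCMError, InvalidParameterError
from bonetex.features import (
    ALLOWED_LEVELS,
    FEATURE_NAMES,
    GLCM,
    GLCMConfig,
    compute_glcm,
    extract_features,
    glcm_autocorrelation,
    glcm_statistics,
    histogram_features,
    quantize,
    quantize_fixed,
)
from oracles import brute_glcm, brute_glcm_stats, brute_quantize


class TestHistogramFeatures:
    def test_small_sample_population_moments(self, roi_factory):
        roi = roi_factory([[1.0, 2.0], [3.0, 3.0]], np.array([[1, 1], [1, 0]], bool))
        mean, sd, *_ = histogram_features(roi)
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_symmetric_distribution_has_zero_skewness(self, roi_factory):
        vals = np.array([[1.0, 2.0, 3.0], [3.0, 4.0, 5.0]])
        mean, sd, skew, kurt, ent = histogram_features(roi_factory(vals))
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert kurt > 0

    def test_constant_roi_flagged_not_error(self, roi_factory):
        mean, sd, skew, kurt, ent = histogram_features(roi_factory(np.full((4, 4), 7.0)))
        assert (mean, sd, skew, kurt, ent) == (7.0, 0.0, 0.0, 0.0, 0.0)

    def test_uniform_two_values_entropy_one_bit(self, roi_factory):
        vals = np.array([[0.0, 1.0]] * 8)
        *_, ent = histogram_features(roi_factory(vals))
        assert ent == pytest.approx(1.0)

    def test_gaussian_kurtosis_near_three(self, rng, roi_factory):
        vals = rng.normal(size=(80, 80))
        mean, sd, skew, kurt, ent = histogram_features(roi_factory(vals))
        assert kurt == pytest.approx(3.0, abs=0.2)  # raw, not excess


class TestQuantize:
    def test_endpoints_clamp_to_first_and_last_bin(self, roi_factory):
        roi = roi_factory(np.array([[0.0, 100.0], [50.0, 25.0]]))
        q = quantize(roi, 16)
        assert q[0, 0] == 0 and q[0, 1] == 15

    def test_four_values_four_levels(self, roi_factory):
        # levels=4 is outside the allowed grid; emulate with the oracle at 16
        roi = roi_factory(np.array([[0.0, 1.0, 2.0, 3.0]]))
        q = quantize(roi, 16)
        assert list(q[0]) == [0, 5, 10, 15]

    def test_matches_per_pixel_formula_on_random_grid(self, rng, roi_factory):
        vals = rng.uniform(-100, 400, size=(8, 8))
        roi = roi_factory(vals)
        for levels in ALLOWED_LEVELS:
            assert np.array_equal(quantize(roi, levels), brute_quantize(vals, levels))

    def test_constant_roi_maps_to_bin_zero(self, roi_factory):
        q = quantize(roi_factory(np.full((3, 3), 5.0)), 32)
        assert np.all(q == 0)

    def test_shift_invariance_of_bins(self, rng, roi_factory):
        vals = rng.integers(0, 200, size=(10, 10)).astype(float)
        q1 = quantize(roi_factory(vals), 64)
        q2 = quantize(roi_factory(vals + 100.0), 64)
        assert np.array_equal(q1, q2)

    def test_fixed_window_mode_is_shared_across_subjects(self, roi_factory):
        a = quantize_fixed(roi_factory(np.array([[0.0, 100.0]])), 16, (0, 400))
        b = quantize_fixed(roi_factory(np.array([[100.0, 399.0]])), 16, (0, 400))
        assert a[0, 1] == b[0, 0] == 4

    def test_disallowed_levels_rejected(self, roi_factory):
        with pytest.raises(InvalidParameterError):
            quantize(roi_factory(np.zeros((2, 2))), 17)


class TestComputeGLCM:
    def test_two_pixel_grid_all_mass_at_pair(self):
        q = np.array([[3, 3]])
        mask = np.ones((1, 2), bool)
        g = compute_glcm(q, mask, GLCMConfig(direction="H", levels=16))
        assert g.matrix[3, 3] == pytest.approx(1.0)
        assert g.matrix.sum() == pytest.approx(1.0)

    def test_constant_disc_mass_on_diagonal(self, small_phantom_cfg):
        q = np.zeros((12, 12), dtype=int)
        mask = np.zeros((12, 12), bool)
        mask[3:9, 3:9] = True
        for cfg in (GLCMConfig("H", 16), GLCMConfig("V", 32)):
            g = compute_glcm(q, mask, cfg)
            assert g.matrix[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("direction", ["H", "V"])
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_exhaustive_pair_enumeration(self, rng, direction, symmetric):
        q = rng.integers(0, 16, size=(4, 4))
        mask = rng.random((4, 4)) > 0.2
        cfg = GLCMConfig(direction=direction, levels=16, symmetric=symmetric)
        try:
            got = compute_glcm(q, mask, cfg)
        except DegenerateGLCMError:
            pytest.skip("mask left no valid pair")
        want = brute_glcm(q, mask, 16, direction, symmetric=symmetric)
        np.testing.assert_allclose(got.matrix, want, atol=1e-15)

    def test_no_valid_pair_raises_degenerate(self):
        mask = np.array([[True, False], [False, True]])
        with pytest.raises(DegenerateGLCMError):
            compute_glcm(np.zeros((2, 2), int), mask, GLCMConfig("H", 16))

    def test_unquantized_grid_rejected(self):
        with pytest.raises(ContractError):
            compute_glcm(np.full((3, 3), 99, int), np.ones((3, 3), bool),
                         GLCMConfig("H", 16))

    def test_agrees_with_scikit_image_on_rectangular_mask(self, rng):
        from skimage.feature import graycomatrix

        img = rng.integers(0, 16, size=(12, 12)).astype(np.uint8)
        mask = np.ones_like(img, bool)
        ours_h = compute_glcm(img, mask, GLCMConfig("H", 16))
        ours_v = compute_glcm(img, mask, GLCMConfig("V", 16))
        sk = graycomatrix(img, [1], [0, np.pi / 2], levels=16,
                          symmetric=True, normed=True)
        np.testing.assert_allclose(ours_h.matrix, sk[:, :, 0, 0], atol=1e-12)
        np.testing.assert_allclose(ours_v.matrix, sk[:, :, 0, 1], atol=1e-12)


class TestGLCMStatistics:
    def test_single_diagonal_cell(self):
        p = np.zeros((16, 16))
        p[5, 5] = 1.0
        contrast, corr, energy, homo, var = glcm_statistics(
            GLCM(p, GLCMConfig("H", 16), 1)
        )
        assert contrast == 0 and energy == 1 and homo == 1 and var == 0
        assert corr == 0  # degenerate marginals

    def test_two_cell_closed_form(self):
        p = np.zeros((16, 16))
        p[0, 1] = p[1, 0] = 0.5
        contrast, corr, energy, homo, var = glcm_statistics(
            GLCM(p, GLCMConfig("H", 16), 2)
        )
        assert contrast == pytest.approx(1.0)
        assert homo == pytest.approx(0.5)
        assert energy == pytest.approx(0.5)
        assert corr == pytest.approx(-1.0)
        assert var == pytest.approx(0.25)

    def test_matches_double_loop_oracle_on_random_matrices(self, rng):
        for _ in range(20):
            p = rng.random((16, 16))
            p /= p.sum()
            got = glcm_statistics(GLCM(p, GLCMConfig("H", 16), 100))
            want = brute_glcm_stats(p)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_autocorrelation_matches_direct_sum(self, rng):
        p = rng.random((16, 16))
        p /= p.sum()
        want = sum(i * j * p[i, j] for i in range(16) for j in range(16))
        assert glcm_autocorrelation(GLCM(p, GLCMConfig("H", 16), 1)) == pytest.approx(
            want, abs=1e-12
        )

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ContractError):
            glcm_statistics(GLCM(np.ones((16, 16)), GLCMConfig("H", 16, normalize=False), 1))


class TestExtractFeatures:
    def test_grid_has_45_features_in_frozen_order(self, small_phantom_cfg):
        from bonetex.roi import extract_roi
        from bonetex.synthetic import generate_phantom

        roi = extract_roi(generate_phantom(1.0, small_phantom_cfg))
        fv = extract_features(roi)
        assert len(fv) == 45
        assert fv.names == FEATURE_NAMES
        assert FEATURE_NAMES[:5] == ("Mean", "SD", "Skewness", "Kurtosis", "Entropy")
        assert FEATURE_NAMES[5] == "Contrast_H_16"
        assert "Contrast_V_64" in FEATURE_NAMES
        assert FEATURE_NAMES[-1] == "Variance_V_128"

    def test_constant_roi_degenerate_values(self, roi_factory):
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        fv = extract_features(roi_factory(np.full((10, 10), 100.0), mask))
        for name in FEATURE_NAMES:
            if name.startswith("Contrast"):
                assert fv[name] == 0.0
            if name.startswith("Energy"):
                assert fv[name] == 1.0

    def test_determinism(self, rng, roi_factory):
        roi = roi_factory(rng.normal(100, 20, size=(16, 16)))
        a = extract_features(roi)
        b = extract_features(roi)
        assert np.array_equal(a.values, b.values)

    def test_energy_and_homogeneity_bounded_in_unit_interval(self, rng, roi_factory):
        fv = extract_features(roi_factory(rng.uniform(0, 400, size=(20, 20))))
        for name in FEATURE_NAMES:
            if name.startswith(("Energy", "Homogeneity")):
                assert 0.0 < fv[name] <= 1.0

    def test_transpose_swaps_horizontal_and_vertical_exactly(self, rng, roi_factory):
        vals = rng.uniform(0, 300, size=(14, 17))
        mask = rng.random((14, 17)) > 0.1
        fv = extract_features(roi_factory(vals, mask))
        fv_t = extract_features(roi_factory(vals.T, mask.T))
        for name in FEATURE_NAMES[5:]:
            stat, d, lv = name.split("_")
            swapped = f"{stat}_{'V' if d == 'H' else 'H'}_{lv}"
            assert fv[name] == fv_t[swapped]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_property_normalized_glcm_sums_to_one(seed):
    """Any normalized GLCM from a random masked grid sums to exactly 1."""
    r = np.random.default_rng(seed)
    q = r.integers(0, 16, size=(r.integers(4, 12), r.integers(4, 12)))
    mask = r.random(q.shape) > 0.15
    cfg = GLCMConfig(direction=("H", "V")[int(r.integers(2))], levels=16)
    try:
        g = compute_glcm(q, mask, cfg)
    except DegenerateGLCMError:
        return
    assert abs(g.matrix.sum() - 1.0) < 1e-12
    np.testing.assert_allclose(
        g.matrix, brute_glcm(q, mask, 16, cfg.direction), atol=1e-15
    )
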
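"""Scene-statistics unit tests: luminance conversion, contrast maps,
Weibull fits and the CE/SC summary statistics."""

import numpy as np
import pytest
from scipy import ndimage, stats

from scenecomplex.scenestats import (
    ContrastMap,
    SceneStatsConfig,
    compute_ce,
    compute_contrast_map,
    compute_sc,
    fit_weibull,
    scene_statistics,
    to_luminance,
)
from scenecomplex.synthetic import gen_texture


class TestToLuminance:
    @pytest.mark.parametrize(
        "value,expected",
        [(255, 1.0), (0, 0.0)],
        ids=["white", "black"],
    )
    def test_saturation_extremes(self, value, expected):
        img = np.full((40, 40, 3), value, dtype=np.uint8)
        assert np.allclose(to_luminance(img).values, expected)

    def test_pure_green_uses_rec601_weight(self):
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        img[:, :, 1] = 255
        assert np.allclose(to_luminance(img).values, 0.587)

    def test_uint16_scaling(self):
        img = np.full((40, 40), 65535, dtype=np.uint16)
        assert np.allclose(to_luminance(img).values, 1.0)

    @pytest.mark.parametrize(
        "bad",
        [
            np.zeros((0, 0)),
            np.zeros((4, 4, 5), dtype=np.uint8),
            np.zeros(16, dtype=np.uint8),
            np.full((8, 8), 2.0),
        ],
        ids=["empty", "five-channel", "one-dim", "float-out-of-range"],
    )
    def test_rejects_invalid_input(self, bad):
        with pytest.raises(ValueError):
            to_luminance(bad)


class TestContrastMap:
    def test_constant_image_has_zero_contrast(self):
        cm = compute_contrast_map(to_luminance(np.full((64, 64), 0.5)))
        assert np.allclose(cm.magnitudes, 0.0)

    def test_linearity_in_global_contrast(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 0.5, (64, 64))
        m1 = compute_contrast_map(to_luminance(img)).magnitudes
        m2 = compute_contrast_map(to_luminance(2.0 * img)).magnitudes
        assert np.allclose(m2, 2.0 * m1, rtol=1e-9)

    def test_step_edge_peak_on_edge_scales_with_height(self):
        # brute-force oracle: direct convolution with an explicit
        # Gaussian-derivative kernel must match the filter response
        img = np.zeros((64, 64))
        img[:, 32:] = 0.8
        cm = compute_contrast_map(to_luminance(img), scale=1.5)
        inner = cm.magnitudes[10:-10, 10:-10]
        peak_cols = np.argmax(inner, axis=1)
        assert np.all(np.isin(peak_cols + 10, (31, 32)))

        half = np.zeros((64, 64))
        half[:, 32:] = 0.4
        cm_half = compute_contrast_map(to_luminance(half), scale=1.5)
        assert np.allclose(cm_half.magnitudes, 0.5 * cm.magnitudes, rtol=1e-9)

        r = int(4.0 * 1.5 + 0.5)  # same truncation radius as the filter
        x = np.arange(-r, r + 1, dtype=float)
        g = np.exp(-0.5 * (x / 1.5) ** 2)
        g /= g.sum()
        dg = -x / 1.5**2 * g  # derivative of the normalised Gaussian
        gx_oracle = np.convolve(img[32], dg, mode="same")
        gx_filter = ndimage.gaussian_filter(
            to_luminance(img).values, 1.5, order=(0, 1), mode="nearest"
        )[32]
        # compare away from borders where padding differs
        assert np.allclose(gx_oracle[20:44], gx_filter[20:44], atol=1e-9)

    def test_rejects_too_small_image(self):
        with pytest.raises(ValueError):
            compute_contrast_map(to_luminance(np.zeros((40, 40)) + 0.5), scale=12.0)


class TestWeibullFit:
    def test_recovers_known_parameters(self):
        rng = np.random.default_rng(1)
        x = stats.weibull_min.rvs(1.5, scale=2.0, size=100_000, random_state=rng)
        fit = fit_weibull(x)
        assert abs(fit.beta - 2.0) / 2.0 < 0.02
        assert abs(fit.gamma - 1.5) / 1.5 < 0.02

    def test_exponential_is_weibull_shape_one(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(1.0, 100_000)
        fit = fit_weibull(x)
        assert abs(fit.gamma - 1.0) < 0.02

    def test_zeros_discarded_and_counted(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.weibull(1.5, 500), np.zeros(40)])
        fit = fit_weibull(x)
        assert fit.n == 500
        assert fit.n_zeros_discarded == 40

    def test_too_few_positive_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_weibull(np.concatenate([np.ones(50), np.zeros(1000)]))


class TestCeSc:
    def test_ce_zero_for_constant_and_linear_in_contrast(self):
        flat = ContrastMap(np.zeros((50, 50)), scale=1.5, border_margin=5)
        assert compute_ce(flat) == 0.0
        rng = np.random.default_rng(4)
        m = rng.uniform(0, 1, (50, 50))
        cm = ContrastMap(m, 1.5, 5)
        cm2 = ContrastMap(2 * m, 1.5, 5)
        assert np.isclose(compute_ce(cm2), 2 * compute_ce(cm), rtol=1e-12)

    def test_sc_constant_map_hits_epsilon_ceiling(self):
        cm = ContrastMap(np.full((50, 50), 3.0), 1.5, 5)
        assert np.isclose(compute_sc(cm), 3.0 / 1e-12)

    def test_sc_rejects_zero_map(self):
        with pytest.raises(ValueError):
            compute_sc(ContrastMap(np.zeros((50, 50)), 1.5, 5))

    def test_sc_invariant_to_global_contrast(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0.1, 0.5, (64, 64))
        for c in (0.5, 2.0):
            sc1 = compute_sc(compute_contrast_map(to_luminance(img)))
            sc2 = compute_sc(compute_contrast_map(to_luminance(c * img)))
            assert abs(sc2 - sc1) / sc1 < 1e-3

    def test_ce_linearity_under_rescaling(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(0.1, 0.5, (64, 64))
        ce1 = compute_ce(compute_contrast_map(to_luminance(img)))
        for c in (0.5, 2.0):
            ce2 = compute_ce(compute_contrast_map(to_luminance(c * img)))
            assert abs(ce2 - c * ce1) / (c * ce1) < 1e-9


class TestSceneStatistics:
    def test_white_noise_has_finite_positive_stats(self):
        rng = np.random.default_rng(7)
        st = scene_statistics(rng.uniform(0, 1, (64, 64)))
        assert st.ce > 0 and np.isfinite(st.sc)

    def test_deterministic_on_identical_input(self):
        img = gen_texture(30, seed=8)
        s1 = scene_statistics(img, SceneStatsConfig(fit_weibull=True))
        s2 = scene_statistics(img, SceneStatsConfig(fit_weibull=True))
        assert s1 == s2

    def test_cluttered_exceeds_sparse_in_ce_and_sc(self):
        # 20-seed majority vote: fragmentation raises both statistics
        wins_ce = wins_sc = 0
        for seed in range(20):
            sparse = scene_statistics(gen_texture(1, seed=seed))
            cluttered = scene_statistics(gen_texture(200, seed=1000 + seed))
            wins_ce += cluttered.ce > sparse.ce
            wins_sc += cluttered.sc > sparse.sc
        assert wins_ce > 10 and wins_sc > 10

    def test_multiscale_pooling_takes_maximum(self):
        img = gen_texture(50, seed=9)
        lum = to_luminance(img)
        single = compute_contrast_map(lum, scale=1.5)
        multi = compute_contrast_map(lum, scales=(1.5, 3.0))
        assert np.all(multi.magnitudes >= single.magnitudes - 1e-15)
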
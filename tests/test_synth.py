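"""Synthetic scene generator: determinism, physics, analytic ground truth."""

import numpy as np
import pytest
from scipy.integrate import quad

from flfaquant import ConfigError, WaveletParams, extract_rois
from flfaquant.analytic import band_avepix, band_response, row_window, trough_offset
from flfaquant.simulate import (
    Band,
    Background,
    SceneSpec,
    Spot,
    generate,
    scene_values,
    weak_signal_suite,
)


def _band_spec(**kw):
    defaults = dict(
        shape=(120, 400),
        background=Background(base=40.0, slope_x=6 / 400),
        bands=(Band(center=200, sigma=20.0, amplitude=30.0),),
        noise_sigma=2.0,
        seed=42,
    )
    defaults.update(kw)
    return SceneSpec(**defaults)


class TestGenerate:
    def test_same_spec_bit_identical(self):
        a, _ = generate(_band_spec())
        b, _ = generate(_band_spec())
        np.testing.assert_array_equal(a.data, b.data)

    def test_different_seed_differs(self):
        a, _ = generate(_band_spec(seed=1))
        b, _ = generate(_band_spec(seed=2))
        assert not np.array_equal(a.data, b.data)

    def test_quantized_and_in_range(self):
        img, _ = generate(_band_spec())
        assert np.array_equal(img.data, np.rint(img.data))
        assert img.data.min() >= 0 and img.data.max() <= 255
        img16, _ = generate(_band_spec(bit_depth=16))
        assert img16.max_gray == 65535

    def test_zero_amplitude_is_background_only(self):
        blank = _band_spec(bands=(Band(200, 20.0, 0.0),))
        ref = _band_spec(bands=())
        a, _ = generate(blank)
        b, _ = generate(ref)
        np.testing.assert_array_equal(a.data, b.data)
        assert extract_rois(a) == []

    def test_saturation_flagged_not_rejected(self):
        img, truth = generate(_band_spec(bands=(Band(200, 20.0, 250.0),)))
        assert truth.saturated
        assert img.data.max() == 255
        _, ok = generate(_band_spec())
        assert not ok.saturated

    def test_superposition_of_prequantization_scene(self):
        bands = (Band(120, 15.0, 10.0), Band(280, 18.0, 25.0))
        both = scene_values(_band_spec(bands=bands))
        first = scene_values(_band_spec(bands=bands[:1]))
        second = scene_values(_band_spec(bands=bands[1:]))
        background = scene_values(_band_spec(bands=()))
        np.testing.assert_allclose(both, first + second - background, atol=1e-9)

    def test_impulse_fraction(self):
        img, _ = generate(_band_spec(impulse_fraction=0.01, noise_sigma=0.0))
        frac = np.mean(img.data == 255)
        assert frac == pytest.approx(0.01, rel=0.3)

    def test_flat_top_band_profile(self):
        spec = _band_spec(bands=(Band(200, 5.0, 30.0, flat_width=30.0),),
                          noise_sigma=0.0, background=Background(base=40.0))
        scene = scene_values(spec)
        profile = scene[0] - 40.0
        assert profile[200] == pytest.approx(30.0, rel=1e-6)
        assert np.ptp(profile[185:216]) < 0.2  # flat within the plateau

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigError):
            _band_spec(bands=(Band(center=500, sigma=5.0, amplitude=1.0),))
        with pytest.raises(ConfigError):
            _band_spec(noise_sigma=-1.0)
        with pytest.raises(ConfigError):
            _band_spec(impulse_fraction=1.5)
        with pytest.raises(ConfigError):
            _band_spec(bit_depth=12)


class TestAnalyticGroundTruth:
    def test_response_matches_numerical_quadrature(self):
        """Closed-form detection response vs direct numerical integration
        of the truncated, mean-corrected kernel against the Gaussian."""
        params = WaveletParams()
        half = params.kernel_len // 2
        sigma_b, amp = 21.0, 17.0

        def numeric(tau):
            total = 0.0
            for s in params.scales:
                m = quad(lambda v: (1 - (v / s) ** 2) * np.exp(-(v**2) / (2 * s**2)),
                         -half, half)[0] / (2 * half + 1)
                val = quad(
                    lambda v: ((1 - (v / s) ** 2) * np.exp(-(v**2) / (2 * s**2)) - m)
                    * amp * np.exp(-((tau - v) ** 2) / (2 * sigma_b**2)),
                    -half, half, limit=200,
                )[0]
                total += val / np.sqrt(s)
            return total / len(params.scales)

        for tau in (0.0, 25.0, 57.0, 80.0):
            closed = band_response(tau, amp, sigma_b, params)
            assert closed == pytest.approx(numeric(tau), rel=0.005, abs=1e-9)

    def test_avepix_matches_dense_numerical_integration(self):
        """Analytic avePix vs trapezoid integration of the profile over
        the same trough window, within 0.5%."""
        amp, sigma_b = 50.0, 22.0
        t = row_window(sigma_b)
        x = np.linspace(-t, t, 20001)
        profile = amp * np.exp(-0.5 * (x / sigma_b) ** 2)
        base = amp * np.exp(-0.5 * (t / sigma_b) ** 2)
        numeric = (np.trapezoid(profile, x) - (2 * t + 1) * base) / (2 * t)
        assert band_avepix(amp, sigma_b) == pytest.approx(numeric, rel=0.005)

    def test_trough_offset_is_response_minimum(self):
        t = trough_offset(20.0)
        grid = np.linspace(1, 120, 1000)
        resp = band_response(grid, 1.0, 20.0)
        assert t == pytest.approx(grid[np.argmin(resp)], abs=0.5)

    def test_ground_truth_fields(self):
        img, truth = generate(_band_spec(noise_sigma=0.0))
        band = truth.bands[0]
        assert band.x_left == 200 - 60 and band.x_right == 200 + 60
        assert band.integrated_signal == pytest.approx(30 * 20 * np.sqrt(2 * np.pi))
        assert band.analytic_avepix == pytest.approx(band_avepix(30.0, 20.0))


class TestWeakSignalSuite:
    def test_size_and_determinism(self):
        a = weak_signal_suite(4, (2.0, 4.0), seed=9, replicates=5)
        b = weak_signal_suite(4, (2.0, 4.0), seed=9, replicates=5)
        assert len(a) == 20
        for (ia, ta), (ib, tb) in zip(a, b):
            np.testing.assert_array_equal(ia.data, ib.data)
            assert ta.spec == tb.spec

    def test_contrast_in_requested_snr_range(self):
        suite = weak_signal_suite(6, (2.0, 4.0), seed=10, replicates=1)
        for img, truth in suite:
            noise = truth.spec.noise_sigma
            bg = scene_values(
                SceneSpec(shape=truth.spec.shape, background=truth.spec.background,
                          noise_sigma=0.0, seed=0)
            )
            scene = scene_values(truth.spec)
            for band in truth.bands:
                col = int(band.center)
                contrast = (scene[:, col] - bg[:, col]).max() / noise
                requested = band.amplitude / noise
                assert contrast == pytest.approx(requested, rel=0.1)
                assert 2.0 <= requested <= 4.0

    def test_band_separation_respected(self):
        suite = weak_signal_suite(10, (2.0, 4.0), seed=13, replicates=1)
        for _, truth in suite:
            centers = sorted(b.center for b in truth.bands)
            assert all(b - a >= 150 for a, b in zip(centers, centers[1:]))

    def test_invalid_snr_range_rejected(self):
        with pytest.raises(ConfigError, match="snr_range"):
            weak_signal_suite(2, (0.0, 4.0), seed=1)
        with pytest.raises(ConfigError, match="snr_range"):
            weak_signal_suite(2, (4.0, 2.0), seed=1)
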
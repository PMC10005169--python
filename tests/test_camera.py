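"""Camera model: band integration, mosaic round trips, RGB fit, smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msimon.camera import (
    CameraModel,
    MosaicFrame,
    demosaic,
    fit_rgb_matrix,
    fit_rgb_transform,
    integrate_bands,
    integrate_bands_batch,
    mosaic,
    reconstruct_rgb,
    smooth_transmission,
)


class TestIntegrateBands:
    def test_constant_spectrum_gives_constant_bands(self, cam):
        r = np.full(cam.wavelengths.size, 0.5)
        assert np.allclose(integrate_bands(cam.wavelengths, r, cam), 0.5)

    def test_delta_filter_picks_spectrum_value(self):
        cam = CameraModel.default()
        # single-sample spike at 500 nm for band 0, flat optics
        responses = np.zeros_like(cam.filter_responses)
        idx500 = int(np.argmin(np.abs(cam.wavelengths - 500.0)))
        responses[0, idx500] = 1.0
        for k in range(1, 16):
            responses[k, idx500 + k] = 1.0
        cam2 = CameraModel(
            wavelengths=cam.wavelengths,
            filter_responses=responses,
            optics_transmission=np.ones_like(cam.wavelengths),
            illuminant=np.ones_like(cam.wavelengths),
            mosaic_layout=cam.mosaic_layout,
        )
        rng = np.random.default_rng(0)
        r = rng.uniform(0.1, 0.9, cam.wavelengths.size)
        bands = integrate_bands(cam2.wavelengths, r, cam2)
        assert bands[0] == pytest.approx(r[idx500], abs=1e-14)

    def test_matches_fine_grid_quadrature(self, cam):
        """Trapezoid on the 2 nm grid equals refined quadrature of the
        linearly interpolated integrand (oracle at 0.1 nm)."""
        rng = np.random.default_rng(7)
        coeffs = rng.normal(0, 0.1, 4)
        wl = cam.wavelengths
        r = 0.5 + sum(
            c * np.sin((i + 1) * wl / 120.0) for i, c in enumerate(coeffs)
        )
        r = np.clip(r, 0.01, 0.99)
        bands = integrate_bands(wl, r, cam)
        fine = np.arange(wl[0], wl[-1] + 1e-9, 0.1)
        weights = cam.filter_responses * cam.optics_transmission * cam.illuminant
        for k in range(16):
            num = np.trapezoid(np.interp(fine, wl, weights[k] * r), fine)
            den = np.trapezoid(np.interp(fine, wl, weights[k]), fine)
            assert bands[k] == pytest.approx(num / den, abs=1e-10)

    def test_linearity_and_range(self, cam):
        rng = np.random.default_rng(1)
        r1 = rng.uniform(0, 1, cam.wavelengths.size)
        r2 = rng.uniform(0, 1, cam.wavelengths.size)
        a, b = 0.3, 1.7
        lhs = integrate_bands(cam.wavelengths, a * r1 + b * r2, cam)
        rhs = a * integrate_bands(cam.wavelengths, r1, cam) + b * integrate_bands(
            cam.wavelengths, r2, cam
        )
        assert np.allclose(lhs, rhs, atol=1e-12)
        bands = integrate_bands(cam.wavelengths, r1, cam)
        assert np.all((bands >= 0) & (bands <= 1))

    def test_zero_response_band_raises(self, cam):
        responses = cam.filter_responses.copy()
        responses[3] = 0.0
        cam2 = CameraModel(
            wavelengths=cam.wavelengths,
            filter_responses=responses,
            optics_transmission=cam.optics_transmission,
            illuminant=cam.illuminant,
            mosaic_layout=cam.mosaic_layout,
        )
        with pytest.raises(ValueError, match="band 3"):
            integrate_bands(cam2.wavelengths, np.ones(cam.wavelengths.size), cam2)

    def test_batch_matches_single(self, cam):
        rng = np.random.default_rng(2)
        R = rng.uniform(0, 1, (5, cam.wavelengths.size))
        batch = integrate_bands_batch(cam.wavelengths, R, cam)
        for i in range(5):
            assert np.allclose(batch[i], integrate_bands(cam.wavelengths, R[i], cam))

    def test_active_subgrid_is_lossless(self, cam):
        rng = np.random.default_rng(3)
        r = rng.uniform(0, 1, cam.wavelengths.size)
        full = integrate_bands(cam.wavelengths, r, cam)
        mask = cam.active_mask()
        sub = integrate_bands(cam.wavelengths[mask], r[mask], cam)
        assert np.allclose(full, sub, atol=1e-12)


class TestMosaic:
    def test_constant_frame(self, small_cam):
        frame = np.full(small_cam.sensor_shape, 7, dtype=np.uint16)
        cube = demosaic(frame, small_cam)
        assert np.all(cube.values == 7)

    def test_toy_layout_bookkeeping(self):
        cam = CameraModel.default(sensor_shape=(8, 8))
        tile = np.arange(16).reshape(4, 4)
        frame = np.tile(tile, (2, 2))
        cube = demosaic(frame, cam)
        assert np.array_equal(cube.values[0, 0], np.arange(16))

    def test_bad_dims_raise(self, small_cam):
        with pytest.raises(ValueError, match="divisible by 4"):
            demosaic(np.zeros((10, 12)), small_cam)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_bit_exact(self, seed):
        rng = np.random.default_rng(seed)
        layout = rng.permutation(16).reshape(4, 4)
        cam = CameraModel.default(sensor_shape=(8, 16), mosaic_layout=layout)
        frame = rng.integers(0, 1024, size=(8, 16)).astype(np.uint16)
        assert np.array_equal(mosaic(demosaic(frame, cam), cam), frame)

    def test_mosaic_frame_validates_counts(self):
        with pytest.raises(ValueError, match="saturation"):
            MosaicFrame(counts=np.full((4, 4), 5000), saturation_limit=1023)


class TestRgbTransform:
    def test_three_band_identity(self):
        wl = np.arange(300.0, 1000.0, 2.0)
        F_rgb = np.stack(
            [np.exp(-0.5 * ((wl - c) / 42.0) ** 2) for c in (460, 550, 640)]
        )
        T, N = fit_rgb_matrix(F_rgb, F_rgb)
        assert np.allclose(T, np.eye(3), atol=1e-8)

    def test_flat_bands_map_to_white(self, cam):
        tf = fit_rgb_transform(cam)
        rgb = tf.T @ np.ones(16)
        assert np.allclose(rgb, 1.0, atol=1e-9)

    def test_matches_normal_equations_oracle(self, cam):
        tf = fit_rgb_transform(cam)
        F_prime = tf.F_prime
        G = F_prime @ F_prime.T
        T_min = np.linalg.solve(G, F_prime @ tf.F_rgb.T).T
        expected = T_min / T_min.sum(axis=1, keepdims=True)
        assert np.allclose(tf.T, expected, atol=1e-8)

    def test_spectrally_flat_cube_is_neutral(self, cam):
        tf = fit_rgb_transform(cam)
        cube = np.full((4, 5, 16), 0.37)
        rgb = reconstruct_rgb(cube, tf)
        imbalance = rgb.max(axis=-1) - rgb.min(axis=-1)
        assert imbalance.max() < 1e-9

    def test_reconstruct_clips_and_checks_shape(self, cam):
        tf = fit_rgb_transform(cam)
        assert np.all(reconstruct_rgb(np.zeros((2, 2, 16)), tf) == 0.0)
        single = reconstruct_rgb(np.ones((1, 1, 16)) * 0.5, tf)
        assert np.allclose(single[0, 0], np.clip(tf.T @ (0.5 * np.ones(16)), 0, 1))
        with pytest.raises(ValueError):
            reconstruct_rgb(np.zeros((2, 2, 8)), tf)


class TestSmoothTransmission:
    def test_constant_signal_with_flagged_borders(self):
        wl = np.arange(400.0, 700.0, 1.0)
        smoothed, valid = smooth_transmission(wl, np.full((3, wl.size), 0.8))
        assert np.allclose(smoothed, 0.8)
        assert not valid[0] and not valid[-1]
        # the prescribed ignore ranges are flagged
        assert not valid[(wl >= 400) & (wl <= 419)].any()
        assert not valid[(wl >= 681) & (wl <= 700)].any()

    def test_linear_ramp_unchanged_in_interior(self):
        wl = np.arange(450.0, 650.0, 1.0)
        ramp = 0.001 * wl + 0.1
        smoothed, valid = smooth_transmission(wl, ramp)
        assert np.allclose(smoothed[valid], ramp[valid], atol=1e-12)

    def test_matches_windowed_mean_oracle(self):
        rng = np.random.default_rng(5)
        wl = np.arange(450.0, 650.0, 1.0)
        sig = np.sin(wl / 10.0) + 0.1 * rng.standard_normal(wl.size)
        smoothed, valid = smooth_transmission(wl, sig)
        half = 9  # 19 nm window on a 1 nm grid
        for i in np.flatnonzero(valid)[:40]:
            assert smoothed[i] == pytest.approx(
                sig[i - half : i + half + 1].mean(), abs=1e-12
            )

    def test_window_larger_than_support_raises(self):
        wl = np.arange(500.0, 510.0, 1.0)
        with pytest.raises(ValueError, match="window"):
            smooth_transmission(wl, np.ones(wl.size), window_nm=50.0)
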
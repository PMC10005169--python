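"""Snapshot-mosaic multispectral camera model.

The sensor records 16 spectral bands in a single exposure through a repeating
4x4 mosaic of Fabry-Perot filters laid over a 272x512 pixel array.  Light
additionally passes through the laparoscope, a 335-610 nm bandpass filter and
a C-Mount adapter, whose combined transmission shapes the effective spectral
response of every band.  This module represents that optical chain and
converts between the four data representations used throughout the package:

* high-resolution reflectance spectra r(lambda) on a per-nm grid,
* 16-band measurements r_k (one value per mosaic filter),
* raw mosaic frames (sensor counts), and
* reconstructed RGB images for visualisation.

A band measurement is the transmission/illuminant/filter-weighted mean of the
reflectance spectrum,

    r_k = int T(l) I(l) f_k(l) r(l) dl / int T(l) I(l) f_k(l) dl,

evaluated by trapezoidal quadrature on the camera wavelength grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraModel",
    "MosaicFrame",
    "BandCube",
    "RgbTransform",
    "integrate_bands",
    "integrate_bands_batch",
    "demosaic",
    "mosaic",
    "fit_rgb_transform",
    "reconstruct_rgb",
    "smooth_transmission",
]

N_BANDS = 16
MOSAIC_PERIOD = 4


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    """Quadrature weights w such that sum(w * y) == trapz(y, x)."""
    w = np.zeros_like(x, dtype=float)
    dx = np.diff(x)
    w[:-1] += dx / 2.0
    w[1:] += dx / 2.0
    return w


@dataclass
class CameraModel:
    """Spectral model of the mosaic sensor plus laparoscope optics.

    Parameters
    ----------
    wavelengths
        Common wavelength grid in nm (default 300-1000 nm, 2 nm step).
    filter_responses
        Nonnegative (16, n_wavelengths) matrix, one row per mosaic band.
    optics_transmission
        Combined transmission of laparoscope, bandpass filter and C-Mount
        adapter on the same grid.
    illuminant
        Relative spectral irradiance of the light source.  The default is
        flat; for reflectance targets the illuminant cancels in the band
        integral of a constant spectrum.
    mosaic_layout
        4x4 integer grid assigning one band index (0-15) to each position of
        the repeating mosaic tile.
    sensor_shape
        (rows, cols) of the raw sensor, both divisible by 4.
    """

    wavelengths: np.ndarray
    filter_responses: np.ndarray
    optics_transmission: np.ndarray
    illuminant: np.ndarray
    mosaic_layout: np.ndarray
    sensor_shape: tuple[int, int] = (272, 512)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.filter_responses = np.asarray(self.filter_responses, dtype=float)
        self.optics_transmission = np.asarray(self.optics_transmission, dtype=float)
        self.illuminant = np.asarray(self.illuminant, dtype=float)
        self.mosaic_layout = np.asarray(self.mosaic_layout, dtype=int)
        self.validate()

    def validate(self) -> None:
        L = self.wavelengths.size
        if self.filter_responses.shape != (N_BANDS, L):
            raise ValueError(
                f"filter_responses must have shape ({N_BANDS}, {L}), "
                f"got {self.filter_responses.shape}"
            )
        if np.any(self.filter_responses < 0):
            raise ValueError("filter responses must be nonnegative")
        for name, curve in (
            ("optics_transmission", self.optics_transmission),
            ("illuminant", self.illuminant),
        ):
            if curve.shape != (L,):
                raise ValueError(f"{name} must share the wavelength grid (length {L})")
        if self.mosaic_layout.shape != (MOSAIC_PERIOD, MOSAIC_PERIOD):
            raise ValueError("mosaic_layout must be 4x4")
        if sorted(self.mosaic_layout.ravel().tolist()) != list(range(N_BANDS)):
            raise ValueError("mosaic_layout must be a permutation of 0..15")
        rows, cols = self.sensor_shape
        if rows % MOSAIC_PERIOD or cols % MOSAIC_PERIOD:
            raise ValueError("sensor_shape must be divisible by 4 in both axes")

    # -- derived quantities -------------------------------------------------

    def band_weights(self) -> np.ndarray:
        """(16, L) quadrature weights T*I*f_k*w_trapz used in band integration."""
        w = _trapezoid_weights(self.wavelengths)
        return self.filter_responses * (self.optics_transmission * self.illuminant * w)

    def active_mask(self) -> np.ndarray:
        """Wavelengths that contribute to at least one band integral."""
        return self.band_weights().sum(axis=0) > 0.0

    def cube_shape(self) -> tuple[int, int]:
        return (self.sensor_shape[0] // MOSAIC_PERIOD, self.sensor_shape[1] // MOSAIC_PERIOD)

    # -- constructors -------------------------------------------------------

    @classmethod
    def default(
        cls,
        wavelengths: np.ndarray | None = None,
        sensor_shape: tuple[int, int] = (272, 512),
        second_order_amplitude: float = 0.35,
        mosaic_layout: np.ndarray | None = None,
    ) -> "CameraModel":
        """Synthetic default camera.

        Sixteen Gaussian filter responses with centres spread over the
        visible range passed by the bandpass filter.  Bands 5-12 carry an
        additional second-order transmission peak at shorter wavelengths, a
        known artefact of Fabry-Perot mosaic filters.  The mosaic layout is
        row-major 0..15 by default; the physical band-to-offset assignment of
        a real sensor should be supplied explicitly.
        """
        if wavelengths is None:
            wavelengths = np.arange(300.0, 1000.0 + 1e-9, 2.0)
        wl = np.asarray(wavelengths, dtype=float)

        centers = np.linspace(470.0, 620.0, N_BANDS)
        sd_main = 7.0
        responses = np.exp(-0.5 * ((wl[None, :] - centers[:, None]) / sd_main) ** 2)
        for k in range(5, 13):
            second = centers[k] - 150.0
            responses[k] += second_order_amplitude * np.exp(
                -0.5 * ((wl - second) / 10.0) ** 2
            )

        # bandpass 335-610 nm with soft shoulders, hard-blocked out of band
        trans = 1.0 / (1.0 + np.exp(-(wl - 335.0) / 4.0))
        trans *= 1.0 / (1.0 + np.exp((wl - 610.0) / 4.0))
        trans *= 0.75  # laparoscope + C-Mount losses
        trans[(wl < 330.0) | (wl > 618.0)] = 0.0

        illuminant = np.ones_like(wl)
        layout = (
            np.arange(N_BANDS).reshape(MOSAIC_PERIOD, MOSAIC_PERIOD)
            if mosaic_layout is None
            else np.asarray(mosaic_layout, dtype=int)
        )
        return cls(
            wavelengths=wl,
            filter_responses=responses,
            optics_transmission=trans,
            illuminant=illuminant,
            mosaic_layout=layout,
            sensor_shape=sensor_shape,
        )

    @classmethod
    def from_csv(
        cls,
        filter_csv,
        transmission_csv=None,
        illuminant_csv=None,
        mosaic_layout: np.ndarray | None = None,
        sensor_shape: tuple[int, int] = (272, 512),
    ) -> "CameraModel":
        """Build a camera from CSV curve files.

        ``filter_csv`` must have columns ``wavelength_nm, band_00..band_15``;
        the optional single-curve files have columns ``wavelength_nm, value``.
        """
        import pandas as pd

        df = pd.read_csv(filter_csv)
        wl = df["wavelength_nm"].to_numpy(dtype=float)
        bands = [f"band_{k:02d}" for k in range(N_BANDS)]
        responses = df[bands].to_numpy(dtype=float).T

        def _curve(path):
            if path is None:
                return np.ones_like(wl)
            c = pd.read_csv(path)
            return np.interp(wl, c["wavelength_nm"], c["value"])

        layout = (
            np.arange(N_BANDS).reshape(MOSAIC_PERIOD, MOSAIC_PERIOD)
            if mosaic_layout is None
            else np.asarray(mosaic_layout, dtype=int)
        )
        return cls(
            wavelengths=wl,
            filter_responses=responses,
            optics_transmission=_curve(transmission_csv),
            illuminant=_curve(illuminant_csv),
            mosaic_layout=layout,
            sensor_shape=sensor_shape,
        )


@dataclass
class MosaicFrame:
    """One raw snapshot: sensor counts plus acquisition metadata."""

    counts: np.ndarray
    integration_time_ms: float = 40.0
    saturation_limit: int = 1023

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("mosaic counts must be nonnegative")
        if np.any(self.counts > self.saturation_limit):
            raise ValueError("mosaic counts exceed the saturation limit")


@dataclass
class BandCube:
    """Demosaicked frame: (rows/4, cols/4, 16) values in camera band order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.shape[2] != N_BANDS:
            raise ValueError("band cube must have shape (h, w, 16)")


@dataclass
class RgbTransform:
    """Linear 16-band -> RGB mapping fitted against Gaussian target filters."""

    T: np.ndarray
    F_prime: np.ndarray
    F_rgb: np.ndarray
    N: np.ndarray
    centers: tuple[float, float, float] = (460.0, 550.0, 640.0)
    sd: float = 42.0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _check_spectrum_grid(wavelengths: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Return per-band weight matrix restricted to the spectrum's grid.

    The spectrum may be given on the full camera grid or on any subset that
    covers every wavelength with nonzero band weight (the bandpass filter is
    exactly zero out of band, so restricting the grid there is lossless).
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.shape == cam.wavelengths.shape and np.allclose(wl, cam.wavelengths):
        return cam.band_weights()
    mask = np.isin(cam.wavelengths, wl)
    missing = ~mask & cam.active_mask()
    if np.any(missing):
        raise ValueError(
            "spectrum grid does not cover the camera's active wavelengths "
            f"(first missing: {cam.wavelengths[missing][0]:.1f} nm)"
        )
    idx = np.searchsorted(wl, cam.wavelengths[mask])
    if not np.allclose(wl[idx], cam.wavelengths[mask]):
        raise ValueError("spectrum wavelengths must be a subset of the camera grid")
    # weights recomputed with trapezoid rule on the (restricted) grid
    w = _trapezoid_weights(cam.wavelengths)[mask]
    full = cam.filter_responses * (cam.optics_transmission * cam.illuminant)
    weights = np.zeros((N_BANDS, wl.size))
    weights[:, idx] = full[:, mask] * w
    return weights


def integrate_bands(
    wavelengths: np.ndarray, reflectance: np.ndarray, cam: CameraModel
) -> np.ndarray:
    """Project a reflectance spectrum onto the 16 camera bands.

    Implements the weighted-mean band adaptation
    r_k = int T I f_k r dl / int T I f_k dl with trapezoidal quadrature.
    Raises if any band has zero weighted response on the given grid.
    """
    r = np.asarray(reflectance, dtype=float)
    weights = _check_spectrum_grid(wavelengths, cam)
    denom = weights.sum(axis=1)
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise ValueError(f"band {bad[0]} has zero weighted spectral response")
    return (weights @ r) / denom


def integrate_bands_batch(
    wavelengths: np.ndarray, reflectances: np.ndarray, cam: CameraModel
) -> np.ndarray:
    """Vectorised :func:`integrate_bands` for an (n, L) spectrum matrix."""
    R = np.atleast_2d(np.asarray(reflectances, dtype=float))
    weights = _check_spectrum_grid(wavelengths, cam)
    denom = weights.sum(axis=1)
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise ValueError(f"band {bad[0]} has zero weighted spectral response")
    return (R @ weights.T) / denom


def demosaic(frame: MosaicFrame | np.ndarray, cam: CameraModel) -> BandCube:
    """Collapse each 4x4 mosaic tile into one 16-band pixel.

    No spatial interpolation is performed: a 272x512 frame becomes a
    68x128x16 cube, preserving the measured values bit-exactly.
    """
    counts = frame.counts if isinstance(frame, MosaicFrame) else np.asarray(frame)
    H, W = counts.shape
    if H % MOSAIC_PERIOD or W % MOSAIC_PERIOD:
        raise ValueError("frame dimensions must be divisible by 4")
    tiles = counts.reshape(H // 4, 4, W // 4, 4).transpose(0, 2, 1, 3)
    cube = np.empty((H // 4, W // 4, N_BANDS), dtype=counts.dtype)
    for dy in range(MOSAIC_PERIOD):
        for dx in range(MOSAIC_PERIOD):
            cube[:, :, cam.mosaic_layout[dy, dx]] = tiles[:, :, dy, dx]
    return BandCube(cube)


def mosaic(cube: BandCube | np.ndarray, cam: CameraModel) -> np.ndarray:
    """Inverse of :func:`demosaic`: scatter bands back to sensor positions."""
    values = cube.values if isinstance(cube, BandCube) else np.asarray(cube)
    h, w, nb = values.shape
    if nb != N_BANDS:
        raise ValueError("cube must have 16 bands")
    tiles = np.empty((h, w, MOSAIC_PERIOD, MOSAIC_PERIOD), dtype=values.dtype)
    for dy in range(MOSAIC_PERIOD):
        for dx in range(MOSAIC_PERIOD):
            tiles[:, :, dy, dx] = values[:, :, cam.mosaic_layout[dy, dx]]
    return tiles.transpose(0, 2, 1, 3).reshape(h * 4, w * 4)


def fit_rgb_matrix(F_prime: np.ndarray, F_rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares band->RGB matrix for arbitrary response matrices.

    Solves min_T ||F_rgb - T F_prime|| and row-normalises the solution so a
    flat band vector maps to (1, 1, 1).  Returns ``(T, N)`` where ``N`` is
    the per-channel normaliser (the row sums of the unnormalised solution).
    """
    F_prime = np.asarray(F_prime, dtype=float)
    F_rgb = np.asarray(F_rgb, dtype=float)
    sol, _, rank, _ = np.linalg.lstsq(F_prime.T, F_rgb.T, rcond=None)
    if rank < F_prime.shape[0]:
        raise np.linalg.LinAlgError(
            f"effective camera response is rank deficient (rank {rank} < "
            f"{F_prime.shape[0]}); cannot fit RGB transform"
        )
    T_min = sol.T  # (3, n_bands)
    N = T_min.sum(axis=1)
    if np.any(np.abs(N) < 1e-12):
        raise np.linalg.LinAlgError("degenerate RGB normaliser (channel sums to zero)")
    return T_min / N[:, None], N


def fit_rgb_transform(
    cam: CameraModel,
    centers: tuple[float, float, float] = (460.0, 550.0, 640.0),
    sd: float = 42.0,
) -> RgbTransform:
    """Fit the (3 x 16) RGB reconstruction matrix.

    The effective camera response F' (filter responses row-scaled by the
    optics transmission) is regressed onto three Gaussian target filters;
    the least-squares solution is then row-normalised so that a spectrally
    flat band vector maps to RGB (1, 1, 1).
    """
    wl = cam.wavelengths
    F_prime = cam.filter_responses * cam.optics_transmission[None, :]
    F_rgb = np.stack(
        [np.exp(-0.5 * ((wl - c) / sd) ** 2) for c in centers], axis=0
    )
    T, N = fit_rgb_matrix(F_prime, F_rgb)
    return RgbTransform(T=T, F_prime=F_prime, F_rgb=F_rgb, N=N,
                        centers=tuple(centers), sd=sd)


def reconstruct_rgb(cube: BandCube | np.ndarray, tf: RgbTransform) -> np.ndarray:
    """Per-pixel linear map from 16 bands to RGB, clipped to [0, 1]."""
    values = cube.values if isinstance(cube, BandCube) else np.asarray(cube)
    if values.shape[-1] != tf.T.shape[1]:
        raise ValueError("band count does not match the RGB transform")
    rgb = values @ tf.T.T
    return np.clip(rgb, 0.0, 1.0)


def save_rgb_png(rgb: np.ndarray, path) -> None:
    """Write a reconstructed RGB image (floats in [0, 1]) as 8-bit PNG."""
    from PIL import Image

    arr = np.asarray(rgb, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (h, w, 3) RGB image")
    Image.fromarray(
        (np.clip(arr, 0.0, 1.0) * 255.0).round().astype(np.uint8), mode="RGB"
    ).save(path, format="PNG")


def smooth_transmission(
    wavelengths: np.ndarray,
    measurements: np.ndarray,
    window_nm: float = 19.0,
    ignore_ranges: tuple[tuple[float, float], ...] = ((400.0, 419.0), (681.0, 700.0)),
) -> tuple[np.ndarray, np.ndarray]:
    """Average repeated spectrometer measurements and smooth across wavelength.

    Repeats are averaged first, then a centred rolling mean of ``window_nm``
    width is applied.  Samples whose centred window does not fit inside the
    measured support, and samples inside ``ignore_ranges`` (border-effect
    regions of the spectrometer), are flagged invalid.

    Returns ``(smoothed, valid_mask)``.
    """
    wl = np.asarray(wavelengths, dtype=float)
    meas = np.atleast_2d(np.asarray(measurements, dtype=float))
    if meas.shape[1] != wl.size:
        raise ValueError("measurement length must match the wavelength grid")
    step = np.diff(wl)
    if wl.size < 2 or not np.allclose(step, step[0]):
        raise ValueError("wavelength grid must be regular")
    half = int(window_nm / (2.0 * step[0]))
    n = 2 * half + 1
    if n > wl.size:
        raise ValueError("smoothing window is larger than the measured support")

    mean = meas.mean(axis=0)
    smoothed = np.convolve(mean, np.ones(n) / n, mode="same")
    valid = np.ones(wl.size, dtype=bool)
    if half > 0:
        valid[:half] = False
        valid[-half:] = False
        smoothed[:half] = mean[:half]
        smoothed[-half:] = mean[-half:]
    for lo, hi in ignore_ranges:
        valid &= ~((wl >= lo) & (wl <= hi))
    return smoothed, valid
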
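"""Preprocessing of mosaic video sequences into normalized pixel spectra.

The pipeline per region of interest (ROI) is:

1. demosaic the raw frame into a 16-band cube,
2. white/dark reference normalization, (I - D) / (W - D) per pixel and band,
3. validity masking (saturation thresholds, degenerate references),
4. l2 normalization across bands, which removes multiplicative illumination
   changes caused by varying laparoscope-to-tissue distance.

Per-pixel unit spectra feed flow training and WAIC scoring; per-ROI median
spectra (of the reference-normalized values, before or after the l2 stage
depending on the analysis) feed the heterogeneity and Beer-Lambert modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ReferencePair",
    "RoiTrack",
    "NormalizedRoi",
    "reference_normalize",
    "l2_normalize",
    "valid_pixel_mask",
    "roi_median_spectrum",
    "prepare_roi",
    "SEQUENCE_ACCEPT_FRACTION",
]

#: Minimum fraction of well-exposed tracked pixels for a sequence to be used.
SEQUENCE_ACCEPT_FRACTION = 0.95

#: Default under-/over-saturation thresholds as fractions of full scale.
LOW_FRACTION = 0.05
HIGH_FRACTION = 0.98


@dataclass
class ReferencePair:
    """White and dark reference mosaic frames (possibly repeated).

    Repeats along the first axis are averaged before use; the white
    reference must exceed the dark reference on every pixel that enters
    the normalization.
    """

    white: np.ndarray
    dark: np.ndarray
    source: str = "self"

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.source != "self":
            logger.warning(
                "white/dark references borrowed from another session (%s); "
                "verify that the hardware setup is identical", self.source,
            )

    def averaged(self) -> tuple[np.ndarray, np.ndarray]:
        w = self.white.mean(axis=0) if self.white.ndim == 3 else self.white
        d = self.dark.mean(axis=0) if self.dark.ndim == 3 else self.dark
        return w, d


@dataclass
class RoiTrack:
    """Per-frame rectangle of one tracked ROI in band-cube coordinates."""

    roi_id: int
    rects: np.ndarray  # (T, 4): top, left, height, width
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rects = np.asarray(self.rects, dtype=int)
        if self.rects.ndim != 2 or self.rects.shape[1] != 4:
            raise ValueError("rects must have shape (T, 4)")
        if self.valid is None:
            self.valid = np.ones(self.rects.shape[0], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)

    def rect(self, frame: int) -> tuple[int, int, int, int]:
        if not self.valid[frame]:
            raise ValueError(f"ROI {self.roi_id} is not valid on frame {frame}")
        return tuple(int(v) for v in self.rects[frame])

    def slices(self, frame: int) -> tuple[slice, slice]:
        top, left, h, w = self.rect(frame)
        return slice(top, top + h), slice(left, left + w)


@dataclass
class NormalizedRoi:
    """Unit-norm pixel spectra of one ROI plus validity mask.

    ``spectra`` is (N, M, 16) l2-normalized; ``reflectance`` keeps the
    reference-normalized values before the l2 stage (needed by physical
    models such as Beer-Lambert); ``mask`` flags pixels that are well
    exposed and non-degenerate.
    """

    spectra: np.ndarray
    mask: np.ndarray
    reflectance: np.ndarray


def reference_normalize(
    intensity: np.ndarray, white: np.ndarray, dark: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """White/dark reference normalization (I - D) / (W - D).

    Pixels (per band) where W <= D are marked invalid rather than raising:
    they indicate a defective reference, not a malformed call.  Returns
    ``(reflectance, valid)`` where ``valid`` has the pixel shape (all bands
    must be normalizable for a pixel to count as valid).
    """
    I = np.asarray(intensity, dtype=float)
    W = np.broadcast_to(np.asarray(white, dtype=float), I.shape)
    D = np.broadcast_to(np.asarray(dark, dtype=float), I.shape)
    denom = W - D
    ok = denom > 0
    out = np.zeros_like(I)
    np.divide(I - D, denom, out=out, where=ok)
    return out, ok.all(axis=-1)


def l2_normalize(spectra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each spectrum to unit Euclidean norm across bands.

    Invariant to multiplication of the input by any positive constant.
    Zero vectors cannot be normalized and are flagged invalid.
    Returns ``(unit_spectra, valid)``.
    """
    x = np.asarray(spectra, dtype=float)
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    ok = norms[..., 0] > 0
    out = np.zeros_like(x)
    np.divide(x, norms, out=out, where=norms > 0)
    return out, ok


def valid_pixel_mask(
    counts: np.ndarray,
    low: float,
    high: float,
) -> tuple[np.ndarray, float]:
    """Exposure mask: a pixel is valid iff every band lies strictly in (low, high).

    Returns ``(mask, valid_fraction)``.  A tracked sequence is accepted for
    training/testing when the valid fraction over the whole track reaches
    :data:`SEQUENCE_ACCEPT_FRACTION`.
    """
    c = np.asarray(counts, dtype=float)
    mask = np.all((c > low) & (c < high), axis=-1)
    return mask, float(mask.mean())


def sequence_accepted(valid_fraction: float) -> bool:
    return valid_fraction >= SEQUENCE_ACCEPT_FRACTION


def roi_median_spectrum(spectra: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-band median over the valid pixels of one ROI."""
    x = np.asarray(spectra, dtype=float).reshape(-1, spectra.shape[-1])
    if mask is not None:
        flat = np.asarray(mask, dtype=bool).ravel()
        x = x[flat]
    if x.shape[0] == 0:
        raise ValueError("ROI has no valid pixels")
    return np.median(x, axis=0)


def prepare_roi(
    cube_counts: np.ndarray,
    white_cube: np.ndarray,
    dark_cube: np.ndarray,
    row_slice: slice,
    col_slice: slice,
    saturation_limit: float,
    low_fraction: float = LOW_FRACTION,
    high_fraction: float = HIGH_FRACTION,
) -> NormalizedRoi:
    """Full preprocessing of one ROI of one demosaicked frame."""
    roi_counts = cube_counts[row_slice, col_slice]
    w = white_cube[row_slice, col_slice]
    d = dark_cube[row_slice, col_slice]
    exposure_mask, _ = valid_pixel_mask(
        roi_counts, low_fraction * saturation_limit, high_fraction * saturation_limit
    )
    refl, ref_ok = reference_normalize(roi_counts, w, d)
    unit, norm_ok = l2_normalize(refl)
    return NormalizedRoi(
        spectra=unit,
        mask=exposure_mask & ref_ok & norm_ok,
        reflectance=refl,
    )
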
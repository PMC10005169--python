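"""Synthetic patient sessions and cohorts.

Patient recordings behind the original clinical findings are not publicly
deposited, so this module generates full surrogate sessions with the
statistical structure the monitoring method assumes:

* a patient-specific perfused tissue state (three-layer optical parameters
  drawn per patient), an ischemic state derived from it by an absolute
  oxygenation drop and a blood-volume scale factor (ischemia reduces both),
* per-patient multiplicative band offsets so that between-patient spectral
  variance dominates between-state variance (the heterogeneity finding),
* two perfused sequences sharing tissue state but differing in illumination
  (emulating laparoscope removal/reinsertion) plus one ischemic sequence,
* per-pixel lognormal spectral jitter, additive Gaussian sensor noise,
  saturation defects, slow ROI drift with emitted ground-truth tracks, and
* white/dark reference frames.

Forward model per frame: state band spectrum (Monte-Carlo, cached per
state) -> per-pixel jitter -> counts D + r (W - D) * illumination ->
noise/saturation -> mosaic assembly.  Everything is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .camera import CameraModel, integrate_bands_batch, mosaic
from .preprocess import ReferencePair, RoiTrack
from .session import SEQUENCE_NAMES, SequenceData, SessionData
from .tissue import (
    SAMPLING_RANGES,
    ExtinctionTable,
    LayerOpticalProps,
    TissueSample,
    simulate_reflectance,
)

__all__ = [
    "PatientConfig",
    "SyntheticSession",
    "SEPARATION_PROFILES",
    "generate_patient",
    "generate_cohort",
]

#: Ischemia separation profiles: (oxygenation drop, blood-volume scale).
SEPARATION_PROFILES = {
    "clear": (-0.30, 0.5),
    "hard": (-0.03, 0.95),
    "null": (0.0, 1.0),
}

#: Perfused-state sampling ranges, narrowed so the ischemic deltas of every
#: profile stay inside the simulator's global parameter ranges.
PERFUSED_RANGES = {
    **SAMPLING_RANGES,
    "s": (0.50, 0.90),
    "v_hb": (0.05, 0.25),
}


@dataclass
class PatientConfig:
    """Generating parameters of one synthetic patient."""

    seed: int = 0
    patient_id: str = "synthetic"
    frames_per_sequence: int = 80
    roi_size: int = 30
    delta_s: float = -0.30
    vhb_scale: float = 0.5
    patient_gain_sd: float = 0.08
    #: Per-sequence light-source scale.  Training (perfused_1) differs from
    #: the two test sequences, emulating laparoscope removal/reinsertion;
    #: the test sequences share one scale because the acquisition protocol
    #: records them under comparable conditions.
    illumination_scales: tuple[float, float, float] = (1.0, 1.1, 1.1)
    noise_sd_frac: float = 0.01
    saturation_fraction: float = 0.002
    pixel_jitter_sd: float = 0.02
    n_photons: int = 2000
    max_roi_step: int = 2
    white_level_frac: float = 0.9
    dark_level_frac: float = 0.01
    #: Light-intensity increase between the white-reference recording and the
    #: tissue recordings (the acquisition protocol adjusts the source so the
    #: tissue is well exposed); scales tissue counts only.
    tissue_illumination_boost: float = 1.8
    perfused_layers: list[LayerOpticalProps] | None = None

    def validate(self) -> None:
        if not (0 < self.roi_size):
            raise ValueError("roi_size must be positive")
        if self.frames_per_sequence < 1:
            raise ValueError("frames_per_sequence must be >= 1")
        if not (0.0 < self.vhb_scale <= 1.0 + 1e-9):
            raise ValueError("vhb_scale must be in (0, 1]")
        if self.delta_s > 0 or self.delta_s < -PERFUSED_RANGES["s"][0]:
            raise ValueError(
                "delta_s must be a non-positive oxygenation drop that keeps "
                "the ischemic state within the simulator's parameter range"
            )


@dataclass
class SyntheticSession:
    """A generated session plus its ground truth."""

    session: SessionData
    config: PatientConfig
    perfused_sample: TissueSample
    ischemic_sample: TissueSample
    band_spectra: dict[str, np.ndarray]  # state -> clean 16-band spectrum
    patient_gain: np.ndarray = field(default_factory=lambda: np.ones(16))


def _ischemic_from_perfused(
    sample: TissueSample, delta_s: float, vhb_scale: float
) -> TissueSample:
    layers = [
        replace(layer, s=layer.s + delta_s, v_hb=layer.v_hb * vhb_scale)
        for layer in sample.layers
    ]
    for layer in layers:
        layer.validate()
    return TissueSample(layers)


def _sample_perfused_layers(rng: np.random.Generator) -> list[LayerOpticalProps]:
    layers = []
    for _ in range(3):
        draws = {name: rng.uniform(*PERFUSED_RANGES[name]) for name in SAMPLING_RANGES}
        layers.append(LayerOpticalProps(**draws))
    return layers


def _random_walk_track(
    rng: np.random.Generator,
    roi_id: int,
    n_frames: int,
    start: tuple[int, int],
    roi_size: int,
    bounds: tuple[int, int],
    max_step: int,
) -> RoiTrack:
    rects = np.empty((n_frames, 4), dtype=int)
    top, left = start
    for t in range(n_frames):
        rects[t] = (top, left, roi_size, roi_size)
        top = int(np.clip(top + rng.integers(-max_step, max_step + 1), 0, bounds[0] - roi_size))
        left = int(np.clip(left + rng.integers(-max_step, max_step + 1), 0, bounds[1] - roi_size))
    return RoiTrack(roi_id=roi_id, rects=rects)


def generate_patient(
    cfg: PatientConfig,
    cam: CameraModel | None = None,
    tab: ExtinctionTable | None = None,
) -> SyntheticSession:
    """Generate one fully synthetic patient session (seed-deterministic)."""
    cfg.validate()
    cam = cam or CameraModel.default()
    tab = tab or ExtinctionTable.default()
    rng = np.random.default_rng(cfg.seed)

    # tissue states -------------------------------------------------------
    perfused_layers = cfg.perfused_layers or _sample_perfused_layers(rng)
    perfused = TissueSample(list(perfused_layers))
    ischemic = _ischemic_from_perfused(perfused, cfg.delta_s, cfg.vhb_scale)

    wl = cam.wavelengths[cam.active_mask()]
    mc_seed = int(rng.integers(0, 2**31))
    spectra = {}
    for state, sample in (("perfused", perfused), ("ischemic", ischemic)):
        if state == "ischemic" and np.array_equal(
            sample.as_array(), perfused.as_array()
        ):
            # exact null: identical tissue must yield the identical expected
            # spectrum, not an independent Monte-Carlo realisation of it
            spectra[state] = spectra["perfused"]
            continue
        spec = simulate_reflectance(
            sample, wl, tab, n_photons=cfg.n_photons,
            seed=mc_seed + (0 if state == "perfused" else 1),
        )
        spectra[state] = integrate_bands_batch(wl, spec.reflectance, cam)[0]

    gain = np.exp(rng.normal(0.0, cfg.patient_gain_sd, 16))
    band_spectra = {k: v * gain for k, v in spectra.items()}

    # references ----------------------------------------------------------
    sat = 1023
    ch, cw = cam.cube_shape()
    band_white = sat * cfg.white_level_frac * (
        1.0 + 0.05 * rng.standard_normal(16)
    )
    band_dark = np.full(16, sat * cfg.dark_level_frac)
    white_cube = np.broadcast_to(band_white, (ch, cw, 16))
    dark_cube = np.broadcast_to(band_dark, (ch, cw, 16))
    ref_noise = rng.standard_normal((3,) + cam.sensor_shape)
    white_frames = np.clip(
        mosaic(np.ascontiguousarray(white_cube), cam)[None] + 2.0 * ref_noise, 0, sat
    ).astype(np.uint16)
    dark_frames = np.clip(
        mosaic(np.ascontiguousarray(dark_cube), cam)[None] + 1.0 * ref_noise[::-1], 0, sat
    ).astype(np.uint16)
    references = ReferencePair(white=white_frames, dark=dark_frames)

    # sequences -----------------------------------------------------------
    state_of_seq = {"perfused_1": "perfused", "perfused_2": "perfused", "ischemic": "ischemic"}
    sequences: dict[str, SequenceData] = {}
    noise_sd = cfg.noise_sd_frac * sat
    for seq_name, illum in zip(SEQUENCE_NAMES, cfg.illumination_scales):
        base = band_spectra[state_of_seq[seq_name]]
        frames = np.empty((cfg.frames_per_sequence,) + cam.sensor_shape, dtype=np.uint16)
        for t in range(cfg.frames_per_sequence):
            jitter = np.exp(
                rng.normal(0.0, cfg.pixel_jitter_sd, (ch, cw, 16))
            )
            cube = base * jitter
            counts = band_dark + cube * (band_white - band_dark) * (
                illum * cfg.tissue_illumination_boost
            )
            frame = mosaic(counts, cam)
            frame = frame + rng.normal(0.0, noise_sd, frame.shape)
            if cfg.saturation_fraction > 0:
                defect = rng.random(frame.shape) < cfg.saturation_fraction
                frame[defect] = sat
            frames[t] = np.clip(frame, 0, sat).astype(np.uint16)
        rois = [
            _random_walk_track(
                rng, roi_id, cfg.frames_per_sequence,
                start=(
                    int(rng.integers(2, ch - cfg.roi_size - 2)),
                    int(rng.integers(2, cw - cfg.roi_size - 2)),
                ),
                roi_size=cfg.roi_size, bounds=(ch, cw), max_step=cfg.max_roi_step,
            )
            for roi_id in (1, 2)
        ]
        sequences[seq_name] = SequenceData(
            frames=frames, rois=rois, illumination_scale=illum
        )

    session = SessionData(
        patient_id=cfg.patient_id,
        sequences=sequences,
        references=references,
        saturation_limit=sat,
        metadata={"profile_delta_s": cfg.delta_s, "profile_vhb_scale": cfg.vhb_scale},
    )
    return SyntheticSession(
        session=session,
        config=cfg,
        perfused_sample=perfused,
        ischemic_sample=ischemic,
        band_spectra=band_spectra,
        patient_gain=gain,
    )


def cohort_configs(
    n_patients: int,
    base_seed: int = 0,
    profile: str = "clear",
    include_hard_patient: bool = False,
    **overrides,
) -> list[PatientConfig]:
    """Per-patient configs with distinct seeds and the chosen separation profile."""
    if profile not in SEPARATION_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(SEPARATION_PROFILES)}")
    delta_s, vhb_scale = SEPARATION_PROFILES[profile]
    ss = np.random.SeedSequence(base_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_patients)]
    configs = []
    for i, seed in enumerate(seeds):
        d, v = delta_s, vhb_scale
        if include_hard_patient and i == n_patients - 1:
            d, v = SEPARATION_PROFILES["hard"]
        configs.append(
            PatientConfig(
                seed=seed,
                patient_id=f"patient_{i + 1:02d}",
                delta_s=d,
                vhb_scale=v,
                **overrides,
            )
        )
    return configs


def generate_cohort(
    n_patients: int,
    base_seed: int = 0,
    profile: str = "clear",
    cam: CameraModel | None = None,
    tab: ExtinctionTable | None = None,
    include_hard_patient: bool = False,
    **overrides,
):
    """Yield synthetic sessions one patient at a time (memory-friendly)."""
    cam = cam or CameraModel.default()
    tab = tab or ExtinctionTable.default()
    for cfg in cohort_configs(
        n_patients, base_seed, profile, include_hard_patient, **overrides
    ):
        yield generate_patient(cfg, cam, tab)
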
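"""Patient-personalised ischemia monitoring model (Model/Results interface).

:class:`IschemiaMonitor` is built from one patient's training data -- the
l2-normalized pixel spectra of the two tracked ROIs over the first frames of
the ``perfused_1`` sequence -- optionally warm-started from an ensemble
pretrained on simulated tissue spectra.  ``fit()`` trains the coupling-flow
ensemble by maximum likelihood and returns an
:class:`IschemiaMonitorResults` object that scores new frames:

    per-pixel WAIC  ->  ROI median  ->  two-ROI mean  =  ischemia index,

with higher index meaning more likely ischemic.  Per-patient evaluation
computes the AU-ROC between the ``perfused_2`` (negative) and ``ischemic``
(positive) test sequences over their first 70 frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .camera import CameraModel, demosaic
from .flow import (
    FlowEnsemble,
    TrainConfig,
    evaluate_auroc,
    ischemia_index,
    minmax_normalize,
    roi_waic,
)
from .preprocess import (
    HIGH_FRACTION,
    LOW_FRACTION,
    prepare_roi,
    sequence_accepted,
)
from .session import SessionData

logger = logging.getLogger(__name__)

__all__ = [
    "IschemiaMonitor",
    "IschemiaMonitorResults",
    "IschemiaIndexSeries",
    "training_spectra_from_session",
    "roi_reflectance_series",
]

EVAL_FRAMES = 70


@dataclass
class IschemiaIndexSeries:
    """Per-frame ischemia indices of one scored sequence."""

    patient_id: str
    sequence: str
    state: str  # "perfused" or "ischemic"
    frames: np.ndarray
    roi1_waic: np.ndarray
    roi2_waic: np.ndarray
    index: np.ndarray
    index_minmax: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "patient": self.patient_id,
                "sequence": self.sequence,
                "state": self.state,
                "frame": self.frames,
                "roi1_waic": self.roi1_waic,
                "roi2_waic": self.roi2_waic,
                "index": self.index,
            }
        )
        if self.index_minmax is not None:
            df["index_minmax"] = self.index_minmax
        return df


def _session_cubes(session: SessionData, cam: CameraModel):
    w, d = session.references.averaged()
    white_cube = demosaic(w, cam).values
    dark_cube = demosaic(d, cam).values
    return white_cube, dark_cube


def training_spectra_from_session(
    session: SessionData,
    cam: CameraModel,
    sequence: str = "perfused_1",
    n_frames: int = EVAL_FRAMES,
    max_spectra: int | None = None,
    subsample_seed: int = 0,
    low_fraction: float = LOW_FRACTION,
    high_fraction: float = HIGH_FRACTION,
) -> np.ndarray:
    """Valid l2-normalized pixel spectra of the tracked ROIs of one sequence.

    Collects every valid pixel of every tracked ROI over the first
    ``n_frames`` frames, then optionally subsamples to ``max_spectra`` rows
    (deterministic in ``subsample_seed``).  Raises if the sequence fails the
    95 % well-exposed-pixel acceptance rule.
    """
    seq = session.sequences[sequence]
    n_frames = min(n_frames, seq.n_frames)
    white_cube, dark_cube = _session_cubes(session, cam)
    rows = []
    n_valid = 0
    n_total = 0
    for t in range(n_frames):
        cube = demosaic(seq.frames[t], cam).values
        for track in seq.rois:
            rs, cs = track.slices(t)
            roi = prepare_roi(
                cube, white_cube, dark_cube, rs, cs, session.saturation_limit,
                low_fraction, high_fraction,
            )
            n_valid += int(roi.mask.sum())
            n_total += roi.mask.size
            rows.append(roi.spectra[roi.mask])
    if not sequence_accepted(n_valid / n_total):
        raise ValueError(
            f"sequence {sequence!r} rejected: only {n_valid / n_total:.1%} of "
            "tracked pixels are well exposed (threshold 95%)"
        )
    X = np.concatenate(rows, axis=0)
    if max_spectra is not None and X.shape[0] > max_spectra:
        idx = np.random.default_rng(subsample_seed).choice(
            X.shape[0], size=max_spectra, replace=False
        )
        X = X[np.sort(idx)]
    return X


def roi_median_series(
    session: SessionData,
    cam: CameraModel,
    sequence: str,
    n_frames: int = EVAL_FRAMES,
    normalized: bool = False,
    low_fraction: float = LOW_FRACTION,
    high_fraction: float = HIGH_FRACTION,
) -> np.ndarray:
    """Per-frame ROI-median spectra, averaged across the tracked ROIs.

    With ``normalized`` the medians are taken over the l2-normalized unit
    spectra (the representation used by the heterogeneity analyses);
    otherwise over the reference-normalized reflectances (the physical
    quantity the Beer-Lambert baseline needs).  Shape (n_frames, 16).
    """
    from .preprocess import roi_median_spectrum

    seq = session.sequences[sequence]
    n_frames = min(n_frames, seq.n_frames)
    white_cube, dark_cube = _session_cubes(session, cam)
    out = np.empty((n_frames, 16))
    for t in range(n_frames):
        cube = demosaic(seq.frames[t], cam).values
        medians = []
        for track in seq.rois:
            rs, cs = track.slices(t)
            roi = prepare_roi(
                cube, white_cube, dark_cube, rs, cs, session.saturation_limit,
                low_fraction, high_fraction,
            )
            values = roi.spectra if normalized else roi.reflectance
            medians.append(roi_median_spectrum(values, roi.mask))
        out[t] = np.mean(medians, axis=0)
    return out


def roi_reflectance_series(
    session: SessionData,
    cam: CameraModel,
    sequence: str,
    n_frames: int = EVAL_FRAMES,
    low_fraction: float = LOW_FRACTION,
    high_fraction: float = HIGH_FRACTION,
) -> np.ndarray:
    """Reference-normalized (pre-l2) per-frame median spectra; see
    :func:`roi_median_series`."""
    return roi_median_series(
        session, cam, sequence, n_frames,
        normalized=False, low_fraction=low_fraction, high_fraction=high_fraction,
    )


class IschemiaMonitor:
    """Flow-ensemble density model of one patient's perfused spectra."""

    def __init__(
        self,
        train_spectra: np.ndarray,
        n_members: int = 5,
        n_blocks: int = 8,
        hidden: int = 64,
        clamp: float = 2.0,
        train_config: TrainConfig | None = None,
        pretrained: FlowEnsemble | None = None,
        low_fraction: float = LOW_FRACTION,
        high_fraction: float = HIGH_FRACTION,
    ) -> None:
        self.train_spectra = np.atleast_2d(np.asarray(train_spectra, dtype=float))
        if self.train_spectra.shape[1] != 16:
            raise ValueError("training spectra must have 16 bands")
        self.n_members = n_members
        self.n_blocks = n_blocks
        self.hidden = hidden
        self.clamp = clamp
        self.train_config = train_config or TrainConfig()
        self.pretrained = pretrained
        self.low_fraction = low_fraction
        self.high_fraction = high_fraction

    @classmethod
    def from_session(
        cls,
        session: SessionData,
        cam: CameraModel,
        n_frames: int = EVAL_FRAMES,
        max_spectra: int | None = 2000,
        subsample_seed: int = 0,
        low_fraction: float = LOW_FRACTION,
        high_fraction: float = HIGH_FRACTION,
        **kwargs,
    ) -> "IschemiaMonitor":
        X = training_spectra_from_session(
            session, cam, "perfused_1", n_frames, max_spectra, subsample_seed,
            low_fraction, high_fraction,
        )
        return cls(X, low_fraction=low_fraction, high_fraction=high_fraction, **kwargs)

    def fit(self, seed: int = 0) -> "IschemiaMonitorResults":
        """Train (or fine-tune) the ensemble on the patient's spectra.

        Member ``i`` derives all its stochasticity (initialisation, batch
        order, noise augmentation) from ``seed + i``.  When a pretrained
        ensemble is supplied it is copied and fine-tuned; the z-score
        statistics are always re-estimated from -- and frozen to -- the
        patient training data, so inference is comparable to it.
        """
        if self.pretrained is not None:
            ensemble = self.pretrained.copy()
            if ensemble.n_members != self.n_members:
                raise ValueError(
                    "pretrained ensemble size does not match n_members"
                )
        else:
            ensemble = FlowEnsemble.initialize(
                dim=16,
                n_members=self.n_members,
                base_seed=seed,
                n_blocks=self.n_blocks,
                hidden=self.hidden,
                clamp=self.clamp,
            )
        ensemble.train(self.train_spectra, self.train_config, base_seed=seed)
        return IschemiaMonitorResults(self, ensemble, seed)


class IschemiaMonitorResults:
    """Fitted ensemble plus scoring, evaluation and reporting methods."""

    def __init__(self, model: IschemiaMonitor, ensemble: FlowEnsemble, seed: int):
        self.model = model
        self.ensemble = ensemble
        self.seed = seed

    # -- densities ----------------------------------------------------------

    def log_likelihoods(self, X: np.ndarray) -> np.ndarray:
        return self.ensemble.log_likelihoods(X)

    def waic(self, X: np.ndarray) -> np.ndarray:
        return self.ensemble.waic(X)

    # -- frame scoring ------------------------------------------------------

    def score_sequence(
        self,
        session: SessionData,
        cam: CameraModel,
        sequence: str,
        n_frames: int = EVAL_FRAMES,
        score: str = "waic",
    ) -> IschemiaIndexSeries:
        """Per-frame ischemia index of one sequence.

        ``score`` may be "waic" (default) or "nll" (ensemble-mean negative
        log-likelihood, the ensemble-free ablation).
        """
        seq = session.sequences[sequence]
        if not seq.rois:
            raise ValueError(f"sequence {sequence!r} has no ROI tracks")
        if score not in ("waic", "nll"):
            raise ValueError("score must be 'waic' or 'nll'")
        n_frames = min(n_frames, seq.n_frames)
        white_cube, dark_cube = _session_cubes(session, cam)
        # gather the valid pixels of every (frame, ROI) once, score the whole
        # sequence with a single ensemble pass, then aggregate per ROI
        chunks: list[np.ndarray] = []
        owners: list[tuple[int, int]] = []
        for t in range(n_frames):
            cube = demosaic(seq.frames[t], cam).values
            for r, track in enumerate(seq.rois):
                rs, cs = track.slices(t)
                roi = prepare_roi(
                    cube, white_cube, dark_cube, rs, cs, session.saturation_limit,
                    self.model.low_fraction, self.model.high_fraction,
                )
                chunks.append(roi.spectra[roi.mask])
                owners.append((t, r))
        pixels = np.concatenate(chunks, axis=0)
        lp = self.ensemble.log_likelihoods(pixels)
        values = lp.var(axis=0, ddof=0) - lp.mean(axis=0) if score == "waic" else -lp.mean(axis=0)
        arr = np.full((n_frames, len(seq.rois)), np.nan)
        start = 0
        for chunk, (t, r) in zip(chunks, owners):
            stop = start + chunk.shape[0]
            if stop > start:
                arr[t, r] = roi_waic(values[start:stop])
            start = stop
        indices = np.empty(n_frames)
        for t in range(n_frames):
            r1, r2 = arr[t]
            if np.isnan(r2):
                indices[t] = ischemia_index(r1)
            elif np.isnan(r1):
                indices[t] = ischemia_index(r2)
            else:
                indices[t] = ischemia_index(r1, r2)
        state = "ischemic" if sequence == "ischemic" else "perfused"
        return IschemiaIndexSeries(
            patient_id=session.patient_id,
            sequence=sequence,
            state=state,
            frames=np.arange(n_frames),
            roi1_waic=arr[:, 0],
            roi2_waic=arr[:, 1],
            index=indices,
        )

    def score_session(
        self,
        session: SessionData,
        cam: CameraModel,
        n_frames: int = EVAL_FRAMES,
        score: str = "waic",
    ) -> dict[str, IschemiaIndexSeries]:
        """Score both test sequences and min-max normalise per patient.

        Normalisation pools the two test sequences, is strictly monotone
        and therefore leaves the AU-ROC unchanged; it exists for display.
        """
        series = {
            name: self.score_sequence(session, cam, name, n_frames, score)
            for name in ("perfused_2", "ischemic")
        }
        pooled = np.concatenate([s.index for s in series.values()])
        if pooled.max() > pooled.min():
            normed = minmax_normalize(pooled)
            split = series["perfused_2"].index.size
            series["perfused_2"].index_minmax = normed[:split]
            series["ischemic"].index_minmax = normed[split:]
        else:
            logger.warning("constant pooled index series; min-max copy withheld")
        return series

    def evaluate(
        self,
        session: SessionData,
        cam: CameraModel,
        n_frames: int = EVAL_FRAMES,
        score: str = "waic",
    ) -> dict:
        """Per-patient AU-ROC (ischemic positive) plus the scored series."""
        series = self.score_session(session, cam, n_frames, score)
        auroc = evaluate_auroc(series["perfused_2"].index, series["ischemic"].index)
        return {"auroc": auroc, "series": series}

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        traces = self.ensemble.loss_traces
        lines = [
            "Ischemia monitor (coupling-flow ensemble, WAIC index)",
            f"  members:            {self.ensemble.n_members}",
            f"  architecture:       {m.n_blocks} coupling blocks, "
            f"{m.hidden} hidden units, soft clamp {m.clamp}",
            f"  training spectra:   {m.train_spectra.shape[0]}",
            f"  epochs / lr / wd:   {m.train_config.epochs} / "
            f"{m.train_config.lr:g} / {m.train_config.weight_decay:g}",
            f"  noise augmentation: SD {m.train_config.noise_sd:g} (z-scored scale)",
            f"  base seed:          {self.seed}",
        ]
        if traces:
            finals = ", ".join(f"{t[-1]:.3f}" for t in traces)
            lines.append(f"  final NLL per member: {finals}")
        return "\n".join(lines)
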
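"""In-memory and HDF5 representation of one patient's recording session.

A session holds three mosaic video sequences -- ``perfused_1`` (training,
recorded before arterial clamping), ``perfused_2`` (testing, recorded after
removing and reinserting the laparoscope but still before clamping) and
``ischemic`` (testing, after clamping) -- together with white/dark reference
frames and the tracked ROI rectangles per sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ReferencePair, RoiTrack

__all__ = ["SequenceData", "SessionData", "SEQUENCE_NAMES"]

SEQUENCE_NAMES = ("perfused_1", "perfused_2", "ischemic")


@dataclass
class SequenceData:
    """One recorded mosaic sequence plus its tracked ROIs."""

    frames: np.ndarray  # (T, H, W) counts
    rois: list[RoiTrack]
    illumination_scale: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class SessionData:
    patient_id: str
    sequences: dict[str, SequenceData]
    references: ReferencePair
    integration_time_ms: float = 40.0
    saturation_limit: int = 1023
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in SEQUENCE_NAMES if s not in self.sequences]
        if missing:
            raise ValueError(f"session is missing sequences: {missing}")

    # -- HDF5 persistence ---------------------------------------------------

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["patient_id"] = self.patient_id
            f.attrs["integration_time_ms"] = self.integration_time_ms
            f.attrs["saturation_limit"] = self.saturation_limit
            ref = f.create_group("references")
            ref.create_dataset("white", data=self.references.white)
            ref.create_dataset("dark", data=self.references.dark)
            ref.attrs["source"] = self.references.source
            for name, seq in self.sequences.items():
                g = f.create_group(name)
                g.create_dataset(
                    "frames", data=seq.frames.astype(np.uint16), compression="gzip"
                )
                g.attrs["illumination_scale"] = seq.illumination_scale
                rois = g.create_group("rois")
                for track in seq.rois:
                    t = rois.create_group(f"roi_{track.roi_id}")
                    t.create_dataset("rects", data=track.rects)
                    t.create_dataset("valid", data=track.valid)

    @classmethod
    def from_hdf5(cls, path) -> "SessionData":
        import h5py

        with h5py.File(path, "r") as f:
            references = ReferencePair(
                white=f["references/white"][()],
                dark=f["references/dark"][()],
                source=f["references"].attrs.get("source", "self"),
            )
            sequences = {}
            for name in SEQUENCE_NAMES:
                g = f[name]
                rois = []
                for key in sorted(g["rois"]):
                    t = g["rois"][key]
                    rois.append(
                        RoiTrack(
                            roi_id=int(key.split("_")[1]),
                            rects=t["rects"][()],
                            valid=t["valid"][()],
                        )
                    )
                sequences[name] = SequenceData(
                    frames=g["frames"][()],
                    rois=rois,
                    illumination_scale=float(g.attrs.get("illumination_scale", 1.0)),
                )
            return cls(
                patient_id=str(f.attrs["patient_id"]),
                sequences=sequences,
                references=references,
                integration_time_ms=float(f.attrs["integration_time_ms"]),
                saturation_limit=int(f.attrs["saturation_limit"]),
            )


def roi_tracks_to_csv(session: SessionData, path) -> None:
    """Export all ROI tracks as CSV `sequence,frame,roi_id,top,left,height,width,valid`."""
    import pandas as pd

    rows = []
    for name, seq in session.sequences.items():
        for track in seq.rois:
            for frame in range(track.rects.shape[0]):
                top, left, h, w = track.rects[frame]
                rows.append(
                    (name, frame, track.roi_id, top, left, h, w, bool(track.valid[frame]))
                )
    pd.DataFrame(
        rows,
        columns=[
            "sequence", "frame", "roi_id", "top", "left", "height", "width", "valid",
        ],
    ).to_csv(path, index=False)
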
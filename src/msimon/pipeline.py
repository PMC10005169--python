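"""End-to-end study orchestration: simulate -> pretrain -> fit -> score -> report.

``run_study`` reproduces the clinical evaluation protocol on a synthetic
cohort: for every patient an ensemble (optionally pretrained on simulated
tissue spectra) is fine-tuned on the patient's own ``perfused_1`` pixel
spectra, both test sequences are scored over their first 70 frames with the
WAIC ischemia index, and the per-patient AU-ROC (ischemic positive) is
aggregated into cohort median/mean.  ``run_baseline_study`` applies the same
protocol with Beer-Lambert oxygenation and total-hemoglobin estimates as
decision scores.

Default problem sizes are desk-scale (reduced architecture, subsampled
training spectra, small pretraining corpus); every knob is on
:class:`RunConfig` and can be raised to the full intraoperative settings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .beer_lambert import BeerLambertModel, band_average_extinctions, classify_by_baseline
from .camera import CameraModel
from .flow import FlowEnsemble, TrainConfig, evaluate_auroc
from .heterogeneity import CohortSpectra
from .monitor import IschemiaMonitor, roi_median_series, roi_reflectance_series
from .preprocess import l2_normalize
from .synthetic import cohort_configs, generate_patient
from .tissue import ExtinctionTable, build_pretraining_corpus

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StudyReport", "run_study", "run_baseline_study", "validate_report"]


@dataclass
class RunConfig:
    """Fully seeded configuration of one synthetic study.

    ``paper_scale`` switches the architecture and data budgets to the full
    intraoperative settings (20 blocks, 256 hidden units, all pixels, large
    corpus); the default is a reduced configuration sized for a single CPU
    core.
    """

    # cohort
    n_patients: int = 10
    base_seed: int = 0
    profile: str = "clear"
    include_hard_patient: bool = False
    frames_per_sequence: int = 80
    eval_frames: int = 70
    session_photons: int = 2000
    noise_sd_frac: float = 0.01
    # pretraining
    pretrain: bool = True
    corpus_samples: int = 200
    corpus_photons: int = 500
    pretrain_epochs: int = 100
    # ensemble / fine-tuning
    n_members: int = 5
    n_blocks: int = 8
    hidden: int = 64
    clamp: float = 2.0
    max_train_spectra: int = 2000
    finetune_epochs: int = 120
    batch_size: int = 256
    lr: float = 1e-3
    weight_decay: float = 1e-4
    noise_sd: float = 0.05
    score: str = "waic"
    # exposure validity thresholds (fractions of sensor full scale); the
    # acceptance rule itself (>= 95 % well-exposed tracked pixels) is fixed
    undersat_fraction: float = 0.02
    oversat_fraction: float = 0.98
    # output
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.eval_frames > self.frames_per_sequence:
            raise ValueError("eval_frames cannot exceed frames_per_sequence")

    @classmethod
    def paper_scale(cls, **overrides) -> "RunConfig":
        base = dict(
            n_blocks=20,
            hidden=256,
            max_train_spectra=0,  # 0 = use all pixels
            finetune_epochs=10,
            batch_size=512,
            corpus_samples=550_000,
            corpus_photons=1_000_000,
            session_photons=1_000_000,
        )
        base.update(overrides)
        return cls(**base)

    # -- seeding ------------------------------------------------------------

    def seeds(self) -> dict:
        ss = np.random.SeedSequence(self.base_seed)
        corpus, pretrain, cohort, finetune = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
        )
        return {
            "corpus": corpus,
            "pretrain": pretrain,
            "cohort": cohort,
            "finetune": finetune,
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            return cls(**yaml.safe_load(text))
        return cls.from_json(text)


@dataclass
class StudyReport:
    config: RunConfig
    patients: pd.DataFrame  # one row per patient
    scores: pd.DataFrame  # one row per scored frame
    summary: dict

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "summary": self.summary,
            "patients": self.patients.to_dict(orient="records"),
        }

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(out / "scores.csv", index=False)
        self.patients.to_csv(out / "patients.csv", index=False)
        (out / "report.json").write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        (out / "manifest.json").write_text(self.config.to_json())


def _load_schema() -> dict:
    with resources.files("msimon.data").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Minimal structural validation of a study report against the shipped schema.

    Checks required keys and primitive types (a deliberately small validator;
    the schema file documents the full report layout).
    """
    schema = schema or _load_schema()

    def _check(obj, spec, path="report"):
        if spec["type"] == "object":
            if not isinstance(obj, dict):
                raise ValueError(f"{path}: expected object")
            for key, sub in spec.get("required_properties", {}).items():
                if key not in obj:
                    raise ValueError(f"{path}: missing required key {key!r}")
                _check(obj[key], sub, f"{path}.{key}")
        elif spec["type"] == "array":
            if not isinstance(obj, list):
                raise ValueError(f"{path}: expected array")
            for i, item in enumerate(obj):
                _check(item, spec["items"], f"{path}[{i}]")
        elif spec["type"] == "number":
            if not isinstance(obj, (int, float)) or isinstance(obj, bool):
                raise ValueError(f"{path}: expected number, got {type(obj).__name__}")
        elif spec["type"] == "string":
            if not isinstance(obj, str):
                raise ValueError(f"{path}: expected string")

    _check(report, schema)


def _five_number(values: np.ndarray) -> dict:
    v = np.asarray(values, dtype=float)
    return {
        "min": float(v.min()),
        "q1": float(np.percentile(v, 25)),
        "median": float(np.median(v)),
        "q3": float(np.percentile(v, 75)),
        "max": float(v.max()),
        "mean": float(v.mean()),
    }


def cohort_spectra_from_sessions(
    sessions,
    cam: CameraModel | None = None,
    n_frames: int = 70,
    low_fraction: float = 0.02,
    high_fraction: float = 0.98,
) -> CohortSpectra:
    """Assemble the heterogeneity-analysis input from recorded sessions.

    One row per frame and sequence: the l2-normalized ROI-median spectrum
    averaged across the tracked ROIs, labelled with patient id and perfusion
    state (both perfused sequences are state 0, the clamped sequence 1).
    """
    cam = cam or CameraModel.default()
    rows, patients, states = [], [], []
    for session in sessions:
        session = getattr(session, "session", session)  # accept SyntheticSession
        for seq, state in (("perfused_1", 0), ("perfused_2", 0), ("ischemic", 1)):
            med = roi_median_series(
                session, cam, seq, n_frames,
                normalized=True, low_fraction=low_fraction, high_fraction=high_fraction,
            )
            rows.append(med)
            patients.extend([session.patient_id] * med.shape[0])
            states.extend([state] * med.shape[0])
    return CohortSpectra(
        spectra=np.vstack(rows), patient=np.array(patients), state=np.array(states)
    )


def pretrain_ensemble(cfg: RunConfig, cam: CameraModel, tab: ExtinctionTable) -> FlowEnsemble:
    """Pretrain one ensemble on l2-normalized simulated band spectra."""
    seeds = cfg.seeds()
    bands, _ = build_pretraining_corpus(
        cfg.corpus_samples,
        cam,
        tab,
        n_photons=cfg.corpus_photons,
        seed=seeds["corpus"],
    )
    unit, ok = l2_normalize(bands)
    ensemble = FlowEnsemble.initialize(
        dim=16,
        n_members=cfg.n_members,
        base_seed=seeds["pretrain"],
        n_blocks=cfg.n_blocks,
        hidden=cfg.hidden,
        clamp=cfg.clamp,
    )
    pre_cfg = TrainConfig(
        epochs=cfg.pretrain_epochs,
        lr=cfg.lr,
        weight_decay=cfg.weight_decay,
        noise_sd=cfg.noise_sd,
        batch_size=cfg.batch_size,
    )
    ensemble.train(unit[ok], pre_cfg, base_seed=seeds["pretrain"])
    ensemble.provenance["pretrain_corpus"] = f"simulated:{cfg.corpus_samples}"
    return ensemble


def run_study(cfg: RunConfig, pretrained: FlowEnsemble | None = None) -> StudyReport:
    """Full synthetic cohort study with the WAIC ischemia index."""
    cam = CameraModel.default()
    tab = ExtinctionTable.default()
    seeds = cfg.seeds()

    if cfg.pretrain and pretrained is None:
        logger.info("pretraining ensemble on %d simulated spectra", cfg.corpus_samples)
        pretrained = pretrain_ensemble(cfg, cam, tab)

    configs = cohort_configs(
        cfg.n_patients,
        seeds["cohort"],
        cfg.profile,
        cfg.include_hard_patient,
        frames_per_sequence=cfg.frames_per_sequence,
        n_photons=cfg.session_photons,
        noise_sd_frac=cfg.noise_sd_frac,
    )
    finetune_cfg = TrainConfig(
        epochs=cfg.finetune_epochs,
        lr=cfg.lr,
        weight_decay=cfg.weight_decay,
        noise_sd=cfg.noise_sd,
        batch_size=cfg.batch_size,
    )

    patient_rows = []
    score_frames = []
    failures = []
    for i, pat_cfg in enumerate(configs):
        try:
            synth = generate_patient(pat_cfg, cam, tab)
            monitor = IschemiaMonitor.from_session(
                synth.session,
                cam,
                n_frames=cfg.eval_frames,
                max_spectra=cfg.max_train_spectra or None,
                subsample_seed=seeds["finetune"] + i,
                n_members=cfg.n_members,
                n_blocks=cfg.n_blocks,
                hidden=cfg.hidden,
                clamp=cfg.clamp,
                train_config=finetune_cfg,
                pretrained=pretrained,
                low_fraction=cfg.undersat_fraction,
                high_fraction=cfg.oversat_fraction,
            )
            results = monitor.fit(seed=seeds["finetune"] + 1000 * i)
            evaluation = results.evaluate(
                synth.session, cam, n_frames=cfg.eval_frames, score=cfg.score
            )
        except Exception as exc:  # report and exclude, never drop silently
            logger.error("patient %s failed: %s", pat_cfg.patient_id, exc)
            failures.append({"patient": pat_cfg.patient_id, "reason": str(exc)})
            continue
        row = {"patient": pat_cfg.patient_id, "auroc": evaluation["auroc"]}
        for name, series in evaluation["series"].items():
            score_frames.append(series.to_frame())
            for stat, value in _five_number(series.index).items():
                row[f"{name}_{stat}"] = value
        patient_rows.append(row)

    patients = pd.DataFrame(patient_rows)
    scores = (
        pd.concat(score_frames, ignore_index=True) if score_frames else pd.DataFrame()
    )
    aurocs = patients["auroc"].to_numpy() if len(patients) else np.array([])
    summary = {
        "n_patients": int(len(patients)),
        "median_auroc": float(np.median(aurocs)) if aurocs.size else float("nan"),
        "mean_auroc": float(np.mean(aurocs)) if aurocs.size else float("nan"),
        "failed_patients": failures,
        "profile": cfg.profile,
    }
    report = StudyReport(config=cfg, patients=patients, scores=scores, summary=summary)
    if cfg.out_dir:
        report.save(cfg.out_dir)
    return report


def run_baseline_study(cfg: RunConfig) -> StudyReport:
    """Same cohort protocol scored with Beer-Lambert parameter estimates."""
    cam = CameraModel.default()
    tab = ExtinctionTable.default()
    seeds = cfg.seeds()
    bx = band_average_extinctions(tab, cam)

    configs = cohort_configs(
        cfg.n_patients,
        seeds["cohort"],
        cfg.profile,
        cfg.include_hard_patient,
        frames_per_sequence=cfg.frames_per_sequence,
        n_photons=cfg.session_photons,
        noise_sd_frac=cfg.noise_sd_frac,
    )
    patient_rows = []
    score_frames = []
    failures = []
    for pat_cfg in configs:
        try:
            synth = generate_patient(pat_cfg, cam, tab)
            refl = {
                seq: roi_reflectance_series(
                    synth.session, cam, seq, cfg.eval_frames,
                    low_fraction=cfg.undersat_fraction,
                    high_fraction=cfg.oversat_fraction,
                )
                for seq in ("perfused_2", "ischemic")
            }
            stacked = np.vstack([refl["perfused_2"], refl["ischemic"]])
            labels = np.concatenate(
                [np.zeros(len(refl["perfused_2"])), np.ones(len(refl["ischemic"]))]
            )
            results = BeerLambertModel(stacked, bx).fit()
            aurocs = classify_by_baseline(results, labels)
        except Exception as exc:
            logger.error("patient %s failed: %s", pat_cfg.patient_id, exc)
            failures.append({"patient": pat_cfg.patient_id, "reason": str(exc)})
            continue
        patient_rows.append(
            {
                "patient": pat_cfg.patient_id,
                "auroc_s": aurocs["auroc_s"],
                "auroc_v_hbt": aurocs["auroc_v_hbt"],
            }
        )
        df = results.to_frame()
        df.insert(0, "patient", pat_cfg.patient_id)
        df.insert(1, "state", labels)
        score_frames.append(df)

    patients = pd.DataFrame(patient_rows)
    summary = {
        "n_patients": int(len(patients)),
        "median_auroc_s": float(patients["auroc_s"].median()) if len(patients) else float("nan"),
        "median_auroc_v_hbt": float(patients["auroc_v_hbt"].median()) if len(patients) else float("nan"),
        "failed_patients": failures,
        "profile": cfg.profile,
    }
    report = StudyReport(
        config=cfg,
        patients=patients,
        scores=pd.concat(score_frames, ignore_index=True) if score_frames else pd.DataFrame(),
        summary=summary,
    )
    if cfg.out_dir:
        report.save(cfg.out_dir)
    return report
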
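"""End-to-end orchestration: simulate -> extract -> stats -> train/eval.

A run is described by a :class:`RunConfig` (flat YAML document; every
paper-unstated constant is a field with its documented default, so any
design decision can be overridden from the config). The run writes session
CSVs + sidecars, per-session ground truth, feature tables, a statistics
table, one evaluation report per feature set, and a manifest with content
checksums for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify, eda, hrv, io, paired, synthetic
from .errors import InvalidArgumentError, StageError

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "extract_features", "simulate_to_dir"]

log = logging.getLogger("vigilance")

FEATURE_SETS = {
    "hrv": hrv.HRV_FEATURE_NAMES,
    "gsr": eda.GSR_FEATURE_NAMES,
    "combined": hrv.HRV_FEATURE_NAMES + eda.GSR_FEATURE_NAMES,
}


@dataclass
class RunConfig:
    seed: int = 0
    n_subjects: int = 30
    duration: float = 300.0
    ecg_fs: float = 250.0
    gsr_fs: float = 10.0
    snr_db: float = 20.0
    effects: synthetic.ConditionEffects = field(default_factory=synthetic.ConditionEffects)
    # extraction
    correction_threshold: float = 0.3
    psd_grid_step: float = 0.002
    entropy_m: int = 2
    entropy_r_factor: float = 0.2
    scr_threshold: float = 0.01
    bateman_tau1: float = 3.75
    bateman_tau2: float = 1.0
    cda_max_iter: int = 500
    cda_refine_passes: int = 3
    window_length: float = 300.0
    # statistics
    alpha: float = 0.05
    # classification
    families: tuple = ("knn",)
    feature_sets: tuple = ("hrv", "gsr", "combined")
    knn_k_max: int = 7
    run_elimination: bool = False
    out_dir: str = "run_out"

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise InvalidArgumentError("alpha must be in (0, 1)")
        if self.n_subjects < 2:
            raise InvalidArgumentError("n_subjects must be >= 2")
        unknown = set(self.feature_sets) - set(FEATURE_SETS)
        if unknown:
            raise InvalidArgumentError(f"unknown feature sets: {sorted(unknown)}")
        unknown = set(self.families) - set(classify.FAMILIES)
        if unknown:
            raise InvalidArgumentError(f"unknown classifier families: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        effects = raw.pop("effects", None)
        cfg = cls(**raw)
        if effects is not None:
            cfg.effects = synthetic.ConditionEffects(**effects)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    sessions: list
    checksums: dict  # relative path -> sha256
    warnings: list
    started: float
    finished: float

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def simulate_to_dir(config: RunConfig, out_dir: Path) -> synthetic.SyntheticDataset:
    """Generate the cohort and persist every session as CSV + sidecars."""
    dataset = synthetic.generate_cohort(
        n_subjects=config.n_subjects, effects=config.effects, seed=config.seed,
        duration=config.duration, ecg_fs=config.ecg_fs, gsr_fs=config.gsr_fs,
        snr_db=config.snr_db,
    )
    sess_dir = out_dir / "sessions"
    sess_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for sess in dataset.sessions:
        stem = f"{sess.subject_id}_{sess.condition}"
        io.write_session(sess_dir / f"{stem}_ecg.csv", sess.ecg.times, sess.ecg.samples,
                         sess.subject_id, sess.condition, "ecg", sess.ecg.fs, "mV")
        io.write_session(sess_dir / f"{stem}_gsr.csv", sess.gsr.times, sess.gsr.samples,
                         sess.subject_id, sess.condition, "gsr", sess.gsr.fs, "uS")
        io.write_truth(sess_dir / f"{stem}_truth.json", sess.truth)
        manifest_rows.append({
            "subject_id": sess.subject_id, "condition": sess.condition,
            "ecg": f"{stem}_ecg.csv", "gsr": f"{stem}_gsr.csv",
            "truth": f"{stem}_truth.json",
        })
    pd.DataFrame(manifest_rows).to_csv(out_dir / "cohort.csv", index=False)
    return dataset


def extract_features(
    dataset: synthetic.SyntheticDataset, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-session HRV, EDA and behavioral tables."""
    bateman = eda.BatemanParams(config.bateman_tau1, config.bateman_tau2)
    entropy = hrv.EntropyParams(m=config.entropy_m)
    hrv_rows, eda_rows, beh_rows = [], [], []
    for sess in dataset.sessions:
        key = {"subject_id": sess.subject_id, "condition": sess.condition}
        try:
            vec = hrv.extract_hrv(
                sess.ecg, correction_threshold=config.correction_threshold,
                grid_step=config.psd_grid_step, entropy=entropy,
            )
        except Exception as exc:  # noqa: BLE001 - stage tagging
            raise StageError("extract-hrv", str(exc), session=f"{sess.subject_id}/{sess.condition}") from exc
        hrv_rows.append(key | vec.to_dict())
        try:
            gvec = eda.extract_eda(
                sess.gsr, params=bateman, threshold=config.scr_threshold,
                max_iter=config.cda_max_iter,
                refine_passes=config.cda_refine_passes,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("extract-eda", str(exc), session=f"{sess.subject_id}/{sess.condition}") from exc
        eda_rows.append(key | gvec.to_dict())
        b = sess.behavior
        beh_rows.append(key | {
            "reaction_time": b.mean_rt, "accuracy": 100.0 * b.accuracy,
            "rating": b.rating,
        })
    return pd.DataFrame(hrv_rows), pd.DataFrame(eda_rows), pd.DataFrame(beh_rows)


def _train_eval(
    matrix: classify.FeatureMatrix, config: RunConfig
) -> dict:
    reports = {}
    for set_name in config.feature_sets:
        sub = matrix.select(FEATURE_SETS[set_name])
        for family in config.families:
            grid = (
                [classify.Hyperparameters("knn", k=k) for k in range(1, config.knn_k_max + 1)]
                if family == "knn"
                else classify.default_grid(family)
            )
            if config.run_elimination:
                trace = classify.backward_elimination(sub, family, grid, seed=config.seed)
                best = sub.select(trace.best_subset)
                hp, _ = classify.grid_search(best, family, grid, seed=config.seed)
                cv = classify.loso_cv(best, hp, seed=config.seed)
            else:
                hp, _ = classify.grid_search(sub, family, grid, seed=config.seed)
                cv = classify.loso_cv(sub, hp, seed=config.seed)
            report = classify.evaluate(cv)
            reports[f"{set_name}/{family}"] = report.to_dict() | {
                "hyperparameters": {k: v for k, v in asdict(hp).items() if v is not None},
            }
    return reports


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages; partial failure raises a stage-tagged error."""
    config.validate()
    started = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings_log: list = []

    log.info("stage simulate: %d subjects, seed %d", config.n_subjects, config.seed)
    dataset = simulate_to_dir(config, out_dir)

    log.info("stage extract: %d sessions", len(dataset.sessions))
    hrv_df, eda_df, beh_df = extract_features(dataset, config)
    hrv_df.to_csv(out_dir / "hrv_features.csv", index=False)
    eda_df.to_csv(out_dir / "eda_features.csv", index=False)
    beh_df.to_csv(out_dir / "behavior.csv", index=False)

    log.info("stage stats")
    merged = hrv_df.merge(eda_df, on=["subject_id", "condition"]).merge(
        beh_df, on=["subject_id", "condition"]
    )
    if merged["Latency"].isna().any():
        warnings_log.append("Latency imputed with window length for nSCR=0 sessions")
        merged["Latency"] = merged["Latency"].fillna(config.window_length)
    stats_df = paired.summarize_features(merged, alpha=config.alpha)
    stats_df.to_csv(out_dir / "stats.csv", index=False)

    log.info("stage train-eval")
    matrix = classify.build_feature_matrix(hrv_df, eda_df, latency_impute=config.window_length)
    reports = _train_eval(matrix, config)
    (out_dir / "evaluation.json").write_text(json.dumps(reports, indent=1))

    checksums = {
        str(p.relative_to(out_dir)): _sha256(p)
        for p in sorted(out_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=config.config_hash(),
        sessions=[f"{s.subject_id}/{s.condition}" for s in dataset.sessions],
        checksums=checksums,
        warnings=warnings_log,
        started=started,
        finished=time.time(),
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
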
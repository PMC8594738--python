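"""End-to-end pipeline: simulate -> filter -> label -> features -> train ->
evaluate, from one config, with provenance in every artifact.

Stage order mirrors the data flow of the acquisition-to-classifier chain;
any stage failure aborts with the stage name attached, and a rerun with the
same config and seed reproduces the report.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass

import numpy as np

from . import __version__, classifiers, evaluation, features_fusion, phase_labeler, preprocess
from .config import PipelineConfig
from .errors import GaitFuseError
from .signal_model import write_recording
from .synthetic_gait import generate_recording

log = logging.getLogger(__name__)

#: exit-code families for the CLI (0 = success)
STAGE_EXIT_CODES = {
    "config": 2, "simulate": 10, "filter": 20, "label": 30,
    "features": 40, "train": 50, "evaluate": 60, "io": 70,
}


class StageError(GaitFuseError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


@dataclass
class PipelineResult:
    config: PipelineConfig
    recording: object
    ground_truth: np.ndarray
    labels: np.ndarray
    dataset: features_fusion.FeatureDataset
    trained: classifiers.TrainedModel | None
    report: evaluation.EvalReport
    artifacts: dict


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except GaitFuseError as e:
                raise StageError(name, e) from e
            log.info("stage %-9s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(cfg: PipelineConfig, outdir: str | None = None) -> PipelineResult:
    """Run the full chain; optionally persist artifacts under ``outdir``."""
    cfg = cfg.resolved()
    sim = cfg.simulator

    rec, truth = _stage("simulate")(generate_recording)(
        sim.schedule, sim.profile, sim.angle, seed=cfg.seed,
        pressure_noise=sim.pressure_noise, ratio=sim.ratio,
        meta={"speed_km_h": sim.speed_km_h},
    )
    log.info("recording: semg %s @%g Hz, low-rate %d samples",
             rec.semg.values.shape, rec.semg.rate_hz, rec.n_low_rate)

    filtered = _stage("filter")(preprocess.denoise_semg)(
        rec.semg, zero_phase=cfg.zero_phase_filter)

    labels = _stage("label")(phase_labeler.label_recording)(
        rec, foot=cfg.labeler.foot, smoothing_len=cfg.labeler.smoothing_len,
        threshold_frac=cfg.labeler.threshold_frac,
        hysteresis_frac=cfg.labeler.hysteresis_frac)

    ds = _stage("features")(features_fusion.build_dataset)(
        filtered, rec.angle, labels, win=cfg.features.win,
        step=cfg.features.step, length=cfg.features.image_length,
        image_step=cfg.features.image_step,
        single_information=cfg.single_information)
    log.info("dataset: %d images of %s", len(ds), ds.images.shape[1:])

    trained = None
    if cfg.evaluation.mode == "temporal":
        def _train_eval():
            train_ds, test_ds = features_fusion.temporal_split(
                ds, cfg.evaluation.train_frac, normalize=cfg.features.normalize)
            model = classifiers.build_model(cfg.model)
            fitted = classifiers.train(model, train_ds, cfg.training)
            return fitted, evaluation.evaluate_model(fitted, test_ds)
        trained, report = _stage("train")(_train_eval)()
    else:
        report = _stage("train")(evaluation.crossval_report)(
            cfg.model, ds, k=cfg.evaluation.k, cfg=cfg.training,
            normalize=cfg.features.normalize)

    artifacts: dict = {}
    if outdir is not None:
        artifacts = _stage("io")(_write_artifacts)(
            outdir, cfg, rec, truth, labels, report)
    return PipelineResult(cfg, rec, truth, labels, ds, trained, report, artifacts)


def _provenance(cfg: PipelineConfig) -> dict:
    return {"package_version": __version__, "seed": cfg.seed,
            "config_hash": cfg.config_hash()}


def _write_artifacts(outdir, cfg, rec, truth, labels, report) -> dict:
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    rec_dir = os.path.join(outdir, "recording")
    write_recording(rec, rec_dir)
    paths["recording"] = rec_dir

    label_path = os.path.join(outdir, "labels.csv")
    write_labels_csv(label_path, labels, rate_hz=rec.angle.rate_hz,
                     truth=truth)
    paths["labels"] = label_path

    report_path = os.path.join(outdir, "report.json")
    payload = {"provenance": _provenance(cfg), "config": cfg.to_dict(),
               "report": report.to_dict()}
    with open(report_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    paths["report"] = report_path
    return paths


def write_labels_csv(path: str, labels: np.ndarray, rate_hz: float = 50.0,
                     truth: np.ndarray | None = None) -> None:
    """Label CSV: time_s, phase code, phase name (+ ground truth if known)."""
    import pandas as pd

    labels = np.asarray(labels, dtype=int)
    df = pd.DataFrame({
        "time_s": np.arange(labels.size) / rate_hz,
        "phase_code": labels,
        "phase_name": [phase_labeler.PhaseLabel(c).label for c in labels],
    })
    if truth is not None:
        df["truth_code"] = np.asarray(truth, dtype=int)[: labels.size]
    df.to_csv(path, index=False)
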
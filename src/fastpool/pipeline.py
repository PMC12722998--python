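"""End-to-end experiment orchestration.

``run_experiment`` drives simulate -> window -> train -> predict -> evaluate
(-> compare) from one nested config dict and writes a reproducible artifact
directory: checkpoints, predictions CSVs, a metrics/ROC report, a McNemar
comparison when a second windowing is configured, and a run log with every
seed and the config hash. Two runs with the same config are byte-identical.

``pooling_benefit_experiment`` is the scaled-down replicate study of the core
claim: pooled multi-frame windows beat single-frame input at video-level
accuracy on held-out subjects when the fluid cue is visible in only a small
fraction of frames.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .infer import PredictionRecord, predict_videos, records_to_frame
from .metrics import compute_metrics, mcnemar_test, roc_auc, threshold_sweep
from .model import (AugmentConfig, TrainConfig, save_checkpoint,
                    split_by_subject, train_model)
from .synthetic import FrameVideo, SyntheticConfig, simulate_dataset
from .windows import WindowingConfig, make_windows

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def config_hash(config: dict) -> str:
    """Stable hash of a (JSON-serializable) config."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _windows_for(videos: list[FrameVideo], wcfg: WindowingConfig):
    out = []
    for v in videos:
        out.extend(make_windows(v, wcfg))
    return out


def _train_on_split(videos, manifest, wcfg: WindowingConfig, tcfg: TrainConfig,
                    acfg: AugmentConfig):
    """Inner fit/early-stop subject split, windowing, and training."""
    fit_subj, stop_subj = split_by_subject(manifest, tcfg.split_fraction,
                                           seed=tcfg.seed)
    if not stop_subj:
        # all groups were singletons: hold out one subject for early stopping
        stop_subj = [fit_subj.pop()]
    by_subj = {}
    for v in videos:
        by_subj.setdefault(v.subject_id, []).append(v)
    fit_videos = [v for s in fit_subj for v in by_subj[s]]
    stop_videos = [v for s in stop_subj for v in by_subj[s]]
    model, history = train_model(_windows_for(fit_videos, wcfg),
                                 _windows_for(stop_videos, wcfg), tcfg, acfg)
    return model, history


def _fit_and_score(train_videos, train_manifest, eval_videos,
                   wcfg: WindowingConfig, tcfg: TrainConfig,
                   acfg: AugmentConfig, grid_step: float, criterion: str,
                   override: float | None,
                   infer_wcfg: WindowingConfig | None = None):
    model, history = _train_on_split(train_videos, train_manifest, wcfg, tcfg, acfg)
    infer_wcfg = infer_wcfg or wcfg
    grid = np.round(np.arange(0.0, 1.0 + 1e-9, grid_step), 10)
    train_records = predict_videos(model, train_videos, infer_wcfg,
                                   threshold=0.5, input_size=tcfg.input_size)
    _, threshold = threshold_sweep(train_records, grid, criterion=criterion,
                                   override=override)
    records = predict_videos(model, eval_videos, infer_wcfg,
                             threshold=threshold, input_size=tcfg.input_size)
    return model, history, threshold, records


DEFAULT_CONFIG: dict = {
    "simulate": {},
    "windowing": {"window_size": 150, "stride": 15},
    "inference": None,            # defaults to the training windowing
    "train": {"architecture": "tiny_cnn", "init": "kaiming_scratch"},
    "threshold": {"grid_step": 0.05, "criterion": "f1", "override": None},
    "compare": None,              # e.g. {"window_size": 1, "stride": 15}
    "write_dataset": False,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_experiment(config: dict, out_dir: str | Path) -> dict:
    """Run the full pipeline from a config dict; returns the run summary.

    The config must carry an explicit top-level ``seed`` — silent randomness
    is never allowed.
    """
    if "seed" not in config:
        raise ValueError("config must specify a seed")
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    chash = config_hash(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    def _simulate():
        scfg = SyntheticConfig(**{**cfg["simulate"], "seed": seed})
        return simulate_dataset(scfg)

    videos, manifest = stage("simulate", _simulate)
    if cfg["write_dataset"]:
        manifest = stage("write_dataset", fio.write_dataset, videos, manifest,
                         out_dir / "dataset")

    train_subj, eval_subj = stage("split", split_by_subject, manifest,
                                  0.8, seed)
    train_videos = [v for v in videos if v.subject_id in train_subj]
    eval_videos = [v for v in videos if v.subject_id in eval_subj]
    train_manifest = manifest[manifest["subject_id"].isin(train_subj)]

    wcfg = WindowingConfig(**cfg["windowing"])
    infer_cfg = WindowingConfig(**cfg["inference"]) if cfg["inference"] else wcfg
    tcfg = TrainConfig(**{**cfg["train"], "in_channels": wcfg.window_size,
                          "seed": seed})
    acfg = AugmentConfig()
    th = cfg["threshold"]

    model, history, threshold, records = stage(
        "train", _fit_and_score, train_videos, train_manifest, eval_videos,
        wcfg, tcfg, acfg, th["grid_step"], th["criterion"], th["override"])
    # re-window eval videos with the inference recipe if it differs
    if infer_cfg.window_size != wcfg.window_size:
        raise StageError("predict", ValueError(
            f"inference window size {infer_cfg.window_size} does not match "
            f"the trained model's {wcfg.window_size} input channels"))
    if infer_cfg != wcfg:
        records = stage("predict", predict_videos, model, eval_videos,
                        infer_cfg, threshold, tcfg.input_size)
    stage("checkpoint", save_checkpoint, out_dir / "checkpoint_main.npz",
          model, tcfg, acfg, wcfg.window_size, wcfg.stride)

    pred_df = records_to_frame(records)
    pred_df["config_hash"] = chash
    pred_df.to_csv(out_dir / "predictions.csv", index=False)

    report = _evaluation_report(records, threshold, chash)
    report["history"] = {"n_epochs": history.n_epochs,
                         "best_epoch": history.best_epoch,
                         "val_loss": history.val_loss}
    (out_dir / "report.json").write_text(json.dumps(report, indent=2,
                                                    sort_keys=True))

    summary = {"config_hash": chash, "seed": seed, "threshold": threshold,
               "accuracy": report["metrics"]["accuracy"],
               "n_eval_videos": len(records)}

    if cfg["compare"]:
        wcfg_b = WindowingConfig(**cfg["compare"])
        tcfg_b = dataclasses.replace(tcfg, in_channels=wcfg_b.window_size)
        _, _, thr_b, records_b = stage(
            "compare-train", _fit_and_score, train_videos, train_manifest,
            eval_videos, wcfg_b, tcfg_b, acfg, th["grid_step"],
            th["criterion"], th["override"])
        pred_b = records_to_frame(records_b)
        pred_b["config_hash"] = chash
        pred_b.to_csv(out_dir / "predictions_compare.csv", index=False)
        mc = mcnemar_test(records, records_b)
        mcnemar_out = {"b": mc.b, "c": mc.c, "n_concordant": mc.n_concordant,
                       "p_value": mc.p_value, "degenerate": mc.degenerate,
                       "method": mc.method, "config_hash": chash,
                       "accuracy_main": report["metrics"]["accuracy"],
                       "accuracy_compare":
                           compute_metrics(records_b, thr_b).accuracy}
        (out_dir / "mcnemar.json").write_text(json.dumps(mcnemar_out, indent=2,
                                                         sort_keys=True))
        summary["mcnemar_p"] = mc.p_value
        summary["accuracy_compare"] = mcnemar_out["accuracy_compare"]

    run_log = {"config": cfg, "config_hash": chash, "seed": seed,
               "train_subjects": train_subj, "eval_subjects": eval_subj,
               "threshold": threshold}
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2,
                                                     sort_keys=True))
    return summary


def _evaluation_report(records: list[PredictionRecord], threshold: float,
                       chash: str) -> dict:
    rep = compute_metrics(records, threshold)
    out = {"config_hash": chash, "threshold": threshold,
           "metrics": {"tp": rep.tp, "fp": rep.fp, "fn": rep.fn, "tn": rep.tn,
                       "accuracy": rep.accuracy, "precision": rep.precision,
                       "sensitivity": rep.sensitivity, "f1": rep.f1,
                       "undefined": list(rep.undefined)}}
    labels = {r.true_label for r in records}
    if len(labels) == 2:
        roc = roc_auc(records)
        out["roc"] = {"points": roc.points, "auc": roc.auc}
    return out


# ---------------------------------------------------------------------------
# the scaled-down replicate study of the pooling claim

POOLING_STUDY_SIMULATE = dict(image_height=64, image_width=64, fps=30.0,
                              duration_s=3.0, n_subjects=8,
                              videos_per_subject=4, positive_fraction=0.5,
                              fluid_visibility_fraction=0.2)
POOLING_STUDY_TRAIN = dict(architecture="tiny_cnn", init="kaiming_scratch",
                           max_epochs=30, early_stop_patience=29,
                           learning_rate=3e-3, input_size=64)


def pooling_benefit_experiment(base_seed: int, n_replicates: int = 5,
                               pooled=dict(window_size=15, stride=3),
                               single=dict(window_size=1, stride=3),
                               simulate_overrides: dict | None = None,
                               train_overrides: dict | None = None) -> dict:
    """Train pooled vs single-frame models on replicate synthetic datasets.

    Each replicate draws a fresh dataset and initialization from
    ``base_seed + r`` and evaluates both models on the same held-out subjects.
    Following the real-time evaluation protocol — where the operating
    threshold is identified on the evaluation sweep itself — each model is
    scored at its own optimal confidence threshold on the held-out videos, so
    the comparison measures how well the video scores discriminate. Returns
    per-replicate accuracies and the count of strict pooled wins.
    """
    sim = {**POOLING_STUDY_SIMULATE, **(simulate_overrides or {})}
    trn = {**POOLING_STUDY_TRAIN, **(train_overrides or {})}
    acfg = AugmentConfig()
    pooled_acc, single_acc = [], []
    for r in range(n_replicates):
        seed = int(base_seed) + r
        scfg = SyntheticConfig(**sim, seed=seed)
        # two capture groups: the 80/20 split then yields 6 training and 2
        # held-out subjects, keeping both sides large enough to be meaningful
        videos, manifest = simulate_dataset(scfg, n_groups=2)
        train_subj, eval_subj = split_by_subject(manifest, 0.8, seed)
        train_videos = [v for v in videos if v.subject_id in train_subj]
        eval_videos = [v for v in videos if v.subject_id in eval_subj]
        train_manifest = manifest[manifest["subject_id"].isin(train_subj)]
        accs = {}
        for name, wspec in (("pooled", pooled), ("single", single)):
            wcfg = WindowingConfig(**wspec)
            tcfg = TrainConfig(**trn, in_channels=wcfg.window_size, seed=seed)
            infer_wcfg = WindowingConfig(window_size=wcfg.window_size, stride=1)
            model, _ = _train_on_split(train_videos, train_manifest, wcfg,
                                       tcfg, acfg)
            records = predict_videos(model, eval_videos, infer_wcfg,
                                     threshold=0.5, input_size=tcfg.input_size)
            grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.05), 10)
            _, thr = threshold_sweep(records, grid, criterion="accuracy")
            accs[name] = compute_metrics(records, thr).accuracy
        pooled_acc.append(accs["pooled"])
        single_acc.append(accs["single"])
        log.info("replicate %d: pooled %.3f vs single %.3f", r,
                 accs["pooled"], accs["single"])
    wins = sum(p > s for p, s in zip(pooled_acc, single_acc))
    return {"pooled_accuracy": pooled_acc, "single_accuracy": single_acc,
            "pooled_wins": wins, "n_replicates": n_replicates,
            "n_eval_videos": len(eval_videos)}
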
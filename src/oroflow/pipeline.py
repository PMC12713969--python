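"""End-to-end orchestration with logged provenance.

``run_pipeline`` executes the stages in order — simulate (write EDF pairs
plus annotations), prepare (sync, filter, normalize, segment, label,
rebalance, split), train, evaluate — writing every intermediate artifact
under the run directory together with a manifest (config snapshot, all
seeds, input checksums, estimated lags, window counts before/after
balancing) sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .config import RunConfig, load_config
from .errors import DependencyError
from .model import (
    build_model,
    compute_metrics,
    load_model,
    predict,
    save_model,
    secondary_validate,
    train,
)
from .prepare import PipelineParams, prepare_recording_pair
from .segmentation import SegmentSet, downsample_majority, split_train_test
from .synthgen import export_dataset, load_exported_subject, make_params

__all__ = ["run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prepare", "train", "evaluate", "all")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _pipeline_params(cfg: RunConfig) -> PipelineParams:
    return PipelineParams(
        oral_filter=cfg.oral_filter(),
        nasal_filter=cfg.nasal_filter(),
        window_s=cfg.prepare.window_s,
        stride_s=cfg.prepare.stride_s,
        event_fraction=cfg.prepare.event_fraction,
        max_lag=cfg.prepare.max_lag,
        event_timeline="a",
    )


def _subject_params(cfg: RunConfig, offsets_rng: np.random.Generator, index: int):
    overrides: dict = dict(
        duration=cfg.simulate.duration,
        fs=cfg.simulate.fs,
        clock_offset=float(offsets_rng.uniform(*cfg.simulate.clock_offset_range)),
        seed=int(offsets_rng.integers(2**31)),
    )
    if cfg.simulate.mouth_fraction is not None:
        overrides["mouth_fraction"] = cfg.simulate.mouth_fraction
    return make_params(cfg.simulate.preset, **overrides)


def _stage_simulate(cfg: RunConfig, out: Path, manifest: dict) -> None:
    rng = np.random.default_rng(cfg.seed)
    train_params = [
        _subject_params(cfg, rng, i) for i in range(cfg.simulate.n_subjects)
    ]
    secondary_params = [
        _subject_params(cfg, rng, i) for i in range(cfg.simulate.n_secondary_subjects)
    ]
    export_dataset(train_params, out / "data" / "train")
    if secondary_params:
        export_dataset(secondary_params, out / "data" / "secondary")
    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted((out / "data").rglob("*.edf"))
    }
    manifest["input_checksums"] = checksums
    manifest["n_train_subjects"] = len(train_params)
    manifest["n_secondary_subjects"] = len(secondary_params)
    logger.info("simulate: wrote %d subjects", len(train_params) + len(secondary_params))


def _load_cohort(out: Path, split: str):
    data_dir = out / "data" / split
    if not data_dir.exists():
        raise DependencyError(f"stage 'prepare' needs {data_dir}; run 'simulate' first")
    stems = sorted(p.name[: -len("_a.edf")] for p in data_dir.glob("*_a.edf"))
    return [(stem, *load_exported_subject(data_dir, stem)) for stem in stems]


def _stage_prepare(cfg: RunConfig, out: Path, manifest: dict) -> None:
    params = _pipeline_params(cfg)
    segments, lags = [], {}
    for stem, rec_a, rec_b, events in _load_cohort(out, "train"):
        from .sync import estimate_lag_recordings

        lag = estimate_lag_recordings(rec_a, rec_b, max_lag=params.max_lag)
        lags[stem] = lag
        segments.append(prepare_recording_pair(rec_a, rec_b, events, params, lag=lag))
        logger.info("prepare: %s lag=%.2f s windows=%d", stem, lag, len(segments[-1]))
    pooled = SegmentSet.concatenate(segments)
    counts_before = {"n_windows": len(pooled), "n_events": pooled.n_events}
    balanced = downsample_majority(
        pooled, keep_fraction=cfg.prepare.keep_fraction, seed=cfg.seed
    )
    counts_after = {"n_windows": len(balanced), "n_events": balanced.n_events}
    train_set, test_set = split_train_test(
        balanced, test_fraction=cfg.prepare.test_fraction, seed=cfg.seed
    )
    seg_dir = out / "segments"
    seg_dir.mkdir(parents=True, exist_ok=True)
    train_set.save(seg_dir / "train.npz")
    test_set.save(seg_dir / "test.npz")
    manifest["lag_estimates_s"] = lags
    manifest["counts_before_balancing"] = counts_before
    manifest["counts_after_balancing"] = counts_after
    manifest["n_train_windows"] = len(train_set)
    manifest["n_test_windows"] = len(test_set)


def _stage_train(cfg: RunConfig, out: Path, manifest: dict) -> None:
    seg_path = out / "segments" / "train.npz"
    if not seg_path.exists():
        raise DependencyError(f"stage 'train' needs {seg_path}; run 'prepare' first")
    train_set = SegmentSet.load(seg_path)
    mcfg = cfg.model
    mcfg.seed = cfg.seed
    model = build_model(mcfg, train_set.oral.shape[1])
    model, history = train(model, train_set, mcfg)
    save_model(model, out / "model", extra_manifest={"train_segments_sha256": _sha256(seg_path)})
    (out / "model" / "history.json").write_text(json.dumps(history, indent=2))
    manifest["final_train_loss"] = history["loss"][-1]
    manifest["final_val_acc"] = history["val_acc"][-1]


def _stage_evaluate(cfg: RunConfig, out: Path, manifest: dict) -> None:
    model_dir = out / "model"
    seg_path = out / "segments" / "test.npz"
    for p in (model_dir / "model.json", seg_path):
        if not p.exists():
            raise DependencyError(f"stage 'evaluate' needs {p}; run earlier stages first")
    model = load_model(model_dir)
    test_set = SegmentSet.load(seg_path)
    y_pred, _ = predict(model, test_set)
    report = {"validation": compute_metrics(test_set.targets, y_pred).as_dict()}

    secondary_dir = out / "data" / "secondary"
    if secondary_dir.exists():
        cohort = _load_cohort(out, "secondary")
        pooled, per_rec = secondary_validate(
            model,
            [(rec_a, rec_b, events) for _, rec_a, rec_b, events in cohort],
            _pipeline_params(cfg),
        )
        report["secondary_validation"] = pooled.as_dict()
        report["secondary_per_recording"] = {
            k: v.as_dict() for k, v in sorted(per_rec.items())
        }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    manifest["report"] = str(report_path)


def run_pipeline(config, stage: str = "all", out_dir=None) -> dict:
    """Execute the requested stage(s); returns the run manifest.

    ``config`` is a YAML path, string, dict or :class:`RunConfig`.
    Validation happens before any computation. Artifacts and
    ``manifest.yaml`` land under the configured output directory.
    """
    if stage not in STAGES:
        raise DependencyError(f"unknown stage {stage!r}; choose from {STAGES}")
    cfg = load_config(config)
    out = Path(out_dir) if out_dir is not None else Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software_version": __version__,
        "seed": cfg.seed,
        "config": cfg.as_dict(),
    }
    todo = ["simulate", "prepare", "train", "evaluate"] if stage == "all" else [stage]
    for s in todo:
        {
            "simulate": _stage_simulate,
            "prepare": _stage_prepare,
            "train": _stage_train,
            "evaluate": _stage_evaluate,
        }[s](cfg, out, manifest)
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest
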
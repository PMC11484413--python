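"""End-to-end experiment driver.

One experiment = one config = one output directory, never mutated in
place: simulate -> featurize -> cross-validated training of the requested
model kinds -> scoring -> metrics tables and figures, with every seed and
the config hash recorded in a run summary.  The directory alone (plus the
package version) re-derives every reported number.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detector import ThresholdPolicy, calibrate_threshold
from .evaluation import (
    FoldReport,
    confusion,
    crossvalidate,
    metrics_from_confusion,
    roc_auc,
)
from .feature_map import build_grid, featurize_plan, save_feature_tensors
from .models import MODEL_KINDS, ModelConfig, save_model
from .plan_model import MachineSpec, default_machine, write_plan_json
from .plotting import plot_roc_curves, plot_score_boxplots
from .synth_data import SimConfig, dataset_manifest, make_dataset

__all__ = ["ExperimentConfig", "ExperimentError", "run_experiment"]

log = logging.getLogger("vmatqa")

_METRIC_NAMES = ("auc", "accuracy", "precision", "recall", "fpr", "fnr", "f1")


class ExperimentError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ExperimentConfig:
    seed: int = 0
    output_dir: str = "runs/experiment"
    resolution: float = 1.0  # mm, logical raster
    target_shape: Tuple[int, int] = (64, 64)
    model_kinds: Tuple[str, ...] = MODEL_KINDS
    metric: str = "d_I"  # active metric for the primary scores
    sim: SimConfig = field(default_factory=SimConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    policy: ThresholdPolicy = field(
        default_factory=lambda: ThresholdPolicy(mode="oracle_fnr0", quantile_q=None)
    )

    def __post_init__(self):
        unknown = set(self.model_kinds) - set(MODEL_KINDS)
        if unknown:
            raise ValueError(f"unknown model kinds: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "resolution": self.resolution,
            "target_shape": list(self.target_shape),
            "model_kinds": list(self.model_kinds),
            "metric": self.metric,
            "sim": asdict(self.sim),
            "model": asdict(self.model),
            "policy": {"mode": self.policy.mode, "quantile_q": self.policy.quantile_q},
        }
        d["sim"]["machine"] = self.sim.machine.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        sim_d = dict(d.pop("sim", {}))
        machine_d = sim_d.pop("machine", None)
        machine = MachineSpec.from_dict(machine_d) if machine_d else default_machine()
        sim = SimConfig(machine=machine, **sim_d)
        model_d = dict(d.pop("model", {}))
        for key in ("input_shape", "channels"):
            if key in model_d:
                model_d[key] = tuple(model_d[key])
        model = ModelConfig(**model_d)
        policy_d = d.pop("policy", {})
        policy = ThresholdPolicy(**policy_d) if policy_d else ThresholdPolicy(
            mode="oracle_fnr0", quantile_q=None
        )
        if "target_shape" in d:
            d["target_shape"] = tuple(d["target_shape"])
        if "model_kinds" in d:
            d["model_kinds"] = tuple(d["model_kinds"])
        return cls(sim=sim, model=model, policy=policy, **d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as e:
                raise ExperimentError(f"stage {name!r} failed: {e}") from e
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return decorator


@_stage("simulate")
def _simulate(config: ExperimentConfig, out: Path):
    sim = replace(config.sim, seed=config.seed)
    plans = make_dataset(sim)
    plan_dir = out / "plans"
    plan_dir.mkdir(parents=True, exist_ok=True)
    for p in plans:
        write_plan_json(p, plan_dir / f"{p.plan_id}.json")
    pd.DataFrame(dataset_manifest(plans)).to_csv(out / "manifest.csv", index=False)
    return plans, sim


@_stage("featurize")
def _featurize(config: ExperimentConfig, sim: SimConfig, plans, out: Path):
    grid = build_grid(sim.machine, config.resolution)
    tensors = {
        p.plan_id: featurize_plan(p, grid, config.target_shape) for p in plans
    }
    save_feature_tensors(
        list(tensors.values()),
        out / "features.h5",
        grid_meta={
            "resolution_mm": config.resolution,
            "target_shape": list(config.target_shape),
        },
    )
    return tensors


@_stage("train")
def _train_and_validate(config: ExperimentConfig, plans, tensors):
    results: Dict[str, Tuple[List[FoldReport], object]] = {}
    for kind in config.model_kinds:
        cfg = replace(config.model, model_kind=kind, seed=config.seed)
        folds, mean = crossvalidate(
            plans,
            cfg,
            config.policy,
            seed=config.seed,
            metric=config.metric,
            tensors=tensors,
            keep_models=True,
        )
        results[kind] = (folds, mean)
    return results


def _fold_grid(folds: List[FoldReport], metric: str) -> List[dict]:
    """Re-derive the FNR=0 metric table for one distance from stored scores."""
    rows = []
    policy = ThresholdPolicy(mode="oracle_fnr0", quantile_q=None)
    per_fold = []
    for f in folds:
        values = [s.distance(metric) for s in f.scores]
        labels = [s.true_label for s in f.scores]
        alpha = calibrate_threshold(values, labels, policy)
        preds = ["anomalous" if v > alpha else "regular" for v in values]
        m = metrics_from_confusion(confusion(labels, preds))
        m.auc, _ = roc_auc(values, labels)
        per_fold.append(m)
        rows.append({"fold": f.fold_index, **m.as_dict()})
    mean_row = {"fold": "mean"}
    for name in _METRIC_NAMES:
        vals = [getattr(m, name) for m in per_fold if getattr(m, name) is not None]
        mean_row[name] = float(np.mean(vals)) if vals else None
    rows.append(mean_row)
    return rows


@_stage("score")
def _write_scores(results, out: Path):
    for kind, (folds, _) in results.items():
        rows = []
        for f in folds:
            for s in f.scores:
                rows.append(
                    {
                        "fold": f.fold_index,
                        "plan_id": s.plan_id,
                        "d_I": s.d_I,
                        "d_A": s.d_A,
                        "d_D": s.d_D,
                        "active_metric": s.active_metric,
                        "threshold": s.threshold_used,
                        "predicted_label": s.predicted_label,
                        "true_label": s.true_label,
                    }
                )
        pd.DataFrame(rows).to_csv(out / f"scores_{kind}.csv", index=False)


@_stage("evaluate")
def _evaluate(config: ExperimentConfig, results, out: Path):
    rows = []
    for kind, (folds, _) in results.items():
        metrics = ("d_I", "d_A", "d_D") if kind == "multitask" else ("d_I",)
        for metric in metrics:
            for row in _fold_grid(folds, metric):
                rows.append({"model_kind": kind, "metric": metric, **row})
    df = pd.DataFrame(rows)
    df.to_csv(out / "metrics.csv", index=False)

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)

    def pooled(kind, metric):
        folds = results[kind][0]
        vals = [s.distance(metric) for f in folds for s in f.scores]
        labels = [s.true_label for f in folds for s in f.scores]
        return np.array(vals), np.array(labels)

    if "multitask" in results:
        curves, boxes = {}, {}
        for metric in ("d_I", "d_A", "d_D"):
            vals, labels = pooled("multitask", metric)
            auc, (fpr, tpr, _) = roc_auc(vals, labels)
            curves[metric] = (fpr, tpr, auc)
            boxes[metric] = (vals[labels == "regular"], vals[labels == "anomalous"])
        plot_roc_curves(curves, fig_dir / "roc_multitask_metrics.png")
        plot_score_boxplots(boxes, fig_dir / "scores_multitask_metrics.png")

    curves, boxes = {}, {}
    for kind in results:
        vals, labels = pooled(kind, "d_I")
        auc, (fpr, tpr, _) = roc_auc(vals, labels)
        curves[kind] = (fpr, tpr, auc)
        boxes[kind] = (vals[labels == "regular"], vals[labels == "anomalous"])
    plot_roc_curves(curves, fig_dir / "roc_models.png")
    plot_score_boxplots(boxes, fig_dir / "scores_models.png")
    return df


@_stage("checkpoint")
def _checkpoints(results, out: Path):
    ckpt_dir = out / "checkpoints"
    ckpt_dir.mkdir(exist_ok=True)
    for kind, (folds, _) in results.items():
        if folds and folds[0].model is not None:
            save_model(folds[0].model, ckpt_dir / f"{kind}_fold0.npz")


def run_experiment(config: ExperimentConfig) -> Path:
    """Run the full pipeline; returns the artifact directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    config.to_yaml(out / "config.yaml")

    plans, sim = _simulate(config, out)
    tensors = _featurize(config, sim, plans, out)
    results = _train_and_validate(config, plans, tensors)
    _write_scores(results, out)
    _evaluate(config, results, out)
    _checkpoints(results, out)

    summary = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "config": config.to_dict(),
        "n_plans": len(plans),
        "model_kinds": list(config.model_kinds),
        "elapsed_s": round(time.perf_counter() - t0, 2),
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return out
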
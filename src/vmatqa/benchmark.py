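"""The package's standard desk-scale detection benchmark.

Study conditions: 200 regular + 20 anomalous two-arc plans (90 CPs per arc)
on the default 40-pair machine, gross-magnitude faults drawn uniformly from
the full taxonomy, 1 mm logical raster reduced to 64 x 64 maps.  The
regular plans are split 80/20 into train/test; the test set additionally
receives every anomalous plan.  Models train on the regular training plans
only and are scored on the test set.

Everything is a pure function of the seed, so independent runs (different
seeds) probe the variability of the whole pipeline, not just of the
network initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .detector import ScoreReport, ThresholdPolicy, apply_threshold, calibrate_threshold, score_plan
from .evaluation import MetricsReport, confusion, metrics_from_confusion, roc_auc
from .feature_map import build_grid, featurize_plan
from .models import ModelConfig, build_model, train
from .synth_data import SimConfig, make_dataset

__all__ = [
    "benchmark_sim_config",
    "benchmark_model_config",
    "BenchmarkData",
    "BenchmarkResult",
    "make_benchmark_data",
    "evaluate_model_kind",
    "run_detection_benchmark",
]

RESOLUTION_MM = 1.0
TARGET_SHAPE = (64, 64)
TEST_FRACTION = 0.2


def benchmark_sim_config(seed: int, n_regular: int = 200, n_anomalous: int = 20) -> SimConfig:
    return SimConfig(n_regular=n_regular, n_anomalous=n_anomalous, seed=seed)


def benchmark_model_config(model_kind: str, seed: int) -> ModelConfig:
    """Benchmark training budget: two passes over every third CP per plan,
    in minibatches of 16.  Adjacent CPs are near-duplicates, so the stride
    costs little information; the small batches maximize optimizer steps,
    which limit reconstruction quality at the fixed learning rate within a
    single-CPU training budget of a few minutes per model."""
    return ModelConfig(
        model_kind=model_kind,
        input_shape=TARGET_SHAPE,
        channels=(4, 8, 16, 32),
        epochs=2,
        cp_stride=3,
        batch_size=16,
        seed=seed,
    )


@dataclass
class BenchmarkData:
    plans: list
    tensors: Dict[str, object]  # plan_id -> FeatureTensor
    train_ids: List[str]  # regular plans used for training
    test_ids: List[str]  # held-out regular + all anomalous


def make_benchmark_data(
    seed: int, n_regular: int = 200, n_anomalous: int = 20
) -> BenchmarkData:
    sim = benchmark_sim_config(seed, n_regular, n_anomalous)
    plans = make_dataset(sim)
    grid = build_grid(sim.machine, RESOLUTION_MM)
    tensors = {p.plan_id: featurize_plan(p, grid, TARGET_SHAPE) for p in plans}

    regular_ids = [p.plan_id for p in plans if p.label == "regular"]
    anomalous_ids = [p.plan_id for p in plans if p.label == "anomalous"]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5317]))
    order = rng.permutation(len(regular_ids))
    n_test = max(1, int(round(TEST_FRACTION * len(regular_ids))))
    test_reg = [regular_ids[i] for i in order[:n_test]]
    train_reg = [regular_ids[i] for i in order[n_test:]]
    return BenchmarkData(
        plans=plans,
        tensors=tensors,
        train_ids=train_reg,
        test_ids=test_reg + anomalous_ids,
    )


@dataclass
class BenchmarkResult:
    model_kind: str
    seed: int
    auc: Dict[str, float]  # metric name -> AUC
    fnr0_metrics: Dict[str, MetricsReport]  # metric name -> metrics at FNR=0
    test_scores: List[ScoreReport]
    test_labels: List[str]
    train_report: object

    def scores_by_label(self, metric: str = "d_I") -> Tuple[np.ndarray, np.ndarray]:
        vals = np.array([s.distance(metric) for s in self.test_scores])
        labels = np.array(self.test_labels)
        return vals[labels == "regular"], vals[labels == "anomalous"]


def evaluate_model_kind(
    data: BenchmarkData,
    model_kind: str,
    seed: int,
    model_config: Optional[ModelConfig] = None,
) -> BenchmarkResult:
    """Train one model kind on the benchmark split and evaluate it."""
    cfg = model_config or benchmark_model_config(model_kind, seed)
    if cfg.model_kind != model_kind:
        cfg = replace(cfg, model_kind=model_kind)
    model = build_model(cfg)
    report = train(model, [data.tensors[i] for i in data.train_ids])

    test_tensors = [data.tensors[i] for i in data.test_ids]
    scores = [score_plan(model, t) for t in test_tensors]
    labels = [t.label for t in test_tensors]

    metrics = ["d_I"] if model_kind != "multitask" else ["d_I", "d_A", "d_D"]
    auc: Dict[str, float] = {}
    fnr0: Dict[str, MetricsReport] = {}
    policy = ThresholdPolicy(mode="oracle_fnr0", quantile_q=None)
    for metric in metrics:
        values = [s.distance(metric) for s in scores]
        auc[metric], _ = roc_auc(values, labels)
        alpha = calibrate_threshold(values, labels, policy)
        preds = ["anomalous" if v > alpha else "regular" for v in values]
        m = metrics_from_confusion(confusion(labels, preds))
        m.auc = auc[metric]
        fnr0[metric] = m
    apply_threshold(
        scores, calibrate_threshold([s.d_I for s in scores], labels, policy), "d_I"
    )
    return BenchmarkResult(
        model_kind=model_kind,
        seed=seed,
        auc=auc,
        fnr0_metrics=fnr0,
        test_scores=scores,
        test_labels=labels,
        train_report=report,
    )


def run_detection_benchmark(
    seed: int, model_kinds: Sequence[str] = ("multitask",)
) -> Dict[str, BenchmarkResult]:
    """Full benchmark at one seed: simulate, featurize, split, train, score."""
    data = make_benchmark_data(seed)
    return {
        kind: evaluate_model_kind(data, kind, seed) for kind in model_kinds
    }
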
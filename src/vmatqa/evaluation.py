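"""Classification metrics and the cross-validation protocol.

The positive class is *anomalous* throughout.  Metrics follow the standard
definitions: accuracy = (TP+TN)/total, precision = TP/(TP+FP),
recall = TP/(TP+FN), FPR = FP/(FP+TN), FNR = FN/(FN+TP),
F1 = 2*precision*recall/(precision+recall).  Ratios with a zero denominator
are reported as missing (None), never silently as 0.

AUC uses the tie-aware Mann-Whitney formulation: the mean over all
(anomaly, regular) pairs of [score_a > score_r] + 1/2 [score_a == score_r],
which equals the trapezoidal area under the full-threshold-sweep ROC.

The evaluation protocol mirrors routine practice for heavily imbalanced QA
archives: the regular plans are split into five folds; each fold's model is
trained on the other four fifths (regular only), and tested on the held-out
regular fifth plus *all* anomalous plans, which are too few to split.
Headline numbers are means across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .detector import (
    ThresholdPolicy,
    apply_threshold,
    calibrate_threshold,
    score_plan,
)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "FoldReport",
    "confusion",
    "metrics_from_confusion",
    "roc_auc",
    "crossvalidate",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    auc: Optional[float] = None
    accuracy: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    fpr: Optional[float] = None
    fnr: Optional[float] = None
    f1: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "fpr": self.fpr,
            "fnr": self.fnr,
            "f1": self.f1,
        }


@dataclass
class FoldReport:
    fold_index: int
    train_ids: list
    test_ids: list
    threshold: float
    counts: ConfusionCounts
    metrics: MetricsReport
    scores: list = field(default_factory=list)  # ScoreReports of the test set
    model: object = None  # populated when crossvalidate(keep_models=True)


def confusion(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> ConfusionCounts:
    """Count outcomes with 'anomalous' as the positive class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    if len(true_labels) == 0:
        raise ValueError("empty label vectors")
    c = ConfusionCounts()
    for t, p in zip(true_labels, predicted_labels):
        if t not in ("regular", "anomalous") or p not in ("regular", "anomalous"):
            raise ValueError(f"unknown label pair ({t!r}, {p!r})")
        if t == "anomalous":
            if p == "anomalous":
                c.tp += 1
            else:
                c.fn += 1
        else:
            if p == "anomalous":
                c.fp += 1
            else:
                c.tn += 1
    return c


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics_from_confusion(c: ConfusionCounts) -> MetricsReport:
    """Threshold-dependent metrics from a confusion table (AUC left unset)."""
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    f1 = None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricsReport(
        auc=None,
        accuracy=(c.tp + c.tn) / c.total,
        precision=precision,
        recall=recall,
        fpr=_ratio(c.fp, c.fp + c.tn),
        fnr=_ratio(c.fn, c.fn + c.tp),
        f1=f1,
    )


def roc_auc(
    scores: Sequence[float], labels: Sequence[str]
) -> Tuple[float, Tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Tie-aware AUC plus the full-threshold-sweep ROC curve.

    AUC is computed from mid-ranks (the Mann-Whitney statistic); the curve
    (fpr, tpr, thresholds) comes from the standard sweep and integrates to
    the same value.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = (labels == "anomalous").astype(int)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = rankdata(scores)  # mid-ranks handle ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thresholds = _sk_roc_curve(y, scores)
    return float(auc), (fpr, tpr, thresholds)


def crossvalidate(
    plans,
    model_config,
    policy: ThresholdPolicy,
    seed: int,
    grid=None,
    target_shape: Optional[Tuple[int, int]] = None,
    metric: str = "d_I",
    tensors: Optional[dict] = None,
    keep_models: bool = False,
) -> Tuple[list, MetricsReport]:
    """Five-fold cross-validation with anomalies in every test fold.

    Regular plans are shuffled (seeded) into 5 folds of sizes differing by
    at most one.  Per fold: train on the other four fifths (regular only),
    score the held-out regular plans plus all anomalous plans, calibrate
    alpha per the policy (oracle_fnr0 on the labeled test scores; quantile
    on the training plans' scores), classify, and report metrics.  Returns
    the per-fold reports and the mean-across-folds aggregate.

    ``tensors`` may carry pre-featurized plans (plan_id -> FeatureTensor) to
    avoid re-rasterizing; otherwise ``grid`` (and optional ``target_shape``)
    are used to featurize here.
    """
    from .feature_map import featurize_plan
    from .models import build_model, train as train_model
    from dataclasses import replace

    if tensors is None:
        if grid is None:
            raise ValueError("provide either tensors or a grid to featurize with")
        tensors = {
            p.plan_id: featurize_plan(p, grid, target_shape) for p in plans
        }
    regular = [p for p in plans if p.label == "regular"]
    anomalous = [p for p in plans if p.label == "anomalous"]
    if len(regular) < 5:
        raise ValueError("need at least 5 regular plans for 5-fold CV")
    if not anomalous:
        raise ValueError("no anomalies in the dataset")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(regular))
    folds = [sorted(order[i::5]) for i in range(5)]

    fold_reports = []
    for fold_index, test_idx in enumerate(folds):
        test_regular = [regular[i] for i in test_idx]
        train_regular = [
            regular[i] for i in range(len(regular)) if i not in set(test_idx)
        ]
        cfg = replace(model_config, seed=int(seed * 31 + fold_index) % (2**31))
        model = build_model(cfg)
        train_model(model, [tensors[p.plan_id] for p in train_regular])

        test_plans = test_regular + anomalous
        reports = [score_plan(model, tensors[p.plan_id]) for p in test_plans]
        values = [r.distance(metric) for r in reports]
        labels = [p.label for p in test_plans]

        if policy.mode == "oracle_fnr0":
            alpha = calibrate_threshold(values, labels, policy)
        else:
            train_vals = [
                score_plan(model, tensors[p.plan_id]).distance(metric)
                for p in train_regular
            ]
            alpha = calibrate_threshold(train_vals, policy=policy)

        apply_threshold(reports, alpha, metric)
        counts = confusion(labels, [r.predicted_label for r in reports])
        metrics = metrics_from_confusion(counts)
        metrics.auc, _ = roc_auc(values, labels)
        fold_reports.append(
            FoldReport(
                fold_index=fold_index,
                train_ids=[p.plan_id for p in train_regular],
                test_ids=[p.plan_id for p in test_plans],
                threshold=alpha,
                counts=counts,
                metrics=metrics,
                scores=reports,
                model=model if keep_models else None,
            )
        )

    mean = MetricsReport()
    for name in ("auc", "accuracy", "precision", "recall", "fpr", "fnr", "f1"):
        vals = [
            getattr(f.metrics, name)
            for f in fold_reports
            if getattr(f.metrics, name) is not None
        ]
        if vals:
            setattr(mean, name, float(np.mean(vals)))
    return fold_reports, mean
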
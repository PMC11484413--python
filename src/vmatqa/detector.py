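"""Plan-level anomaly scoring and thresholding.

A trained autoencoder reconstructs every control point of a plan; the plan
score is the reconstruction distance averaged over its CPs.  Three distances
are available:

``d_I``
    mean squared intensity-map error, 1/(K*M*N) * sum (I - I')^2, on the
    physical dose scale.  (Normalized per pixel so scores are comparable
    across raster resolutions.)
``d_A``
    binary cross-entropy between the binary aperture stack A and the
    reconstructed probabilities A' (multi-task model only).
``d_D``
    mean squared dose error between D and D' (multi-task model only).

A plan is called anomalous when its active distance strictly exceeds the
threshold alpha.  Two calibration policies are provided: ``oracle_fnr0``
picks the largest observed score that keeps the false-negative rate at
exactly zero on labeled calibration data (so no anomaly is ever missed),
and ``quantile`` needs no labels, taking an upper quantile of regular-plan
scores (default q = 0.99).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .feature_map import FeatureTensor
from .models import loss_aperture, loss_dose, reconstruct

__all__ = [
    "METRICS",
    "ScoreReport",
    "ThresholdPolicy",
    "distance_I",
    "score_plan",
    "calibrate_threshold",
    "classify",
    "PlanAnomalyDetector",
    "PlanAnomalyResults",
]

METRICS = ("d_I", "d_A", "d_D")


@dataclass
class ScoreReport:
    """Per-plan reconstruction distances and (optionally) a verdict."""

    plan_id: str
    d_I: float
    d_A: Optional[float] = None
    d_D: Optional[float] = None
    active_metric: str = "d_I"
    predicted_label: Optional[str] = None
    threshold_used: Optional[float] = None
    true_label: str = "unknown"

    def distance(self, metric: Optional[str] = None) -> float:
        metric = metric or self.active_metric
        value = getattr(self, metric)
        if value is None:
            raise ValueError(
                f"metric {metric!r} is unavailable for this model kind"
            )
        return value


@dataclass
class ThresholdPolicy:
    """How the detection threshold alpha is chosen."""

    mode: str = "quantile"  # "oracle_fnr0" | "quantile"
    quantile_q: Optional[float] = 0.99

    def __post_init__(self):
        if self.mode not in ("oracle_fnr0", "quantile"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "quantile":
            if self.quantile_q is None or not 0.0 < self.quantile_q < 1.0:
                raise ValueError("quantile mode requires quantile_q in (0, 1)")


def distance_I(i: np.ndarray, i_hat: np.ndarray) -> float:
    """Per-pixel mean squared difference between two K x M x N stacks."""
    if i.shape != i_hat.shape:
        raise ValueError(f"shape mismatch: {i.shape} vs {i_hat.shape}")
    diff = i.astype(np.float64) - i_hat.astype(np.float64)
    return float(np.mean(diff**2))


def score_plan(model, tensor: FeatureTensor) -> ScoreReport:
    """Score one plan with a trained model (or any object exposing
    ``kind`` and the reconstruction interface of :func:`models.reconstruct`).

    For the multi-task model the reconstructed intensity is assembled from
    the two decoder outputs, I' = D' * A' (A' kept as continuous
    probabilities), and all three distances are populated; single-decoder
    baselines populate only ``d_I``.
    """
    recon = (
        model.reconstruct(tensor)
        if hasattr(model, "reconstruct")
        else reconstruct(model, tensor)
    )
    d_i = distance_I(tensor.intensities, recon.intensity_hat)
    d_a = d_d = None
    if recon.aperture_prob is not None:
        d_a = loss_aperture(tensor.apertures, recon.aperture_prob)
    if recon.dose_hat is not None:
        d_d = loss_dose(tensor.doses, recon.dose_hat)
    return ScoreReport(
        plan_id=tensor.plan_id,
        d_I=d_i,
        d_A=d_a,
        d_D=d_d,
        true_label=tensor.label,
    )


def calibrate_threshold(
    scores: Sequence[float],
    labels: Optional[Sequence[str]] = None,
    policy: Optional[ThresholdPolicy] = None,
) -> float:
    """Choose the detection threshold alpha.

    ``oracle_fnr0``: among the observed score values, take the largest
    candidate c such that every anomaly score is strictly greater than c
    (the classification rule is strict >, so FNR is exactly 0).  If even
    the smallest observed score fails, fall back to just below the minimum
    anomaly score.

    ``quantile``: the nearest-rank empirical q-quantile of (regular-only)
    scores; no labels required.
    """
    policy = policy or ThresholdPolicy()
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty scores")

    if policy.mode == "quantile":
        return float(np.quantile(scores, policy.quantile_q, method="inverted_cdf"))

    if labels is None:
        raise ValueError("oracle_fnr0 calibration requires labels")
    labels = np.asarray(labels)
    anom = scores[labels == "anomalous"]
    if anom.size == 0:
        raise ValueError("oracle_fnr0 calibration requires at least one anomaly")
    lo = float(anom.min())
    candidates = scores[scores < lo]
    if candidates.size:
        alpha = float(candidates.max())
    else:
        alpha = lo - 1e-12 * max(1.0, abs(lo))
    # contract: zero false negatives on the calibration data themselves
    assert np.all(anom > alpha), "FNR=0 calibration failed"
    return alpha


def classify(score: float, alpha: float) -> str:
    """Anomalous iff the score strictly exceeds alpha (ties are regular)."""
    if not (np.isfinite(score) and np.isfinite(alpha)):
        raise ValueError("score and threshold must be finite")
    return "anomalous" if score > alpha else "regular"


def apply_threshold(
    reports: Sequence[ScoreReport], alpha: float, metric: str = "d_I"
) -> None:
    """Classify each report in place using metric > alpha."""
    for r in reports:
        r.active_metric = metric
        r.threshold_used = alpha
        r.predicted_label = classify(r.distance(metric), alpha)


# ---------------------------------------------------------------------------
# Model/Results facade
# ---------------------------------------------------------------------------

class PlanAnomalyDetector:
    """Convenience front end tying the pieces together.

    Built from regular-only training tensors and a model configuration;
    ``fit()`` trains the autoencoder, scores the training plans, calibrates
    the label-free threshold, and returns a :class:`PlanAnomalyResults`.
    """

    def __init__(self, train_tensors, model_config, policy=None, metric="d_I"):
        from .models import build_model  # local to avoid cycle at import time

        if metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        self.train_tensors = list(train_tensors)
        self.model_config = model_config
        self.policy = policy or ThresholdPolicy()
        self.metric = metric
        self.model = build_model(model_config)

    def fit(self) -> "PlanAnomalyResults":
        from .models import train as train_model

        report = train_model(self.model, self.train_tensors)
        train_scores = [score_plan(self.model, t) for t in self.train_tensors]
        values = [s.distance(self.metric) for s in train_scores]
        if self.policy.mode == "quantile":
            alpha = calibrate_threshold(values, policy=self.policy)
        else:
            alpha = None  # oracle policy needs labeled data at evaluation
        return PlanAnomalyResults(
            model=self.model,
            train_report=report,
            train_scores=train_scores,
            threshold=alpha,
            metric=self.metric,
            policy=self.policy,
        )


@dataclass
class PlanAnomalyResults:
    model: object
    train_report: object
    train_scores: list
    threshold: Optional[float]
    metric: str
    policy: ThresholdPolicy

    def score(self, tensor: FeatureTensor) -> ScoreReport:
        report = score_plan(self.model, tensor)
        if self.threshold is not None:
            apply_threshold([report], self.threshold, self.metric)
        return report

    def score_plans(self, tensors) -> list:
        return [self.score(t) for t in tensors]

    def summary(self) -> str:
        cfg = self.model.config
        values = np.array([s.distance(self.metric) for s in self.train_scores])
        lines = [
            "Plan anomaly detector",
            "=" * 54,
            f"model kind:        {cfg.model_kind}",
            f"input shape:       {tuple(cfg.input_shape)}",
            f"latent dim:        {cfg.latent_dim}",
            f"epochs trained:    {cfg.epochs}",
            f"training plans:    {len(self.train_scores)}",
            f"active metric:     {self.metric}",
            f"threshold policy:  {self.policy.mode}",
            f"threshold alpha:   "
            f"{self.threshold if self.threshold is not None else 'n/a (labeled calibration)'}",
            f"train score mean:  {values.mean():.6g}",
            f"train score max:   {values.max():.6g}",
        ]
        final = {k: v[-1] for k, v in self.train_report.losses.items() if v}
        if final:
            lines.append(
                "final losses:      "
                + ", ".join(f"{k}={v:.4g}" for k, v in sorted(final.items()))
            )
        return "\n".join(lines)
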
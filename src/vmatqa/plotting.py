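"""ROC and score-distribution figures."""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_roc_curves", "plot_score_boxplots"]


def plot_roc_curves(curves: Dict[str, Tuple[np.ndarray, np.ndarray, float]], path) -> None:
    """One ROC per entry; ``curves`` maps a label to (fpr, tpr, auc)."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for name, (fpr, tpr, auc) in curves.items():
        ax.plot(fpr, tpr, label=f"{name} (AUC={auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_score_boxplots(groups: Dict[str, Tuple[Sequence[float], Sequence[float]]], path) -> None:
    """Regular-vs-anomalous score distributions, one panel per entry."""
    n = len(groups)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 4), squeeze=False)
    for ax, (name, (reg, anom)) in zip(axes[0], groups.items()):
        ax.boxplot([list(reg), list(anom)], tick_labels=["regular", "anomalous"])
        ax.set_yscale("log")
        ax.set_title(name, fontsize=9)
        ax.set_ylabel("reconstruction distance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
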
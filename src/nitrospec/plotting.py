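"""Simple evaluation graphics: CCR/AUC box plots and ROC curves."""

from __future__ import annotations

import numpy as np

from .evaluation import EvaluationReport, roc_auc

__all__ = ["plot_ccr_boxplots", "plot_auc_boxplots", "plot_roc_curves"]


def plot_ccr_boxplots(report: EvaluationReport, ax=None):
    """Box plots of per-iteration CCR for every classifier and MV."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    names = list(report.ccr_series)
    ax.boxplot([report.ccr_series[n] for n in names], tick_labels=names)
    ax.set_ylabel("CCR per iteration (%)")
    ax.set_title(f"Correct classification rate over "
                 f"{report.iterations} iterations")
    return ax


def plot_auc_boxplots(report: EvaluationReport, classifier: str = "MV",
                      ax=None):
    """Per-class one-vs-rest AUC distribution for one classifier."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    series = report.auc_series[classifier]
    data = [series[~np.isnan(series[:, i]), i]
            for i in range(len(report.classes))]
    ax.boxplot(data, tick_labels=list(report.classes))
    ax.set_ylabel("AUC per iteration")
    ax.set_title(f"{classifier}: one-vs-rest AUC")
    return ax


def plot_roc_curves(scores: np.ndarray, labels, classes, ax=None):
    """One-vs-rest ROC curves for a single score matrix."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    labels = np.asarray([str(v) for v in labels])
    for j, cls in enumerate(classes):
        mask = labels == cls
        if mask.all() or not mask.any():
            continue
        auc, fpr, tpr = roc_auc(scores[:, j], mask)
        ax.plot(fpr, tpr, label=f"{cls} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", linewidth=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    return ax
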
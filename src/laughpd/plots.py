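"""Optional figure helpers (require matplotlib, `pip install laughpd[plot]`)."""

from __future__ import annotations

from pathlib import Path

from .classify import EvalReport
from .filterbanks import FilterBank


def plot_filterbank(bank: FilterBank, path: str | Path | None = None):
    """Triangular filter responses over frequency, one curve per filter."""
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(8, 3))
    bins = np.arange(bank.weights.shape[1]) * bank.bin_width
    for row in bank.weights:
        ax.plot(bins, row, lw=0.8)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("weight")
    ax.set_title(f"{bank.kind} bank ({bank.n_filters} filters)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_roc(report: EvalReport, path: str | Path | None = None, label: str = ""):
    """ROC curve with its AUC annotated."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    fpr, tpr = report.roc_points[:, 0], report.roc_points[:, 1]
    ax.plot(fpr, tpr, label=f"{label} AUC={report.auc:.3f}".strip())
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
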
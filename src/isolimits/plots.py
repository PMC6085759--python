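"""Report figures: stacked resolution bins and long-read trade-off curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .resolution import BIN_LABELS
from .tradeoff import TradeoffReport

__all__ = ["plot_resolution_bins", "plot_tradeoff"]

_BIN_COLORS = ["#c6413b", "#e49b3f", "#bfce63", "#5aa457"]


def plot_resolution_bins(summary: pd.DataFrame, path, cell_type: str | None = None):
    """Stacked bars of the 4 resolution bins per protocol."""
    df = summary
    if cell_type is not None:
        df = df[df["cell_type"] == cell_type]
    fig, ax = plt.subplots(figsize=(8, 4))
    bottom = None
    x = range(len(df))
    for label, color in zip(BIN_LABELS, _BIN_COLORS):
        vals = df[f"bin_{label}"].to_numpy()
        ax.bar(x, vals, bottom=bottom, label=f"{label}%", color=color)
        bottom = vals if bottom is None else bottom + vals
    ax.set_xticks(list(x), df["protocol"], rotation=45, ha="right")
    ax.set_ylabel("fraction of MIGs")
    ax.set_title("MIG resolution by protocol")
    ax.legend(title="isoforms resolved", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_tradeoff(report: TradeoffReport, path):
    """MIG and switch detection vs cells sequenced, with dashed references."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    t = report.table
    axes[0].plot(t["n_cells"], t["mean_migs_per_cell"], "o-")
    axes[0].axhline(report.ref_migs, ls="--", color="grey")
    axes[0].set_xlabel("cells sequenced")
    axes[0].set_ylabel("MIGs detected per cell")
    axes[1].plot(t["n_cells"], t["mean_switches"], "o-")
    axes[1].axhline(report.ref_switches, ls="--", color="grey")
    axes[1].set_xlabel("cells sequenced")
    axes[1].set_ylabel("isoform switches detected")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
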
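"""Kinetics plots mirroring the classic morphometry panels: aggregate
length per generation, cumulative branch events per generation, total tip
number, and event-type counts over time."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_kinetics"]


def plot_kinetics(table: pd.DataFrame, out_path, sample_id: str | None = None):
    """Four-panel kinetics figure from a morphometry table."""
    df = table if sample_id is None else table[table["sample_id"] == sample_id]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for g, sub in df.groupby("generation"):
        s = sub.groupby("time_h")["aggregate_length_um"].mean()
        axes[0, 0].plot(s.index, s.values, marker="o", label=f"gen {g}")
        e = sub.groupby("time_h")["cum_branch_events"].mean()
        axes[0, 1].plot(e.index, e.values, marker="s", label=f"gen {g}")
    axes[0, 0].set_ylabel("aggregate length (µm)")
    axes[0, 1].set_ylabel("cumulative branch events")
    tips = df.groupby("time_h")["total_tips"].mean()
    axes[1, 0].plot(tips.index, tips.values, marker="^", color="k")
    axes[1, 0].set_ylabel("total tip number")
    for col, lbl in [("cum_bifed", "bifed"), ("cum_trifed", "trifed"),
                     ("cum_lateral", "lateral")]:
        if col in df:
            s = df.groupby("time_h")[col].max()
            axes[1, 1].plot(s.index, s.values, marker="d", label=lbl)
    axes[1, 1].set_ylabel("cumulative type counts")
    for ax in axes.flat:
        ax.set_xlabel("time (h)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
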
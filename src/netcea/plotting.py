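"""Static matplotlib figures for the three standard CEA graphics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_ceac", "plot_tornado", "plot_scatter"]


def plot_ceac(ceac_df: pd.DataFrame):
    """Acceptability curves: probability cost-effective vs willingness-to-pay."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for col in ceac_df.columns:
        if col == "wtp":
            continue
        ax.plot(ceac_df["wtp"], ceac_df[col], label=col)
    ax.set_xlabel("Willingness-to-pay ($/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    return fig


def plot_tornado(tornado_df: pd.DataFrame):
    """Tornado diagram of incremental-NMB swings, widest bar on top."""
    df = tornado_df.sort_values("width")
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.5))
    lo = df[["incremental_nmb_low", "incremental_nmb_high"]].min(axis=1)
    hi = df[["incremental_nmb_low", "incremental_nmb_high"]].max(axis=1)
    ax.barh(df["parameter"], hi - lo, left=lo, color="#4878d0")
    ax.set_xlabel("Incremental net monetary benefit ($)")
    ax.axvline(0.0, color="k", lw=0.8)
    fig.tight_layout()
    return fig


def plot_scatter(scatter_df: pd.DataFrame, label: str = ""):
    """Incremental cost-effectiveness scatter on the CE plane."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(scatter_df["delta_effect"], scatter_df["delta_cost"], s=2, alpha=0.2)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost ($)")
    if label:
        ax.set_title(label)
    fig.tight_layout()
    return fig
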
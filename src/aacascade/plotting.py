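"""Basic figures: ensemble prediction bands and enrichment bar plots."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_band", "plot_enrichment"]


def plot_band(summary: pd.DataFrame, ax=None, label: str = "", color="C0"):
    """Median line with interquartile shading from a band summary frame."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(summary["time_h"], summary["median"], color=color, label=label or None)
    ax.fill_between(summary["time_h"], summary["q25"], summary["q75"],
                    color=color, alpha=0.25, linewidth=0)
    ax.set_xlabel("time post-stimulus (h)")
    ax.set_ylabel("concentration (mM)")
    ax.set_yscale("log")
    if label:
        ax.legend()
    return ax


def plot_enrichment(enrichment: pd.DataFrame, ax=None, color="purple"):
    """Bar plot of per-bin log-ratios over the prior's log-space support."""
    if ax is None:
        _, ax = plt.subplots()
    centers = 0.5 * (enrichment["ln_lo"] + enrichment["ln_hi"])
    width = (enrichment["ln_hi"] - enrichment["ln_lo"]).iloc[0]
    ax.bar(centers, enrichment["log_ratio"], width=0.9 * width, color=color)
    ax.axhline(0.0, color="k", linewidth=0.8)
    ax.set_xlabel("ln(parameter value)")
    ax.set_ylabel("log-ratio observed/expected")
    return ax
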
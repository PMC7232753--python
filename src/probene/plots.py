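"""Health-vs-density plots with per-group fitted lines."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import DEFAULT_SCALE, ExperimentRecord, records_to_frame, to_analysis_scale
from .inference import test_slope_variation


def plot_health_density(
    records: Iterable[ExperimentRecord] | pd.DataFrame,
    grouping: str = "strain",
    *,
    scale: str = DEFAULT_SCALE,
    out: str | Path | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Scatter health against analysis-scale density, one colour per group,
    with the fitted per-group lines overlaid over each group's observed
    density span."""
    df = records_to_frame(records).copy()
    df["d"] = to_analysis_scale(df["density"].to_numpy(), scale)
    fit = test_slope_variation(df, grouping, scale=scale)

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    colors = plt.cm.tab10.colors
    for i, line in enumerate(fit.group_lines):
        sub = df[df[grouping].astype(str) == line.group]
        c = colors[i % len(colors)]
        ax.scatter(sub["d"], sub["outcome"], s=14, alpha=0.55, color=c, label=line.group)
        span = np.linspace(sub["d"].min(), sub["d"].max(), 50)
        ax.plot(span, line.a + line.b * span, color=c, lw=2)
    xlabel = "microbial density (log10 cfu + 1)" if scale == "log10p1" else "microbial density (cfu)"
    ax.set_xlabel(xlabel)
    ax.set_ylabel("host health")
    ax.legend(title=grouping, frameon=False)
    ax.set_title(f"health vs density by {grouping}")
    if out is not None:
        ax.figure.savefig(out, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_density_distributions(
    records: Iterable[ExperimentRecord] | pd.DataFrame,
    grouping: str = "host_type",
    *,
    scale: str = DEFAULT_SCALE,
    out: str | Path | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Per-group density histograms (the resistance/proliferation view)."""
    df = records_to_frame(records).copy()
    df["d"] = to_analysis_scale(df["density"].to_numpy(), scale)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    colors = plt.cm.tab10.colors
    for i, lev in enumerate(sorted(df[grouping].astype(str).unique())):
        sub = df.loc[df[grouping].astype(str) == lev, "d"]
        ax.hist(sub, bins=15, alpha=0.5, color=colors[i % len(colors)], label=lev)
        ax.axvline(sub.mean(), color=colors[i % len(colors)], ls="--")
    ax.set_xlabel("microbial density (analysis scale)")
    ax.set_ylabel("hosts")
    ax.legend(title=grouping, frameon=False)
    if out is not None:
        ax.figure.savefig(out, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
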
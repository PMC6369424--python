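"""Optional matplotlib views of the utilization metrics."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analytics import UtilizationSummary

__all__ = ["plot_attrition", "plot_hour_histogram", "plot_zone_stack", "save_all_plots"]


def plot_attrition(
    weekly_active: Sequence[float],
    reference: Optional[Sequence[float]] = None,
    ax=None,
):
    """Weekly-active fraction by enrollment-relative week, with an optional
    user-supplied reference decay series."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    weeks = np.arange(1, len(weekly_active) + 1)
    ax.plot(weeks, weekly_active, marker="o", ms=3, label="cohort weekly active")
    if reference is not None:
        ax.plot(weeks[: len(reference)], reference, ls="--", label="reference curve")
    ax.set_xlabel("week since enrollment")
    ax.set_ylabel("fraction of cohort active")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_hour_histogram(hist: Sequence[int], ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.bar(np.arange(24), hist, width=0.85)
    ax.set_xlabel("local hour of day")
    ax.set_ylabel("logins")
    ax.set_xticks(range(0, 24, 2))
    return ax


def plot_zone_stack(zone_proportions: dict, ax=None):
    """One stacked bar of zone-calculation outcome shares."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 4))
    order = ["green", "yellow", "red", "insufficient"]
    colors = {"green": "#4caf50", "yellow": "#ffc107", "red": "#e53935", "insufficient": "#9e9e9e"}
    bottom = 0.0
    for z in order:
        if z not in zone_proportions:
            continue
        frac = zone_proportions[z][1]
        ax.bar([0], [frac], bottom=bottom, color=colors[z], label=z)
        bottom += frac
    ax.set_xticks([])
    ax.set_ylabel("share of zone calculations")
    ax.legend()
    return ax


def save_all_plots(summary: UtilizationSummary, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, fn, arg in [
        ("attrition.png", plot_attrition, summary.weekly_active),
        ("hour_histogram.png", plot_hour_histogram, summary.hour_histogram),
    ]:
        ax = fn(arg)
        ax.figure.savefig(out / name, dpi=110)
        plt.close(ax.figure)
        paths.append(out / name)
    if summary.zone_proportions:
        zp = {z: v for z, v in summary.zone_proportions.items()}
        ax = plot_zone_stack(zp)
        ax.figure.savefig(out / "zone_stack.png", dpi=110)
        plt.close(ax.figure)
        paths.append(out / "zone_stack.png")
    return paths
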
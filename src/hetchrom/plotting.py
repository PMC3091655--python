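"""Simple landscape and per-class median charts."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .features import WindowFeatureRecord, landscape, summarize_by_class

__all__ = ["plot_landscape", "plot_class_medians"]

_CLASS_COLORS = {
    "EU": "#808080",
    "PEU": "#bbbbbb",
    "PH": "#d62728",
    "IHc": "#1f77b4",
    "IHd": "#17becf",
}


def plot_landscape(
    records: Sequence[WindowFeatureRecord],
    feature: str,
    value: str = "coverage_pct",
    path: str | None = None,
):
    """Per-arm window landscape of one feature (midpoint vs value)."""
    df = landscape(records)
    df = df[df["feature"] == feature]
    arms = list(dict.fromkeys(df["arm"]))
    fig, axes = plt.subplots(len(arms), 1, figsize=(8, 1.8 * len(arms)), sharex=False)
    if len(arms) == 1:
        axes = [axes]
    for ax, arm in zip(axes, arms):
        sub = df[df["arm"] == arm]
        for cls, grp in sub.groupby("class"):
            ax.scatter(
                grp["midpoint"] / 1e6,
                grp[value],
                s=12,
                label=cls,
                color=_CLASS_COLORS.get(cls, "black"),
            )
        ax.set_ylabel(arm)
    axes[-1].set_xlabel("position (Mb)")
    axes[0].legend(fontsize=7, ncol=5)
    fig.suptitle(f"{feature}: {value}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_class_medians(
    records: Sequence[WindowFeatureRecord],
    value: str = "median_coverage_pct",
    path: str | None = None,
):
    """Grouped bars of per-class medians across features."""
    df = summarize_by_class(records)
    pivot = df.pivot(index="feature", columns="class", values=value)
    fig, ax = plt.subplots(figsize=(8, 4))
    pivot.plot.bar(
        ax=ax,
        color=[_CLASS_COLORS.get(c, "black") for c in pivot.columns],
    )
    ax.set_ylabel(value)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
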
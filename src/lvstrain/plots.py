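"""Report figures: Bland–Altman scatter plots and per-group boxplots."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .agreement import BlandAltmanResult
from .metrics import METRIC_NAMES

__all__ = ["bland_altman_plot", "metric_boxplots"]


def bland_altman_plot(
    result: BlandAltmanResult, title: str, path: Union[str, Path]
) -> None:
    """Scatter of pairwise (mean, difference) with bias and LoA lines."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.points["mean"], result.points["difference"], s=8, alpha=0.4)
    ax.axhline(result.bias, color="k", lw=1.2, label=f"bias {result.bias:+.2f} cm")
    for lim, name in ((result.loa_low, "LoA low"), (result.loa_high, "LoA high")):
        ax.axhline(lim, color="r", ls="--", lw=1.0, label=f"{name} {lim:+.2f} cm")
    ax.set_xlabel("mean of pair (cm)")
    ax.set_ylabel("difference (cm)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def metric_boxplots(
    metrics_df: pd.DataFrame,
    path: Union[str, Path],
    metric_names: Sequence[str] = METRIC_NAMES,
) -> None:
    """Per-metric boxplots of reader values by (software, repetition) group.

    Automated (duplicated) sessions appear as single marks next to the
    reader boxes.
    """
    manual = metrics_df[metrics_df["kind"] == "manual"]
    auto = metrics_df[metrics_df["kind"] == "automated"]
    groups = sorted(
        manual.groupby(["software", "repetition"]).groups.keys(),
        key=lambda g: (g[0], g[1]),
    )
    ncols = 2
    nrows = (len(metric_names) + 1) // 2
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.5 * ncols, 2.8 * nrows))
    for ax, metric in zip(axes.ravel(), metric_names):
        data = [
            manual[(manual["software"] == sw) & (manual["repetition"] == rep)][metric]
            for sw, rep in groups
        ]
        ax.boxplot(data, tick_labels=[f"{sw}\nT{rep}" for sw, rep in groups])
        if not auto.empty:
            ax.scatter(
                [len(groups) + 0.5] * len(auto),
                auto[metric],
                marker="D",
                color="tab:orange",
                label="automated",
            )
            ax.set_xlim(0.5, len(groups) + 1.0)
        ax.set_title(metric, fontsize=10)
    for ax in axes.ravel()[len(metric_names):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
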
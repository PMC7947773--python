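"""Quick-look figures for pipeline outputs (matplotlib, non-interactive)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_rate_by_haplogroup(rates, path):
    """Box plot of the relative Y somatic mutation rate R per haplogroup."""
    valid = rates[rates["valid"] & (rates["haplogroup"] != "OUT")]
    haps = sorted(valid["haplogroup"].unique())
    data = [valid.loc[valid["haplogroup"] == h, "R"] for h in haps]
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(haps)), 3.5))
    ax.boxplot(data, tick_labels=haps)
    ax.set_ylabel("relative Y somatic rate R")
    ax.set_xlabel("haplogroup")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_timing_profile(profile, path, max_samples: int = 30):
    """Per-sample profiles (grey) with the consensus overlaid (red)."""
    fig, ax = plt.subplots(figsize=(8, 3))
    x = profile.windows["start"] / 1e6
    for row in profile.values[:max_samples]:
        ax.plot(x, row, color="0.8", lw=0.5)
    if profile.consensus is not None:
        ax.plot(x, profile.consensus, color="crimson", lw=1.5, label="consensus")
        ax.legend(frameon=False)
    ax.set_xlabel("Y position (Mb)")
    ax.set_ylabel("timing (std.; higher = earlier)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_timing_bins(trend, path):
    """Per-bin mean mutation count vs mean timing, with the linear trend."""
    import numpy as np

    fig, ax = plt.subplots(figsize=(4, 3.5))
    b = trend.bins
    ax.scatter(b["mean_timing"], b["mean_mutations"], s=18)
    coef = np.polyfit(b["mean_timing"], b["mean_mutations"], 1)
    xs = np.linspace(b["mean_timing"].min(), b["mean_timing"].max(), 10)
    ax.plot(xs, np.polyval(coef, xs), color="crimson")
    ax.set_xlabel("mean replication timing (earlier →)")
    ax.set_ylabel("mean mutations per window")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
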
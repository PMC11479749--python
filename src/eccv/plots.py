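"""Cohort characterization figures (written as files, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from eccv.characterize import CohortStats, KS_MAX_LEN, PEAK_MAX_LEN


def plot_length_density(stats: CohortStats, lengths_by_group, outpath: Path) -> Path:
    from scipy.stats import gaussian_kde

    fig, ax = plt.subplots(figsize=(6, 4))
    for group, lengths in lengths_by_group.items():
        sub = np.asarray(lengths, float)
        sub = sub[sub < PEAK_MAX_LEN]
        if len(sub) > 10 and np.ptp(sub) > 0:
            grid = np.arange(0, PEAK_MAX_LEN)
            ax.plot(grid, gaussian_kde(sub, bw_method="silverman")(grid), label=group)
    ax.set_xlabel("circle length (bp)")
    ax.set_ylabel("density")
    ax.legend()
    fig.savefig(outpath, dpi=100)
    plt.close(fig)
    return outpath


def plot_length_ecdf(lengths_by_group, outpath: Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    for group, lengths in lengths_by_group.items():
        sub = np.sort(np.asarray(lengths, float))
        sub = sub[sub < KS_MAX_LEN]
        if len(sub):
            ax.step(sub, np.arange(1, len(sub) + 1) / len(sub), where="post", label=group)
    ax.set_xlabel("circle length (bp)")
    ax.set_ylabel("cumulative frequency")
    ax.legend()
    fig.savefig(outpath, dpi=100)
    plt.close(fig)
    return outpath


def plot_chrom_density(stats: CohortStats, outpath: Path) -> Path:
    df = stats.chrom_density
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(df["chrom"], df["pct"])
    ax.axhline(df["mean_pct"].iloc[0], ls="--", color="k", label="mean")
    ax.set_ylabel("% of circles per Mb")
    ax.legend()
    fig.savefig(outpath, dpi=100)
    plt.close(fig)
    return outpath
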
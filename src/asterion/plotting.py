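"""Figure helpers: enrichment null histograms, correlation densities and
intron-length distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_enrichment(result, path: str) -> None:
    """Null-count histogram with the observed count as a vertical line."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(result.null_counts, bins=30, color="0.7", label="resampled null")
    ax.axvline(result.observed, color="crimson", lw=2, label="observed")
    ax.set_xlabel("transcripts with protein evidence")
    ax.set_ylabel("resamples")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlations(comparison, path: str) -> None:
    """Overlaid histograms of pair vs random-pair Spearman rhos."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    bins = np.linspace(-1, 1, 41)
    ax.hist(
        comparison.null_rhos, bins=bins, density=True, color="0.7",
        label="random pairs",
    )
    ax.hist(
        comparison.pair_rhos, bins=bins, density=True, histtype="step",
        color="navy", lw=2, label="antisense pairs",
    )
    ax.set_xlabel("Spearman rho")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_intron_lengths(table, path: str) -> None:
    """Host vs non-host largest-intron distributions (log scale)."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    host = table.loc[table["is_host"] & (table["largest_intron"] > 0), "largest_intron"]
    non = table.loc[~table["is_host"] & (table["largest_intron"] > 0), "largest_intron"]
    bins = np.logspace(1, 5, 40)
    ax.hist(non, bins=bins, density=True, color="0.7", label="non-host genes")
    ax.hist(host, bins=bins, density=True, histtype="step", color="darkgreen",
            lw=2, label="host genes")
    ax.set_xscale("log")
    ax.set_xlabel("largest intron per gene (bp)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
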
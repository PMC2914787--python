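"""Small diagnostic plots for runs and sweeps (not publication figures)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .analysis import RunRecord, SweepSummary

__all__ = ["plot_run", "plot_sweep"]


def plot_run(record: RunRecord, path=None):
    """Population, cluster count and diversity vs. generation for one run."""
    s = record.series
    fig, axes = plt.subplots(3, 1, figsize=(7, 8), sharex=True)
    axes[0].plot(s["generation"], s["population"])
    axes[0].set_ylabel("population")
    axes[1].plot(s["generation"], s["n_clusters"])
    axes[1].set_ylabel("clusters")
    axes[2].plot(s["generation"], s["diversity"])
    axes[2].set_ylabel("diversity")
    axes[2].set_xlabel("generation")
    fig.suptitle(
        f"mu={record.mu} kernel={record.kernel} landscape={record.landscape_mode}"
    )
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_sweep(summary: SweepSummary, path=None):
    """Order parameters vs. mu with across-replicate error bars."""
    t = summary.table
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    panels = [
        ("mean_population", "sd_population", "population"),
        ("mean_clusters", "sd_clusters", "clusters"),
        ("mean_diversity", "sd_diversity", "diversity"),
        ("mean_corr", "sd_corr", "pop-cluster corr."),
    ]
    for ax, (m, s, label) in zip(axes.ravel(), panels):
        ax.errorbar(t["mu"], t[m], yerr=t[s], fmt="o-", capsize=2)
        ax.set_ylabel(label)
    for ax in axes[1]:
        ax.set_xlabel("mu")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
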
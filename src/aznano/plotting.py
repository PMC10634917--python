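"""Matplotlib summaries of pipeline results: population enrichment curves and
the separation-index histogram with its overlap / no-overlap split."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_enrichment_curves", "plot_separation_histogram", "plot_autocorrelation"]


def plot_enrichment_curves(curves: dict, ax=None):
    """Mean +/- SEM of the smoothed per-nanocluster enrichment curves.

    ``curves`` is ``PipelineResult.enrichment_curves``: direction ->
    {"bin_edges_nm", "curves"} with one row per nanocluster.
    """
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    for direction, entry in curves.items():
        edges = np.asarray(entry["bin_edges_nm"])
        mat = np.asarray(entry["curves"])
        centers = 0.5 * (edges[:-1] + edges[1:])
        mean = np.nanmean(mat, axis=0)
        sem = np.nanstd(mat, axis=0) / np.sqrt(max(len(mat), 1))
        ax.plot(centers, mean, label=direction)
        ax.fill_between(centers, mean - sem, mean + sem, alpha=0.3)
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("distance from nanocluster center (nm)")
    ax.set_ylabel("normalized enrichment")
    ax.legend(frameon=False)
    return ax


def plot_separation_histogram(separation, target: str | None = None, ax=None, bins=20):
    """Histogram of separation indices, split at SI = 1 (overlap vs none)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    df = separation if target is None else separation[separation["target"] == target]
    si = df["si"].to_numpy(float)
    edges = np.linspace(0, max(2.5, np.nanmax(si) if len(si) else 2.5), bins + 1)
    ax.hist(si[si < 1], bins=edges, color="tab:red", alpha=0.7, label="overlap (SI < 1)")
    ax.hist(si[si >= 1], bins=edges, color="tab:gray", alpha=0.7, label="no overlap (SI > 1)")
    ax.axvline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("separation index")
    ax.set_ylabel("nanoclusters")
    ax.legend(frameon=False)
    return ax


def plot_autocorrelation(curve, ax=None, **kwargs):
    """One within-synapse pair-autocorrelation curve g(r)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    centers = 0.5 * (curve.bin_edges_nm[:-1] + curve.bin_edges_nm[1:])
    ax.plot(centers, curve.g, **kwargs)
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("r (nm)")
    ax.set_ylabel("g(r)")
    return ax
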
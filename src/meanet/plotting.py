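"""Figure builders: rastergrams, activity heatmaps, connectivity maps, PSTHs."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe default

import matplotlib.pyplot as plt
import numpy as np

from .types import PSTH, ConnectivityGraph, SpikeTrainSet, N_ROWS, N_COLS


def raster_plot(trains: SpikeTrainSet, ax=None):
    """Rastergram: one row per electrode, a tick per spike."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))
    for e, ts in enumerate(trains.spikes):
        if ts.size:
            ax.vlines(ts, e + 0.6, e + 1.4, color="k", lw=0.4)
    ax.set_xlim(0, trains.duration)
    ax.set_ylim(0.5, trains.n_electrodes + 0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("electrode")
    ax.set_title(f"well {trains.well}")
    return ax


def rate_heatmap(trains: SpikeTrainSet, ax=None):
    """8x8 firing-rate heatmap (Hz) over the electrode grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    rates = trains.rates().reshape(N_ROWS, N_COLS)
    im = ax.imshow(rates, cmap="magma", origin="upper")
    ax.set_xticks(range(N_COLS), [str(c + 1) for c in range(N_COLS)])
    ax.set_yticks(range(N_ROWS), [str(r + 1) for r in range(N_ROWS)])
    plt.colorbar(im, ax=ax, label="firing rate (Hz)")
    ax.set_title(f"well {trains.well}")
    return ax


def connectivity_map(graph: ConnectivityGraph, ax=None):
    """Functional-connectivity map drawn on the electrode grid."""
    if graph.adj is None:
        raise ValueError("graph has no adjacency; run threshold_graph first")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pos = graph.positions
    ii, jj = np.where(np.triu(graph.adj, 1))
    for i, j in zip(ii, jj):
        ax.plot(
            [pos[i, 1], pos[j, 1]],
            [pos[i, 0], pos[j, 0]],
            color="tab:blue",
            alpha=0.3,
            lw=0.6,
        )
    degree = graph.adj.sum(axis=1)
    ax.scatter(pos[:, 1], pos[:, 0], s=10 + 8 * degree, c=degree, cmap="viridis", zorder=3)
    ax.set_xlim(0.5, N_COLS + 0.5)
    ax.set_ylim(N_ROWS + 0.5, 0.5)
    ax.set_aspect("equal")
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    return ax


def psth_plot(psth: PSTH, ax=None):
    """PSTH with percentile envelope; onset marked at t = 0."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = psth.centers * 1e3
    ax.fill_between(t, psth.lower, psth.upper, alpha=0.3, label="envelope")
    ax.plot(t, psth.mean_rate, color="k", label="mean")
    ax.axvline(0.0, color="r", ls="--", lw=0.8)
    ax.set_xlabel("time from stimulus (ms)")
    ax.set_ylabel("network rate (Hz)")
    ax.legend(frameon=False)
    return ax
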
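"""Evoked-response analysis: event-aligned rasters, PSTHs, response duration.

Stimulation events are cut out of the spike record, spikes inside a short
post-onset blank window (default 2 ms, the electrical artifact) are removed,
and the network peri-stimulus time histogram (PSTH) is built from per-event
binned network rates with an across-event percentile envelope (default
5th/95th).  The network response duration is the time from onset until the
rate falls back to the pre-stimulus baseline (mean + 2 SD rule with a 3-bin
persistence requirement).
"""
from __future__ import annotations

import numpy as np

from .types import PSTH, EvokedRasters, SpikeTrainSet, StimulationLog

DEFAULT_WINDOW = 0.5  # s post-onset
DEFAULT_WINDOW_PRE = 0.1  # s pre-onset
DEFAULT_BLANK = 0.002  # s artifact blank
DEFAULT_BIN = 0.005  # s PSTH bin
DEFAULT_PERCENTILES = (5.0, 95.0)


def extract_evoked(
    trains: SpikeTrainSet,
    log: StimulationLog,
    window: float = DEFAULT_WINDOW,
    window_pre: float = DEFAULT_WINDOW_PRE,
    blank: float = DEFAULT_BLANK,
) -> EvokedRasters:
    """Cut stimulus-aligned network rasters out of a recording.

    For each event all spikes with ``t - onset`` in [-window_pre, window] are
    pooled over electrodes and re-referenced to the onset; spikes in the
    artifact window [0, blank] are removed.  When an event's window would
    overlap the next onset it is truncated there.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if window_pre < 0 or blank < 0:
        raise ValueError("window_pre and blank must be non-negative")
    all_spikes = (
        np.sort(np.concatenate([ts for ts in trains.spikes]))
        if trains.total_spikes()
        else np.empty(0)
    )
    onsets = log.onsets
    events: list[np.ndarray] = []
    for i, onset in enumerate(onsets):
        hi = onset + window
        if i + 1 < onsets.size:
            hi = min(hi, onsets[i + 1])
        seg = all_spikes[(all_spikes >= onset - window_pre) & (all_spikes <= hi)] - onset
        seg = seg[(seg < 0.0) | (seg > blank)]
        events.append(seg)
    return EvokedRasters(events=events, window_pre=window_pre, window=window, blank=blank)


def compute_psth(
    rasters: EvokedRasters,
    bin_width: float = DEFAULT_BIN,
    percentiles: tuple[float, float] = DEFAULT_PERCENTILES,
) -> PSTH:
    """Network PSTH: across-event mean rate per bin with percentile envelope.

    Each event's spike counts per ``bin_width`` bin are converted to a network
    rate (Hz); the PSTH reports the mean and the low/high across-event
    percentiles per bin, spanning [-window_pre, window].
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    low, high = percentiles
    if not 0 <= low < high <= 100:
        raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
    n_pre = int(np.ceil(rasters.window_pre / bin_width))
    n_post = int(np.ceil(rasters.window / bin_width))
    edges = np.arange(-n_pre, n_post + 1) * bin_width
    if rasters.n_events == 0:
        z = np.zeros(edges.size - 1)
        return PSTH(edges=edges, mean_rate=z, lower=z.copy(), upper=z.copy(), n_events=0)
    rates = np.empty((rasters.n_events, edges.size - 1))
    for i, ev in enumerate(rasters.events):
        counts, _ = np.histogram(ev, bins=edges)
        rates[i] = counts / bin_width
    return PSTH(
        edges=edges,
        mean_rate=rates.mean(axis=0),
        lower=np.percentile(rates, low, axis=0),
        upper=np.percentile(rates, high, axis=0),
        n_events=rasters.n_events,
    )


def response_duration(psth: PSTH, baseline_window: float | None = None) -> float:
    """Network response duration (s) from a PSTH with pre-onset bins.

    The baseline cutoff is mean + 2 SD of the pre-onset bin rates (over
    ``baseline_window`` seconds before onset; default: all pre-onset bins).
    The duration runs from onset to the start of the first post-peak bin at or
    below the cutoff that opens a run of at least 3 consecutive sub-baseline
    bins.  Returns 0 when no post-onset bin ever exceeds the cutoff, and the
    end of the PSTH window when the rate never returns within it.
    """
    centers = psth.centers
    pre = centers < 0
    if baseline_window is not None:
        pre &= centers >= -baseline_window
    if not pre.any():
        raise ValueError("PSTH lacks pre-onset bins covering the baseline window")
    base = psth.mean_rate[pre]
    cutoff = base.mean() + 2.0 * base.std()

    post = np.flatnonzero(centers >= 0)
    post_rates = psth.mean_rate[post]
    if not (post_rates > cutoff).any():
        return 0.0
    peak = int(np.argmax(post_rates))
    sub = post_rates <= cutoff
    for j in range(peak + 1, post_rates.size - 2):
        if sub[j] and sub[j + 1] and sub[j + 2]:
            return float(psth.edges[post[j]])
    return float(psth.edges[-1])
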
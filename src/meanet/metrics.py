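"""First-order network activity statistics.

Covers the standard multiwell-MEA descriptors of a 10-minute recording:
number of active electrodes, mean firing rate (MFR), single-electrode burst
detection with the max-interval method, mean bursting rate (MBR), inter-spike
intervals (ISI) and network bursts.

Conventions
-----------
* An electrode is *active* when it fires at least ``min_rate`` spikes per
  minute (default 5/min, the common multiwell-MEA criterion).
* MFR and MBR are network-wide means over **all 64 electrodes** by default;
  an explicit electrode mask restricts the denominator when a per-active
  figure is wanted.  The network-wide convention is what the developmental
  presets are calibrated against: a sparse immature well with a handful of
  firing electrodes has a low network MFR even though each firing electrode
  individually exceeds the activity criterion.
* ISI statistics are pooled over active electrodes only, so sparse noise on
  silent channels does not dominate the mean interval.
"""
from __future__ import annotations

import numpy as np

from .types import ActivitySummary, Burst, BurstSet, NetworkBurst, SpikeTrainSet

DEFAULT_MIN_RATE = 5.0  # spikes/min for the active-electrode criterion
DEFAULT_MAX_ISI = 0.1  # s, max-interval burst criterion
DEFAULT_MIN_SPIKES = 5  # spikes per burst
DEFAULT_NET_FRACTION = 0.25  # fraction of active electrodes for a network burst
DEFAULT_NET_BIN = 0.025  # s


def active_electrodes(
    trains: SpikeTrainSet, min_rate: float = DEFAULT_MIN_RATE
) -> tuple[int, np.ndarray]:
    """Count electrodes firing at least ``min_rate`` spikes per minute.

    Returns ``(count, mask)`` with a boolean mask over the 64 electrodes.
    """
    if min_rate < 0:
        raise ValueError("min_rate must be non-negative")
    rates_per_min = trains.counts() / trains.duration * 60.0
    mask = rates_per_min >= min_rate
    return int(mask.sum()), mask


def mean_firing_rate(trains: SpikeTrainSet, mask: np.ndarray | None = None) -> float:
    """Mean firing rate (Hz) over the masked electrodes (default: all 64).

    Returns 0 for an empty mask.
    """
    rates = trains.rates()
    if mask is not None:
        rates = rates[np.asarray(mask, dtype=bool)]
    if rates.size == 0:
        return 0.0
    return float(rates.mean())


def detect_bursts(
    train: np.ndarray,
    max_isi: float = DEFAULT_MAX_ISI,
    min_spikes: int = DEFAULT_MIN_SPIKES,
) -> list[Burst]:
    """Max-interval burst detection on one electrode's spike train.

    A burst is a maximal run of consecutive spikes whose inter-spike intervals
    are all ``<= max_isi`` and whose length is ``>= min_spikes``; it is
    reported as (first spike, last spike, spike count).
    """
    if max_isi <= 0:
        raise ValueError("max_isi must be positive")
    if min_spikes < 2:
        raise ValueError("min_spikes must be at least 2")
    train = np.asarray(train, dtype=float)
    if train.size and np.any(np.diff(train) < 0):
        raise ValueError("spike train must be sorted ascending")
    if train.size < min_spikes:
        return []
    short = np.diff(train) <= max_isi
    bursts: list[Burst] = []
    run_start = 0
    for i in range(short.size + 1):
        if i == short.size or not short[i]:
            run_len = i - run_start + 1  # spikes in the run ending at spike i
            if run_len >= min_spikes:
                bursts.append(
                    Burst(start=float(train[run_start]), end=float(train[i]), n_spikes=run_len)
                )
            run_start = i + 1
    return bursts


def detect_bursts_set(
    trains: SpikeTrainSet,
    max_isi: float = DEFAULT_MAX_ISI,
    min_spikes: int = DEFAULT_MIN_SPIKES,
) -> BurstSet:
    """Burst detection over every electrode of a well."""
    return BurstSet(bursts=[detect_bursts(ts, max_isi, min_spikes) for ts in trains.spikes])


def mean_burst_rate(
    bursts: BurstSet, duration: float, mask: np.ndarray | None = None
) -> float:
    """Mean bursting rate (bursts/min) over the masked electrodes (default all).

    Returns 0 for an empty mask.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    counts = bursts.counts().astype(float)
    if mask is not None:
        counts = counts[np.asarray(mask, dtype=bool)]
    if counts.size == 0:
        return 0.0
    return float(counts.mean() / duration * 60.0)


def isi_stats(
    trains: SpikeTrainSet, mask: np.ndarray | None = None
) -> tuple[list[np.ndarray], float]:
    """Per-electrode inter-spike intervals and their pooled mean (s).

    Electrodes outside the mask or with fewer than two spikes contribute
    nothing; the pooled mean is NaN when no ISI exists.
    """
    if mask is None:
        mask = np.ones(trains.n_electrodes, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    isis = [
        np.diff(ts) if (mask[e] and ts.size >= 2) else np.empty(0)
        for e, ts in enumerate(trains.spikes)
    ]
    pooled = np.concatenate(isis) if isis else np.empty(0)
    mean = float(pooled.mean()) if pooled.size else float("nan")
    return isis, mean


def detect_network_bursts(
    bursts: BurstSet,
    duration: float,
    n_active: int | None = None,
    min_fraction: float = DEFAULT_NET_FRACTION,
    bin_width: float = DEFAULT_NET_BIN,
) -> list[NetworkBurst]:
    """Detect epochs in which many electrodes burst simultaneously.

    The recording is discretized into ``bin_width`` bins; a bin belongs to a
    network burst when at least ``min_fraction`` of the ``n_active``
    electrodes are inside a single-electrode burst during it.  Adjacent
    suprathreshold bins merge into one network burst, reported with the number
    of distinct participating electrodes.  ``n_active`` defaults to the number
    of electrodes with at least one burst.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n_active is None:
        n_active = int((bursts.counts() > 0).sum())
    if n_active == 0:
        return []

    n_bins = int(np.ceil(duration / bin_width))
    counts = np.zeros(n_bins, dtype=int)
    members: list[set[int]] = [set() for _ in range(n_bins)]
    for e, blist in enumerate(bursts.bursts):
        for b in blist:
            lo = int(b.start / bin_width)
            hi = min(n_bins - 1, int(b.end / bin_width))
            for i in range(lo, hi + 1):
                if e not in members[i]:
                    members[i].add(e)
                    counts[i] += 1

    need = min_fraction * n_active
    hot = counts >= need
    out: list[NetworkBurst] = []
    i = 0
    while i < n_bins:
        if hot[i]:
            j = i
            electrodes: set[int] = set()
            while j < n_bins and hot[j]:
                electrodes |= members[j]
                j += 1
            out.append(
                NetworkBurst(
                    start=i * bin_width,
                    end=min(j * bin_width, duration),
                    n_electrodes=len(electrodes),
                )
            )
            i = j
        else:
            i += 1
    return out


def summarize_activity(
    trains: SpikeTrainSet,
    min_rate: float = DEFAULT_MIN_RATE,
    max_isi: float = DEFAULT_MAX_ISI,
    min_spikes: int = DEFAULT_MIN_SPIKES,
    net_fraction: float = DEFAULT_NET_FRACTION,
    net_bin: float = DEFAULT_NET_BIN,
) -> ActivitySummary:
    """Full first-order summary of one recording (network-wide conventions)."""
    n_active, mask = active_electrodes(trains, min_rate)
    bursts = detect_bursts_set(trains, max_isi, min_spikes)
    net = detect_network_bursts(
        bursts, trains.duration, n_active=n_active or None, min_fraction=net_fraction, bin_width=net_bin
    )
    _, isi_mean = isi_stats(trains, mask)
    return ActivitySummary(
        n_active=n_active,
        active_mask=mask,
        mfr=mean_firing_rate(trains),
        mbr=mean_burst_rate(bursts, trains.duration),
        isi_mean=isi_mean,
        n_network_bursts=len(net),
        network_burst_rate=len(net) / trains.duration * 60.0,
    )
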
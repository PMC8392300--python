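"""Adaptive threshold-crossing spike detection.

Spikes are extracted from raw extracellular traces by thresholding at a
multiple (default 6) of a robust, locally estimated noise standard deviation.
Adaptivity is realized as non-overlapping estimation windows (default 10 s);
within each window the noise SD is the median absolute deviation scaled to be
consistent for Gaussian noise, ``median(|x - median(x)|) / 0.6745``, which is
insensitive to the spikes themselves.  Both polarities are detected (the
waveforms are biphasic) and each suprathreshold excursion is timestamped at
its extremum.
"""
from __future__ import annotations

import numpy as np

from .types import RawTraceSet, SpikeTrainSet, N_ELECTRODES

MAD_SCALE = 0.6745  # Phi^-1(0.75): MAD -> SD for Gaussian noise


def estimate_noise_sd(trace: np.ndarray, fs: float, window: float = 10.0) -> np.ndarray:
    """Robust per-window noise SD of a single-electrode trace.

    Returns one MAD-based SD estimate per non-overlapping window of ``window``
    seconds (the final, possibly partial window included), so the sequence has
    ``ceil(duration / window)`` entries.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if window <= 0:
        raise ValueError("window must be positive")
    win_len = max(1, int(round(window * fs)))
    n_win = int(np.ceil(trace.size / win_len))
    sds = np.empty(n_win)
    for i in range(n_win):
        seg = trace[i * win_len : (i + 1) * win_len]
        med = np.median(seg)
        sds[i] = np.median(np.abs(seg - med)) / MAD_SCALE
    return sds


def detect_spikes(
    trace: np.ndarray,
    fs: float,
    mult: float = 6.0,
    dead_time: float = 0.001,
    window: float = 10.0,
) -> np.ndarray:
    """Detect spike times (s) on one electrode by adaptive threshold crossing.

    A spike is the extremum time of each excursion beyond ``±mult`` times the
    local noise SD; crossings within ``dead_time`` of an accepted spike are
    discarded, which also collapses the two phases of a biphasic waveform into
    a single event.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if mult <= 0:
        raise ValueError("threshold multiplier must be positive")
    if dead_time < 0:
        raise ValueError("dead_time must be non-negative")
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        return np.empty(0)

    sds = estimate_noise_sd(trace, fs, window)
    win_len = max(1, int(round(window * fs)))
    thr = np.repeat(sds * mult, win_len)[: trace.size]

    above = np.abs(trace) > thr
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return np.empty(0)
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    times = []
    for run in np.split(idx, splits):
        ext = run[np.argmax(np.abs(trace[run]))]
        times.append(ext / fs)

    out = []
    last = -np.inf
    for t in times:
        if t - last >= dead_time:
            out.append(t)
            last = t
    return np.asarray(out)


def detect_spiketrains(
    traces: RawTraceSet,
    mult: float = 6.0,
    dead_time: float = 0.001,
    window: float = 10.0,
    well: str | None = None,
) -> SpikeTrainSet:
    """Run spike detection on every channel of a trace set."""
    spikes: list[np.ndarray] = [np.empty(0) for _ in range(N_ELECTRODES)]
    for ch, e in enumerate(traces.electrodes):
        spikes[int(e)] = detect_spikes(traces.samples[ch], traces.fs, mult, dead_time, window)
    return SpikeTrainSet(spikes=spikes, duration=traces.duration, well=well or traces.well)
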
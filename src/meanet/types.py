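"""Core data containers for multiwell-MEA recordings.

The analysis operates on one well of an 8x8 microelectrode array.  Electrodes
are addressed either by 1-based (row, col) grid coordinates, matching the
column layout of exported spike lists, or by a flat index in row-major order
(``index = (row - 1) * 8 + (col - 1)``).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

N_ROWS = 8
N_COLS = 8
N_ELECTRODES = N_ROWS * N_COLS


def electrode_index(row: int, col: int) -> int:
    """Flat electrode index from 1-based grid coordinates."""
    if not (1 <= row <= N_ROWS and 1 <= col <= N_COLS):
        raise ValueError(f"electrode ({row}, {col}) outside the {N_ROWS}x{N_COLS} grid")
    return (row - 1) * N_COLS + (col - 1)


def electrode_rowcol(index: int) -> tuple[int, int]:
    """1-based (row, col) grid coordinates from a flat electrode index."""
    if not (0 <= index < N_ELECTRODES):
        raise ValueError(f"electrode index {index} outside [0, {N_ELECTRODES})")
    return index // N_COLS + 1, index % N_COLS + 1


def electrode_positions() -> np.ndarray:
    """(64, 2) array of (row, col) grid positions, 1-based, row-major order."""
    rows, cols = np.divmod(np.arange(N_ELECTRODES), N_COLS)
    return np.column_stack([rows + 1, cols + 1])


@dataclass
class SpikeTrainSet:
    """Per-electrode spike timestamps for one well.

    Parameters
    ----------
    spikes
        Sequence of 64 sorted timestamp arrays (seconds), one per electrode in
        row-major grid order.  Electrodes without spikes hold empty arrays.
    duration
        Recording duration in seconds.  All timestamps lie in [0, duration].
    well
        Well label (e.g. ``"A1"``).
    """

    spikes: list[np.ndarray]
    duration: float
    well: str = "A1"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if len(self.spikes) != N_ELECTRODES:
            raise ValueError(f"expected {N_ELECTRODES} electrode trains, got {len(self.spikes)}")
        clean = []
        for i, ts in enumerate(self.spikes):
            ts = np.asarray(ts, dtype=float)
            if ts.ndim != 1:
                raise ValueError(f"electrode {i}: timestamps must be one-dimensional")
            if ts.size and np.any(np.diff(ts) < 0):
                raise ValueError(f"electrode {i}: timestamps must be sorted ascending")
            if ts.size and (ts[0] < 0 or ts[-1] > self.duration):
                raise ValueError(f"electrode {i}: timestamps outside [0, {self.duration}]")
            clean.append(ts)
        self.spikes = clean

    @property
    def n_electrodes(self) -> int:
        return len(self.spikes)

    def counts(self) -> np.ndarray:
        """Spike count per electrode."""
        return np.array([ts.size for ts in self.spikes])

    def rates(self) -> np.ndarray:
        """Firing rate per electrode (Hz)."""
        return self.counts() / self.duration

    def total_spikes(self) -> int:
        return int(self.counts().sum())


@dataclass
class RawTraceSet:
    """Multichannel extracellular voltage traces at a fixed sampling rate.

    ``samples`` is (n_channels, n_samples) in microvolts; ``electrodes`` maps
    each channel to a flat electrode index.  ``ground_truth`` optionally holds
    per-channel inserted spike times (seconds) when the trace is synthetic.
    """

    samples: np.ndarray
    fs: float
    electrodes: np.ndarray
    well: str = "A1"
    ground_truth: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.electrodes = np.asarray(self.electrodes, dtype=int)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[0] != self.electrodes.size:
            raise ValueError("one electrode id per channel required")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass(frozen=True)
class Burst:
    """A run of closely spaced spikes on one electrode."""

    start: float
    end: float
    n_spikes: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("burst end before start")
        if self.n_spikes < 2:
            raise ValueError("a burst contains at least two spikes")


@dataclass(frozen=True)
class NetworkBurst:
    """An epoch in which many electrodes burst simultaneously."""

    start: float
    end: float
    n_electrodes: int


@dataclass
class BurstSet:
    """Per-electrode burst intervals plus detected network bursts."""

    bursts: list[list[Burst]]
    network_bursts: list[NetworkBurst] = field(default_factory=list)

    def counts(self) -> np.ndarray:
        """Burst count per electrode."""
        return np.array([len(b) for b in self.bursts])


@dataclass
class ActivitySummary:
    """First-order network-wide activity statistics for one recording."""

    n_active: int
    active_mask: np.ndarray
    mfr: float
    mbr: float
    isi_mean: float
    n_network_bursts: int
    network_burst_rate: float


@dataclass
class ConnectivityGraph:
    """Electrode-level functional-connectivity graph.

    ``corr`` is the 64x64 Pearson correlation matrix of binned spike counts
    (diagonal 1, zero-variance convention r = 0); ``adj`` is the thresholded
    boolean adjacency once :func:`meanet.graph.threshold_graph` has run.
    """

    corr: np.ndarray
    adj: np.ndarray | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        n = self.corr.shape[0]
        if self.corr.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.corr, self.corr.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(self.corr < -1 - 1e-9) or np.any(self.corr > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.adj is not None:
            self.adj = np.asarray(self.adj, dtype=bool)
            if self.adj.shape != self.corr.shape:
                raise ValueError("adjacency shape mismatch")
            if np.any(np.diag(self.adj)):
                raise ValueError("self-loops are not allowed")
            if not np.array_equal(self.adj, self.adj.T):
                raise ValueError("adjacency must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.corr.shape[0]

    @property
    def positions(self) -> np.ndarray:
        return electrode_positions()[: self.n_nodes]


@dataclass
class TopologySummary:
    """Graph-topology metrics of a thresholded connectivity graph."""

    n_edges: int
    degree: np.ndarray
    clustering: np.ndarray
    hubs: list[int] = field(default_factory=list)

    @property
    def mean_degree(self) -> float:
        return float(np.mean(self.degree))


@dataclass(frozen=True)
class StimEvent:
    site: int
    onset: float


@dataclass
class StimulationLog:
    """Stimulation events (site, onset) plus pulse metadata.

    ``pulse`` records the biphasic pulse shape (phase width in µs, peak-to-peak
    amplitude in µA) as metadata only; no electrical simulation is attached.
    """

    events: list[StimEvent]
    stim_freq: float = 0.2
    pulse: tuple[float, float] = (500.0, 160.0)
    ground_truth: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulation onsets must be sorted")

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events])

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class EvokedRasters:
    """Stimulus-aligned network spike times, one pooled array per event.

    Times are relative to stimulation onset; spikes inside the artifact blank
    window [0, blank] have been removed.
    """

    events: list[np.ndarray]
    window_pre: float
    window: float
    blank: float

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class PSTH:
    """Peri-stimulus time histogram of network firing rate.

    ``edges`` are bin edges (s, relative to onset); ``mean_rate`` the across-
    event mean network rate per bin (Hz); ``lower``/``upper`` the across-event
    percentile envelope.
    """

    edges: np.ndarray
    mean_rate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_events: int
    site: int | None = None

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0
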
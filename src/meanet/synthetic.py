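"""Synthetic developing-network MEA recordings.

The generator emulates one well of an 8x8 electrode grid: 10-minute
spontaneous recordings across developmental stages (days after induction,
DAI) and low-frequency electrical stimulation with a fast evoked network
response.  Each stage is a :class:`DevPreset`; presets are calibrated so the
pipeline's *network-wide* statistics (mean over all 64 electrodes) reproduce
the developmental endpoints: ~5 active electrodes, MFR 0.06 Hz and MBR
0.17 burst/min at DAI8, rising to 64 active electrodes, 0.89 Hz and
1.13 burst/min at DAI21.

Spike model per active electrode (superposition):

* homogeneous Poisson background (``rate_active`` Hz);
* an independent Poisson *burst* process (``burst_rate``/min; each burst is
  ``burst_len`` spikes at ``intra_burst_isi`` spacing) — these bursts carry
  the mean bursting rate;
* *network bursts*: a global Poisson process (``netburst_rate``/min) whose
  events recruit each active electrode with probability ``participation``;
  recruited electrodes emit a simultaneous ``netburst_len``-spike burst;
* *synchronous volleys*: a second, faster global Poisson process
  (``sync_rate``/min) recruiting electrodes with probability
  ``sync_participation * w_e``, where ``w_e`` is a persistent per-electrode
  propensity (mean 1).  Volleys are ``sync_len`` = 2 spikes — below the burst
  criterion — so they shape the pairwise correlation structure (and, through
  ``w_e``, hubs) without inflating burst counts.

Inactive electrodes emit sparse Poisson noise so the active-electrode
criterion is non-degenerate.

A fixed seed instantiates a persistent virtual culture across stages: the
electrode permutation, the propensities ``w_e`` and the global event pools
are drawn from per-purpose random streams keyed by (seed, purpose,
electrode/event), and counts use inverse-CDF sampling.  Simulating two
stages with the same seed therefore yields nested active sets and coherently
coupled activity, the way one culture looks when recorded at two ages.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import (
    N_ELECTRODES,
    RawTraceSet,
    SpikeTrainSet,
    StimEvent,
    StimulationLog,
)

DEFAULT_FS = 12_500.0  # Hz, sampling rate of the raw acquisition

STAGE_LABELS = ("DAI5", "DAI8", "DAI14", "DAI17", "DAI21")

# stream purposes for the keyed RNG layout
_PERM, _PROPENSITY, _NET_COUNT, _NET_TIMES, _NET_RECRUIT = 0, 1, 2, 3, 4
_SYNC_COUNT, _SYNC_TIMES, _SYNC_RECRUIT, _BG, _BURST, _NOISE = 5, 6, 7, 8, 9, 10


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _poisson_count(u: float, mu: float) -> int:
    """Inverse-CDF Poisson draw; monotone in ``mu`` for a fixed uniform."""
    if mu <= 0:
        return 0
    return int(stats.poisson.ppf(u, mu))


@dataclass(frozen=True)
class DevPreset:
    """Generator parameters for one developmental stage.

    Rates are per active electrode except the global event rates
    ``netburst_rate``/``sync_rate`` (events per minute network-wide) and
    ``noise_rate`` (per inactive electrode).
    """

    label: str
    n_active: int
    rate_active: float  # Hz, Poisson background per active electrode
    burst_rate: float  # bursts/min per active electrode
    burst_len: int = 5  # spikes per burst
    intra_burst_isi: float = 0.005  # s
    netburst_rate: float = 0.0  # network-burst events/min
    participation: float = 0.0  # P(active electrode joins a network burst)
    netburst_len: int = 12  # spikes per network-burst response
    sync_rate: float = 0.0  # synchronous-volley events/min
    sync_participation: float = 0.0  # mean P(electrode joins a volley)
    sync_len: int = 2  # spikes per volley (< burst criterion)
    noise_rate: float = 0.02  # Hz on inactive electrodes

    def __post_init__(self) -> None:
        if not 0 <= self.n_active <= N_ELECTRODES:
            raise ValueError("n_active must lie in [0, 64]")
        for name in ("rate_active", "burst_rate", "netburst_rate", "sync_rate", "noise_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("participation", "sync_participation"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sync_participation > 0.5:
            # propensities span [0, 2], so the product must stay a probability
            raise ValueError("sync_participation must be <= 0.5")
        if min(self.burst_len, self.netburst_len, self.sync_len) < 0 or self.intra_burst_isi < 0:
            raise ValueError("burst shape parameters must be non-negative")

    @property
    def bursts_per_min(self) -> float:
        """Expected detected bursts per active electrode per minute."""
        return self.burst_rate + self.netburst_rate * self.participation

    @property
    def rate_per_active(self) -> float:
        """Expected total firing rate of one active electrode (Hz)."""
        burst_spikes = (
            self.burst_rate * self.burst_len
            + self.netburst_rate * self.participation * self.netburst_len
            + self.sync_rate * self.sync_participation * self.sync_len
        )
        return self.rate_active + burst_spikes / 60.0

    @property
    def expected_mfr(self) -> float:
        """Analytic network-wide mean firing rate (Hz, mean over 64 electrodes)."""
        n_in = N_ELECTRODES - self.n_active
        return (self.n_active * self.rate_per_active + n_in * self.noise_rate) / N_ELECTRODES

    @property
    def expected_mbr(self) -> float:
        """Analytic network-wide mean bursting rate (bursts/min over 64 electrodes)."""
        return self.n_active * self.bursts_per_min / N_ELECTRODES


# Stage endpoints.  DAI8/DAI21 are solved so expected_mfr / expected_mbr hit
# the reported endpoint statistics exactly; DAI5 is a sparser, slower stage
# below DAI8; DAI14/DAI17 interpolate linearly between the two endpoints.
_DAI8 = DevPreset(
    label="DAI8",
    n_active=5,
    rate_active=0.34865,
    burst_rate=2.173,
    netburst_rate=0.02,
    participation=0.15,
    sync_rate=0.5,
    sync_participation=0.1,
)
_DAI21 = DevPreset(
    label="DAI21",
    n_active=64,
    rate_active=0.485333,
    burst_rate=1.04,
    netburst_rate=0.3,
    participation=0.3,
    sync_rate=20.0,
    sync_participation=0.45,
)
_DAI5 = DevPreset(
    label="DAI5",
    n_active=2,
    rate_active=0.05,
    burst_rate=1.0,
    netburst_rate=0.01,
    participation=0.1,
    sync_rate=0.2,
    sync_participation=0.05,
)


def _interpolate(label: str, frac: float) -> DevPreset:
    def lerp(attr: str) -> float:
        a, b = getattr(_DAI8, attr), getattr(_DAI21, attr)
        return a + frac * (b - a)

    return DevPreset(
        label=label,
        n_active=int(round(lerp("n_active"))),
        rate_active=lerp("rate_active"),
        burst_rate=lerp("burst_rate"),
        netburst_rate=lerp("netburst_rate"),
        participation=lerp("participation"),
        sync_rate=lerp("sync_rate"),
        sync_participation=lerp("sync_participation"),
    )


PRESETS: dict[str, DevPreset] = {
    "DAI5": _DAI5,
    "DAI8": _DAI8,
    "DAI14": _interpolate("DAI14", (14 - 8) / (21 - 8)),
    "DAI17": _interpolate("DAI17", (17 - 8) / (21 - 8)),
    "DAI21": _DAI21,
}


def make_preset(stage_label: str) -> DevPreset:
    """Return the built-in developmental preset for ``stage_label``.

    Raises ``ValueError`` listing the valid stage labels for unknown stages.
    """
    try:
        return PRESETS[stage_label]
    except KeyError:
        raise ValueError(
            f"unknown stage {stage_label!r}; valid stages: {', '.join(STAGE_LABELS)}"
        ) from None


def electrode_propensity(seed: int) -> np.ndarray:
    """Persistent per-electrode synchrony propensity w_e (mean 1, range [0, 2])."""
    return 2.0 * _rng(seed, _PROPENSITY).beta(2.0, 2.0, N_ELECTRODES)


def _burst_spikes(
    onset: float, n: int, isi: float, jitter_sd: float, rng: np.random.Generator | None
) -> np.ndarray:
    t = onset + np.arange(n) * isi
    if jitter_sd > 0 and n > 1 and rng is not None:
        t[1:] += np.cumsum(rng.normal(0.0, jitter_sd, n - 1))
        t.sort()
    return t


def simulate_spiketrains(
    preset: DevPreset,
    duration: float = 600.0,
    seed: int | None = None,
    isi_jitter_sd: float = 0.0,
    well: str = "A1",
) -> SpikeTrainSet:
    """Simulate one well of spontaneous activity under a developmental preset.

    The first ``n_active`` electrodes of a seed-determined permutation carry
    background spiking, bursts, network bursts and synchronous volleys; the
    rest emit sparse noise.  Identical ``(preset, duration, seed)`` yields
    identical output, and different presets under the same seed describe the
    same virtual culture at different ages (nested active sets, coupled event
    pools).  ``isi_jitter_sd`` optionally jitters intra-burst intervals
    (default 0: regular bursts).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if seed is None:
        seed = int(np.random.default_rng().integers(2**31))
    T = duration

    perm = _rng(seed, _PERM).permutation(N_ELECTRODES)
    active = perm[: preset.n_active]
    active_set = set(int(a) for a in active)
    w = electrode_propensity(seed)
    jit = _rng(seed, 99) if isi_jitter_sd > 0 else None

    # Global event pools (prefixes shared across stages for a fixed seed).
    n_net = _poisson_count(_rng(seed, _NET_COUNT).random(), preset.netburst_rate / 60.0 * T)
    net_times = _rng(seed, _NET_TIMES).random(max(n_net, 1))[:n_net] * T
    net_recruit = [
        _rng(seed, _NET_RECRUIT, i).random(N_ELECTRODES) < preset.participation
        for i in range(n_net)
    ]
    n_sync = _poisson_count(_rng(seed, _SYNC_COUNT).random(), preset.sync_rate / 60.0 * T)
    sync_times = _rng(seed, _SYNC_TIMES).random(max(n_sync, 1))[:n_sync] * T
    sync_recruit = [
        _rng(seed, _SYNC_RECRUIT, i).random(N_ELECTRODES) < preset.sync_participation * w
        for i in range(n_sync)
    ]

    spikes: list[np.ndarray] = []
    for e in range(N_ELECTRODES):
        parts: list[np.ndarray] = []
        if e in active_set:
            rng_bg = _rng(seed, _BG, e)
            n_bg = _poisson_count(rng_bg.random(), preset.rate_active * T)
            parts.append(rng_bg.random(n_bg) * T)
            rng_b = _rng(seed, _BURST, e)
            n_b = _poisson_count(rng_b.random(), preset.burst_rate / 60.0 * T)
            for onset in rng_b.random(max(n_b, 1))[:n_b] * T:
                parts.append(
                    _burst_spikes(onset, preset.burst_len, preset.intra_burst_isi, isi_jitter_sd, jit)
                )
            for i in range(n_net):
                if net_recruit[i][e]:
                    parts.append(
                        _burst_spikes(
                            net_times[i], preset.netburst_len, preset.intra_burst_isi, isi_jitter_sd, jit
                        )
                    )
            for i in range(n_sync):
                if sync_recruit[i][e]:
                    parts.append(
                        _burst_spikes(
                            sync_times[i], preset.sync_len, preset.intra_burst_isi, isi_jitter_sd, jit
                        )
                    )
        else:
            rng_n = _rng(seed, _NOISE, e)
            n_noise = _poisson_count(rng_n.random(), preset.noise_rate * T)
            parts.append(rng_n.random(n_noise) * T)
        ts = np.concatenate(parts) if parts else np.empty(0)
        ts = np.sort(ts[(ts >= 0.0) & (ts < T)])
        spikes.append(ts)
    return SpikeTrainSet(spikes=spikes, duration=duration, well=well)


def biphasic_waveform(
    fs: float = DEFAULT_FS,
    amplitude: float = 60.0,
    neg_width: float = 4e-4,
    pos_width: float = 8e-4,
    pos_frac: float = 0.4,
) -> np.ndarray:
    """Stereotyped extracellular spike waveform (µV).

    A sharp negative trough (width ``neg_width`` s, peak ``-amplitude``)
    followed by a slower positive rebound (``pos_frac * amplitude``).  The
    global extremum is the trough, used as the alignment point.
    """
    n_neg = max(2, int(round(neg_width * fs)))
    n_pos = max(2, int(round(pos_width * fs)))
    neg = -amplitude * np.sin(np.pi * np.arange(n_neg) / n_neg)
    pos = pos_frac * amplitude * np.sin(np.pi * np.arange(n_pos) / n_pos)
    return np.concatenate([neg, pos])


def simulate_raw_trace(
    trains: SpikeTrainSet,
    noise_sd: float = 5.0,
    fs: float = DEFAULT_FS,
    amplitude: float = 60.0,
    waveform: np.ndarray | None = None,
    electrodes: np.ndarray | None = None,
    seed: int | None = None,
) -> RawTraceSet:
    """Render spike trains as raw voltage traces with additive Gaussian noise.

    A stereotyped biphasic waveform is inserted at each spike time (aligned on
    its extremum); the sample-quantized insertion times are retained as
    ``ground_truth`` for detector validation.  ``electrodes`` restricts the
    rendered channels (default: all 64).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if waveform is None:
        waveform = biphasic_waveform(fs=fs, amplitude=amplitude)
    waveform = np.asarray(waveform, dtype=float)
    align = int(np.argmax(np.abs(waveform)))
    if electrodes is None:
        electrodes = np.arange(N_ELECTRODES)
    electrodes = np.asarray(electrodes, dtype=int)

    rng = np.random.default_rng(seed)
    n_samples = int(round(trains.duration * fs))
    samples = (
        rng.normal(0.0, noise_sd, (electrodes.size, n_samples))
        if noise_sd > 0
        else np.zeros((electrodes.size, n_samples))
    )
    ground_truth: list[np.ndarray] = []
    for ch, e in enumerate(electrodes):
        inserted = []
        for t in trains.spikes[e]:
            center = int(round(t * fs))
            if center >= n_samples:
                raise ValueError(f"spike at {t} s beyond trace duration")
            start = center - align
            w0 = max(0, -start)
            w1 = min(waveform.size, n_samples - start)
            samples[ch, start + w0 : start + w1] += waveform[w0:w1]
            inserted.append(center / fs)
        ground_truth.append(np.asarray(inserted))
    return RawTraceSet(
        samples=samples, fs=fs, electrodes=electrodes, well=trains.well, ground_truth=ground_truth
    )


@dataclass(frozen=True)
class StimModel:
    """Stimulation protocol and evoked-response kernel.

    ``stim_freq`` is the pulse-train frequency (Hz).  After each onset plus
    ``latency`` every active electrode's rate is transiently raised by
    ``response_peak * exp(-t / response_tau)``; spikes within
    ``artifact_blank`` of the onset are suppressed.  ``phase_width`` (µs) and
    ``amplitude`` (µA) describe the biphasic current pulse as metadata only.
    """

    stim_freq: float = 0.2
    response_peak: float = 50.0  # Hz added per active electrode at the kernel peak
    response_tau: float = 0.015  # s
    latency: float = 0.005  # s
    artifact_blank: float = 0.002  # s
    phase_width: float = 500.0  # µs
    amplitude: float = 160.0  # µA peak-to-peak

    def __post_init__(self) -> None:
        if self.response_tau <= 0:
            raise ValueError("response_tau must be positive")
        if self.artifact_blank < 0:
            raise ValueError("artifact_blank must be non-negative")
        if self.stim_freq <= 0:
            raise ValueError("stim_freq must be positive")


def simulate_evoked(
    baseline: DevPreset,
    stim: StimModel | None = None,
    n_stim: int = 60,
    seed: int | None = None,
    n_sites: int = 8,
    start: float = 2.0,
) -> tuple[SpikeTrainSet, StimulationLog]:
    """Simulate a stimulation session over spontaneous baseline activity.

    ``n_stim`` onsets are spaced ``1/stim_freq`` apart, delivered in a random
    sequence over ``n_sites`` stimulation electrodes.  Evoked spikes follow
    the exponential response kernel on every active electrode; all spikes
    (baseline and evoked) within the artifact blank window are removed.  The
    per-event evoked spike times are retained on the log as ``ground_truth``.
    """
    if n_stim < 1:
        raise ValueError("n_stim must be at least 1")
    stim = stim or StimModel()
    if seed is None:
        seed = int(np.random.default_rng().integers(2**31))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1000]))
    period = 1.0 / stim.stim_freq
    onsets = start + period * np.arange(n_stim)
    duration = float(onsets[-1] + period)

    base = simulate_spiketrains(baseline, duration=duration, seed=seed)
    perm = _rng(seed, _PERM).permutation(N_ELECTRODES)
    active = perm[: baseline.n_active]
    if active.size == 0:
        active = np.arange(N_ELECTRODES)
    sites = rng.choice(N_ELECTRODES, size=min(n_sites, N_ELECTRODES), replace=False)
    site_seq = rng.choice(sites, size=n_stim, replace=True)

    mean_evoked = stim.response_peak * stim.response_tau  # per electrode per event
    extra: list[list[float]] = [[] for _ in range(N_ELECTRODES)]
    ground_truth: list[np.ndarray] = []
    for onset in onsets:
        event_spikes: list[float] = []
        for e in active:
            n_ev = rng.poisson(mean_evoked)
            if n_ev:
                lags = stim.latency + rng.exponential(stim.response_tau, n_ev)
                for t in onset + lags:
                    if t < duration:
                        extra[int(e)].append(t)
                        event_spikes.append(t - onset)
        ground_truth.append(np.sort(np.asarray(event_spikes)))

    spikes = []
    for e in range(N_ELECTRODES):
        ts = np.concatenate([base.spikes[e], np.asarray(extra[e])]) if extra[e] else base.spikes[e]
        # Suppress the stimulation artifact window after every onset.
        for onset in onsets:
            ts = ts[(ts < onset) | (ts > onset + stim.artifact_blank)]
        spikes.append(np.sort(ts))
    trains = SpikeTrainSet(spikes=spikes, duration=duration, well=base.well)
    events = [StimEvent(site=int(s), onset=float(t)) for s, t in zip(site_seq, onsets)]
    log = StimulationLog(
        events=events,
        stim_freq=stim.stim_freq,
        pulse=(stim.phase_width, stim.amplitude),
        ground_truth=ground_truth,
    )
    return trains, log
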
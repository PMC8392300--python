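"""Readers and writers for the pipeline's file dialects.

Spike lists are CSV in the shape of multiwell acquisition exports, header
``well,electrode_row,electrode_col,time_s`` with 1-based grid coordinates and
timestamps in seconds.  Stimulation logs are CSV ``site,onset_s``.  Raw traces
travel as HDF5 containers (channels x samples with an ``fs`` attribute).
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .types import (
    N_COLS,
    N_ELECTRODES,
    N_ROWS,
    RawTraceSet,
    SpikeTrainSet,
    StimEvent,
    StimulationLog,
    electrode_index,
    electrode_rowcol,
)

SPIKE_COLUMNS = ["well", "electrode_row", "electrode_col", "time_s"]
STIM_COLUMNS = ["site", "onset_s"]


def read_spike_csv(
    path: str | Path, well: str | None = None, duration: float | None = None
) -> SpikeTrainSet:
    """Read one well's spike list from CSV.

    The file must carry the exact header ``well,electrode_row,electrode_col,
    time_s``.  With multiple wells present, ``well`` selects one.  ``duration``
    defaults to the latest timestamp in the file.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != SPIKE_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(SPIKE_COLUMNS)}, got {','.join(df.columns)}"
        )
    for col in ("electrode_row", "electrode_col", "time_s"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: malformed {col!r} value on line {bad[0] + 2}")
    wells = df["well"].astype(str).unique().tolist()
    if well is None:
        if len(wells) > 1:
            raise ValueError(f"{path}: multiple wells {wells}; pass well=")
        well = wells[0] if wells else "A1"
    else:
        df = df[df["well"].astype(str) == str(well)]

    rows = df["electrode_row"].astype(int).to_numpy()
    cols = df["electrode_col"].astype(int).to_numpy()
    out_of_grid = (rows < 1) | (rows > N_ROWS) | (cols < 1) | (cols > N_COLS)
    if out_of_grid.any():
        line = df.index[out_of_grid][0] + 2
        raise ValueError(f"{path}: electrode outside the {N_ROWS}x{N_COLS} grid on line {line}")
    times = df["time_s"].astype(float).to_numpy()
    if duration is None:
        duration = float(times.max()) if times.size else 1.0
    spikes: list[np.ndarray] = [np.empty(0) for _ in range(N_ELECTRODES)]
    idx = (rows - 1) * N_COLS + (cols - 1)
    for e in np.unique(idx):
        spikes[int(e)] = np.sort(times[idx == e])
    return SpikeTrainSet(spikes=spikes, duration=duration, well=str(well))


def write_spike_csv(trains: SpikeTrainSet, path: str | Path) -> None:
    """Write a spike list CSV (rows sorted by time, then electrode)."""
    records = []
    for e, ts in enumerate(trains.spikes):
        row, col = electrode_rowcol(e)
        for t in ts:
            records.append((trains.well, row, col, t))
    df = pd.DataFrame(records, columns=SPIKE_COLUMNS)
    if len(df):
        df = df.sort_values(["time_s", "electrode_row", "electrode_col"], kind="stable")
    df.to_csv(path, index=False, float_format="%.6f")


def read_stim_csv(path: str | Path, stim_freq: float = 0.2) -> StimulationLog:
    """Read a stimulation log CSV with header ``site,onset_s``."""
    df = pd.read_csv(path)
    if list(df.columns) != STIM_COLUMNS:
        raise ValueError(f"{path}: expected header {','.join(STIM_COLUMNS)}")
    df = df.sort_values("onset_s", kind="stable")
    events = [StimEvent(site=int(s), onset=float(t)) for s, t in zip(df["site"], df["onset_s"])]
    return StimulationLog(events=events, stim_freq=stim_freq)


def write_stim_csv(log: StimulationLog, path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.site, e.onset) for e in log.events], columns=STIM_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.6f")


def write_trace_h5(traces: RawTraceSet, path: str | Path) -> None:
    """Write a raw trace container (datasets ``samples``/``electrodes``,
    attribute ``fs``; synthetic ground-truth spike times kept under ``gt/``)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=traces.samples)
        f.create_dataset("electrodes", data=traces.electrodes)
        f.attrs["fs"] = traces.fs
        f.attrs["well"] = traces.well
        if traces.ground_truth is not None:
            grp = f.create_group("gt")
            for ch, ts in enumerate(traces.ground_truth):
                grp.create_dataset(str(ch), data=np.asarray(ts))


def read_trace_h5(path: str | Path) -> RawTraceSet:
    with h5py.File(path, "r") as f:
        gt = None
        if "gt" in f:
            grp = f["gt"]
            gt = [np.asarray(grp[str(ch)]) for ch in range(len(grp))]
        return RawTraceSet(
            samples=np.asarray(f["samples"]),
            fs=float(f.attrs["fs"]),
            electrodes=np.asarray(f["electrodes"]),
            well=str(f.attrs.get("well", "A1")),
            ground_truth=gt,
        )


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run.

    Every tunable of every stage has its module default here, so a serialized
    config reproduces a run exactly given the same seed.
    """

    # inputs: either a preset to simulate or a spike CSV to load
    preset: str | None = "DAI21"
    duration: float = 600.0
    seed: int = 0
    spikes_path: str | None = None
    stim_path: str | None = None
    outdir: str = "meanet_out"
    well: str = "A1"
    # detection
    threshold_mult: float = 6.0
    noise_window: float = 10.0
    dead_time: float = 0.001
    # activity metrics
    min_rate: float = 5.0
    max_isi: float = 0.1
    min_spikes: int = 5
    net_fraction: float = 0.25
    net_bin: float = 0.025
    # connectivity
    corr_bin: float = 0.025
    corr_threshold: float = 0.3
    n_null: int = 100
    # evoked response
    psth_bin: float = 0.005
    psth_window: float = 0.5
    psth_window_pre: float = 0.1
    blank: float = 0.002
    percentiles: tuple[float, float] = (5.0, 95.0)
    # reporting
    figures: bool = True

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["percentiles"] = list(self.percentiles)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "percentiles" in data:
            data["percentiles"] = tuple(data["percentiles"])
        return cls(**data)
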
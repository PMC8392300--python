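"""End-to-end pipeline: simulate or load spikes, then metrics, connectivity
and (when a stimulation log is present) evoked-response analysis, with a
machine-readable JSON summary and optional figures."""
from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib.pyplot as plt
import numpy as np

from . import evoked as ev
from . import graph as gr
from . import io as mio
from . import metrics as mx
from . import plotting
from .synthetic import make_preset, simulate_spiketrains
from .types import SpikeTrainSet

log = logging.getLogger("meanet")


def _round(x: float, nd: int = 6) -> float:
    return float(np.round(float(x), nd))


def run_pipeline(config: mio.RunConfig) -> dict:
    """Execute the configured stages and write ``summary.json`` to the outdir.

    Returns the summary dictionary.  Identical configs (including seed)
    produce byte-identical summaries.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.spikes_path:
        trains = mio.read_spike_csv(config.spikes_path, duration=config.duration)
        source = {"spikes_path": config.spikes_path}
    elif config.preset:
        preset = make_preset(config.preset)
        trains = simulate_spiketrains(
            preset, duration=config.duration, seed=config.seed, well=config.well
        )
        mio.write_spike_csv(trains, outdir / "spikes.csv")
        source = {"preset": config.preset, "seed": config.seed}
    else:
        raise ValueError("config needs either spikes_path or preset")
    log.info("input: %s (%d spikes)", source, trains.total_spikes())

    summary: dict = {
        "parameters": {k: v for k, v in vars(config).items()},
        "source": source,
        "duration_s": trains.duration,
    }

    act = mx.summarize_activity(
        trains,
        min_rate=config.min_rate,
        max_isi=config.max_isi,
        min_spikes=config.min_spikes,
        net_fraction=config.net_fraction,
        net_bin=config.net_bin,
    )
    summary["activity"] = {
        "n_active": act.n_active,
        "mfr_hz": _round(act.mfr),
        "mbr_per_min": _round(act.mbr),
        "isi_mean_s": _round(act.isi_mean) if np.isfinite(act.isi_mean) else None,
        "n_network_bursts": act.n_network_bursts,
        "network_burst_rate_per_min": _round(act.network_burst_rate),
    }

    g, topo = gr.connectivity_pipeline(
        trains,
        bin_width=config.corr_bin,
        threshold=config.corr_threshold,
        active_mask=act.active_mask,
    )
    rc = gr.rich_club(g, n_null=config.n_null, seed=config.seed)
    summary["graph"] = {
        "n_edges": topo.n_edges,
        "mean_degree": _round(topo.mean_degree),
        "mean_clustering": _round(float(topo.clustering.mean())),
        "hubs": topo.hubs,
        "rich_club": {str(k): _round(v.phi_norm) for k, v in rc.items() if np.isfinite(v.phi_norm)},
    }

    psth = None
    if config.stim_path:
        stim_log = mio.read_stim_csv(config.stim_path)
        rasters = ev.extract_evoked(
            trains,
            stim_log,
            window=config.psth_window,
            window_pre=config.psth_window_pre,
            blank=config.blank,
        )
        psth = ev.compute_psth(rasters, bin_width=config.psth_bin, percentiles=config.percentiles)
        summary["evoked"] = {
            "n_events": psth.n_events,
            "peak_rate_hz": _round(float(psth.mean_rate.max())),
            "response_duration_ms": _round(ev.response_duration(psth) * 1e3),
        }
    else:
        log.info("no stimulation log configured; PSTH stage skipped")
        summary["evoked"] = None

    if config.figures:
        figdir = outdir / "figures"
        figdir.mkdir(exist_ok=True)
        for name, fn, arg in [
            ("raster", plotting.raster_plot, trains),
            ("rate_heatmap", plotting.rate_heatmap, trains),
            ("connectivity_map", plotting.connectivity_map, g),
        ] + ([("psth", plotting.psth_plot, psth)] if psth is not None else []):
            ax = fn(arg)
            ax.figure.savefig(figdir / f"{name}.png", dpi=120)
            plt.close(ax.figure)

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
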
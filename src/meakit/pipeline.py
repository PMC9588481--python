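"""The full single-file analysis pipeline, shared by the CLI and tests.

Stages per file: high-pass filter -> baseline-noise estimation -> spike
detection -> artifact rejection -> activity flags -> single-channel bursts
(both methods) -> network bursts per well -> connectivity -> synchrony ->
optional spike sorting -> per-well endpoints.  Timestamp-only inputs skip
the voltage-dependent stages.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from meakit import bursts as _bursts
from meakit import connectivity as _conn
from meakit import endpoints as _endpoints
from meakit import network_bursts as _nb
from meakit import sorting as _sorting
from meakit import spike_detect as _sd
from meakit import synchrony as _sync
from meakit.containers import Recording, SpikeTrainSet
from meakit.io_formats import (
    read_recording_hdf5,
    read_spike_csv,
    write_spike_csv,
    write_table,
)
from meakit.layouts import get_layout


@dataclass
class FileResult:
    """Everything the pipeline computed for one input file."""

    source: str
    tset: SpikeTrainSet
    noise: dict[str, _sd.NoiseEstimate] = field(default_factory=dict)
    bursts_mi: dict[str, list[_bursts.Burst]] = field(default_factory=dict)
    bursts_li: dict[str, list[_bursts.Burst]] = field(default_factory=dict)
    nbs_per_well: dict[str, list[_nb.NetworkBurst]] = field(default_factory=dict)
    endpoints: dict[str, dict[str, float]] = field(default_factory=dict)
    channel_table: pd.DataFrame | None = None
    connectivity: dict[str, _conn.ConnectivityMatrix] = field(default_factory=dict)
    synchrony: dict[str, tuple[list[str], np.ndarray]] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def detect_all_spikes(
    rec: Recording, cfg: dict[str, Any], log: list[str]
) -> tuple[SpikeTrainSet, dict[str, _sd.NoiseEstimate]]:
    sd_cfg = cfg["spike_detection"]
    params = _sd.SpikeDetectParams(**sd_cfg)
    tset = SpikeTrainSet(layout=rec.layout, duration=rec.duration)
    noises: dict[str, _sd.NoiseEstimate] = {}
    for ch, trace in rec.traces.items():
        filtered = _sd.highpass(
            trace, rec.sample_rate, params.filter_cutoff_hz, params.filter_order
        )
        noise = _sd.estimate_noise(filtered, rec.sample_rate, params)
        noises[ch] = noise
        if not noise.usable:
            log.append(f"channel {ch}: no pure-noise stretch found, excluded as too noisy")
            continue
        train = _sd.detect_spikes(filtered, rec.sample_rate, noise, params, channel_id=ch)
        n_raw = train.n_spikes
        train = _sd.reject_artifacts(train)
        log.append(
            f"channel {ch}: threshold {noise.threshold:.2f} uV, "
            f"{n_raw} candidates, {train.n_spikes} after artifact rejection"
        )
        tset.trains[ch] = train
    return tset, noises


def analyze_tset(
    tset: SpikeTrainSet,
    cfg: dict[str, Any],
    noises: dict[str, _sd.NoiseEstimate] | None = None,
    source: str = "",
) -> FileResult:
    """Run every post-spike stage on a (flagged) spike-train set."""
    log: list[str] = []
    res = FileResult(source=source, tset=tset, noise=noises or {}, log=log)
    _sd.flag_active(tset, cfg["spike_detection"]["min_rate_hz"])
    active = tset.active_channels()
    log.append(f"{len(active)} active channels of {len(tset.trains)} with spikes")

    mi_params = _bursts.MaxIntervalParams(**cfg["burst"]["max_interval"])
    li_params = _bursts.LogISIParams(**cfg["burst"]["logisi"])
    for ch in active:
        res.bursts_mi[ch] = _bursts.detect_max_interval(tset.trains[ch], mi_params)
        res.bursts_li[ch] = _bursts.detect_logisi(tset.trains[ch], li_params)

    nb_cfg = dict(cfg["network_burst"])
    scb_method = nb_cfg.pop("scb_method", "max_interval")
    nb_params = _nb.NetworkBurstParams(**nb_cfg)
    scbs_all = res.bursts_mi if scb_method == "max_interval" else res.bursts_li

    layout = tset.layout
    for w, well in enumerate(layout.well_names):
        chans = [c for c in layout.channels_of_well(w) if c in active]
        scbs = {c: scbs_all[c] for c in chans}
        res.nbs_per_well[well] = _nb.detect_network_bursts(scbs, len(chans), nb_params)

    if cfg["connectivity"]["enabled"]:
        for w, well in enumerate(layout.well_names):
            chans = [c for c in layout.channels_of_well(w) if c in active]
            if len(chans) < 2:
                continue
            sub = SpikeTrainSet(
                layout=layout,
                duration=tset.duration,
                trains={c: tset.trains[c] for c in chans},
                active_flags={c: True for c in chans},
            )
            res.connectivity[well] = _conn.connectivity_pipeline(
                sub,
                chunk_spikes=cfg["connectivity"]["chunk_spikes"],
                bin_s=cfg["connectivity"]["bin_s"],
                max_lag_s=cfg["connectivity"]["max_lag_s"],
                snr_factor=cfg["connectivity"]["snr_factor"],
            )

    if cfg["synchrony"]["enabled"]:
        for w, well in enumerate(layout.well_names):
            chans = [c for c in layout.channels_of_well(w) if c in active]
            eligible = {c: tset.trains[c] for c in chans if tset.trains[c].n_spikes >= 2}
            if len(eligible) >= 2:
                res.synchrony[well] = _sync.isi_distance_matrix(
                    eligible, grid_step_s=cfg["synchrony"]["grid_step_s"]
                )

    ch_rows = []
    for ch in active:
        m = _endpoints.channel_metrics(
            tset.trains[ch],
            res.bursts_mi[ch],
            res.bursts_li[ch],
            (noises or {}).get(ch),
            tset.duration,
        )
        ch_rows.append(vars(m))
    res.channel_table = pd.DataFrame(ch_rows)

    for w, well in enumerate(layout.well_names):
        chans = layout.channels_of_well(w)
        res.endpoints[well] = _endpoints.well_endpoints(
            trains={c: tset.trains[c] for c in chans if c in tset.trains},
            active={c: tset.active_flags.get(c, False) for c in chans},
            bursts_mi={c: res.bursts_mi.get(c, []) for c in chans},
            nbs=res.nbs_per_well[well],
            duration=tset.duration,
        )
    return res


def analyze_file(path: str, cfg: dict[str, Any], layout_name: str | None = None) -> FileResult:
    """Analyze one input file (HDF5 voltage traces or timestamp CSV)."""
    log: list[str] = [f"input: {path}"]
    if str(path).endswith((".h5", ".hdf5")):
        rec = read_recording_hdf5(path)
        remove = set(cfg["general"]["remove_channels"])
        if remove:
            rec.traces = {c: t for c, t in rec.traces.items() if c not in remove}
            log.append(f"removed channels per config: {sorted(remove)}")
        tset, noises = detect_all_spikes(rec, cfg, log)
    else:
        layout = get_layout(layout_name or "multiwell-24x12")
        tset = read_spike_csv(path, layout)
        remove = set(cfg["general"]["remove_channels"])
        if remove:
            tset.trains = {c: t for c, t in tset.trains.items() if c not in remove}
        noises = {}
        log.append("timestamp-only input: voltage-dependent stages skipped")
    res = analyze_tset(tset, cfg, noises, source=str(path))
    res.log = log + res.log
    return res


def burst_count_table(res: FileResult) -> pd.DataFrame:
    rows = [
        {
            "channel": ch,
            "n_scb_maxint": len(res.bursts_mi.get(ch, [])),
            "n_scb_logisi": len(res.bursts_li.get(ch, [])),
        }
        for ch in res.tset.active_channels()
    ]
    return pd.DataFrame(rows, columns=["channel", "n_scb_maxint", "n_scb_logisi"])


def write_outputs(res: FileResult, out_dir: str | os.PathLike, stem: str) -> None:
    """Write per-file intermediate CSVs plus the spike-train cache."""
    out = Path(out_dir)
    (out / "cache").mkdir(parents=True, exist_ok=True)
    write_spike_csv(res.tset, out / "cache" / f"{stem}.spikes.csv")
    meta = {
        "layout": res.tset.layout.name,
        "duration_s": res.tset.duration,
        "source": res.source,
        "thresholds_uv": {
            ch: ne.threshold for ch, ne in res.noise.items() if ne.usable
        },
    }
    (out / "cache" / f"{stem}.meta.json").write_text(json.dumps(meta, indent=1))
    if res.channel_table is not None:
        write_table(res.channel_table, out / f"{stem}.channel_metrics.csv")
    write_table(burst_count_table(res), out / f"{stem}.burst_counts.csv")
    nb_rows = []
    for well, nbs in res.nbs_per_well.items():
        table, _ = _nb.network_burst_stats(nbs, res.tset.duration)
        if len(table):
            table.insert(0, "well", well)
            nb_rows.append(table)
    if nb_rows:
        write_table(pd.concat(nb_rows, ignore_index=True), out / f"{stem}.network_bursts.csv")
    for well, mat in res.connectivity.items():
        edges = mat.top_connections(k=10**9)
        df = pd.DataFrame(edges, columns=["source", "target", "strength_M", "latency_s"])
        write_table(df, out / f"{stem}.{well}.connectivity_edges.csv")
    for well, (chans, m) in res.synchrony.items():
        df = pd.DataFrame(m, index=chans, columns=chans)
        df.insert(0, "channel", chans)
        write_table(df, out / f"{stem}.{well}.isi_distance.csv")
    (out / f"{stem}.log").write_text("\n".join(res.log) + "\n")
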
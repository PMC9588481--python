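"""Per-channel "general data" metrics and the 20 per-well neuro endpoints.

The endpoint table summarizes each well with 20 metrics spanning spike-train,
single-channel-burst (SCB, max-interval detected) and network categories.
Channel-level quantities are averaged over the active electrodes of the
well; a well with no active channel reports all endpoints missing.  Wells
can be grouped, with mean/SEM or median/interquartile summaries per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from meakit.bursts import Burst, BurstStats, burst_stats
from meakit.containers import SpikeTrain
from meakit.network_bursts import NetworkBurst, network_burst_stats
from meakit.spike_detect import NoiseEstimate

ENDPOINT_COLUMNS = [
    "n_active_channels",
    "mean_fire_rate_hz",
    "median_fire_rate_hz",
    "mean_isi_s",
    "mean_cv_isi",
    "mean_cv2_isi",
    "scb_rate_per_min",
    "mean_scb_duration_s",
    "mean_spikes_per_scb",
    "pct_spikes_in_scbs",
    "mean_intra_scb_isi_s",
    "mean_scb_ibi_s",
    "scb_ibi_cv",
    "pct_bursting_channels",
    "nb_rate_per_min",
    "mean_nb_duration_s",
    "mean_nb_ibi_s",
    "nb_cv_ibi",
    "mean_nb_channel_participation",
    "pct_spikes_in_nbs",
]


@dataclass
class ChannelMetrics:
    channel_id: str
    spike_count: int
    mean_isi_s: float
    median_isi_s: float
    std_isi_s: float
    n_scb_maxint: int
    n_scb_logisi: int
    fire_rate_hz: float
    mean_instantaneous_rate_hz: float
    mean_cv_isi: float
    mean_cv2_isi: float
    threshold_uv: float


def cv2_of_isis(isis: np.ndarray) -> float:
    """Mean CV2: 2|ISI_{k+1} - ISI_k| / (ISI_{k+1} + ISI_k), averaged."""
    if len(isis) < 2:
        return float("nan")
    a, b = isis[:-1], isis[1:]
    return float(np.mean(2.0 * np.abs(b - a) / (b + a)))


def channel_metrics(
    train: SpikeTrain,
    bursts_mi: list[Burst],
    bursts_li: list[Burst],
    noise: NoiseEstimate | None,
    duration: float,
) -> ChannelMetrics:
    """All per-channel spike-train metrics; ISI fields are NaN below 2 spikes."""
    isis = train.isis()
    nan = float("nan")
    have_isi = len(isis) >= 1
    mean_isi = float(np.mean(isis)) if have_isi else nan
    return ChannelMetrics(
        channel_id=train.channel_id,
        spike_count=train.n_spikes,
        mean_isi_s=mean_isi,
        median_isi_s=float(np.median(isis)) if have_isi else nan,
        std_isi_s=float(np.std(isis)) if have_isi else nan,
        n_scb_maxint=len(bursts_mi),
        n_scb_logisi=len(bursts_li),
        fire_rate_hz=train.rate(duration),
        mean_instantaneous_rate_hz=float(np.mean(1.0 / isis)) if have_isi else nan,
        mean_cv_isi=float(np.std(isis) / np.mean(isis))
        if have_isi and np.mean(isis) > 0
        else nan,
        mean_cv2_isi=cv2_of_isis(isis),
        threshold_uv=noise.threshold if noise is not None else nan,
    )


def _nanmean(values: list[float]) -> float:
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(arr.mean()) if arr.size else float("nan")


def _scb_ibis(bursts: list[Burst]) -> np.ndarray:
    if len(bursts) < 2:
        return np.empty(0)
    return np.array(
        [bursts[k + 1].start_s - bursts[k].end_s for k in range(len(bursts) - 1)]
    )


def well_endpoints(
    trains: dict[str, SpikeTrain],
    active: dict[str, bool],
    bursts_mi: dict[str, list[Burst]],
    nbs: list[NetworkBurst],
    duration: float,
) -> dict[str, float]:
    """One row of the 20 neuro endpoints for a well.

    ``trains``/``bursts_mi`` cover the well's channels; averages run over
    active channels only.  Burst endpoints use the max-interval SCBs.
    """
    act = [ch for ch, ok in active.items() if ok and ch in trains]
    row = {c: float("nan") for c in ENDPOINT_COLUMNS}
    row["n_active_channels"] = float(len(act))
    if not act:
        return row

    rates = [trains[ch].rate(duration) for ch in act]
    row["mean_fire_rate_hz"] = float(np.mean(rates))
    row["median_fire_rate_hz"] = float(np.median(rates))

    mean_isis, cvs, cv2s = [], [], []
    for ch in act:
        isis = trains[ch].isis()
        if len(isis):
            mean_isis.append(float(np.mean(isis)))
            if np.mean(isis) > 0:
                cvs.append(float(np.std(isis) / np.mean(isis)))
        cv2s.append(cv2_of_isis(isis))
    row["mean_isi_s"] = _nanmean(mean_isis)
    row["mean_cv_isi"] = _nanmean(cvs)
    row["mean_cv2_isi"] = _nanmean(cv2s)

    per_ch_stats: list[BurstStats] = [
        burst_stats(bursts_mi.get(ch, []), trains[ch], duration) for ch in act
    ]
    row["scb_rate_per_min"] = _nanmean([s.burst_rate_per_min for s in per_ch_stats])
    row["mean_scb_duration_s"] = _nanmean([s.mean_duration_s for s in per_ch_stats])
    row["mean_spikes_per_scb"] = _nanmean([s.mean_spikes_per_burst for s in per_ch_stats])
    row["pct_spikes_in_scbs"] = _nanmean([s.pct_spikes_in_bursts for s in per_ch_stats])
    row["mean_intra_scb_isi_s"] = _nanmean([s.mean_intra_burst_isi_s for s in per_ch_stats])

    ibi_means, ibi_cvs = [], []
    for ch in act:
        ibis = _scb_ibis(bursts_mi.get(ch, []))
        if ibis.size:
            ibi_means.append(float(np.mean(ibis)))
            if np.mean(ibis) > 0:
                ibi_cvs.append(float(np.std(ibis) / np.mean(ibis)))
    row["mean_scb_ibi_s"] = _nanmean(ibi_means)
    row["scb_ibi_cv"] = _nanmean(ibi_cvs)
    row["pct_bursting_channels"] = (
        100.0 * sum(1 for ch in act if bursts_mi.get(ch)) / len(act)
    )

    _, nb_summary = network_burst_stats(nbs, duration)
    row["nb_rate_per_min"] = nb_summary["nb_rate_per_min"]
    row["mean_nb_duration_s"] = nb_summary["mean_duration_s"]
    row["mean_nb_ibi_s"] = nb_summary["mean_ibi_s"]
    row["nb_cv_ibi"] = nb_summary["cv_ibi"]
    row["mean_nb_channel_participation"] = (
        _nanmean([float(nb.n_channels) for nb in nbs]) if nbs else float("nan")
    )

    total_spikes = sum(trains[ch].n_spikes for ch in act)
    in_nb = 0
    for ch in act:
        t = trains[ch].times
        for nb in nbs:
            in_nb += int(np.sum((t >= nb.start_s) & (t <= nb.end_s)))
    row["pct_spikes_in_nbs"] = 100.0 * in_nb / total_spikes if total_spikes else 0.0
    return row


def endpoint_table(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Assemble per-well endpoint rows (keyed by well label) into a table."""
    df = pd.DataFrame.from_dict(rows, orient="index", columns=ENDPOINT_COLUMNS)
    df.index.name = "well"
    return df.reset_index()


def group_wells(
    table: pd.DataFrame,
    groups: dict[str, list[str]],
    mode: str = "mean",
) -> pd.DataFrame:
    """Append per-group summary rows to a per-well endpoint table.

    ``mode='mean'`` appends mean and SEM (sample SD / sqrt(n)) rows;
    ``mode='median'`` appends median and 25%/75% quartile rows (linear
    interpolation).  Group names are embedded in the row labels.  A group
    referencing an unknown well raises.
    """
    if mode not in ("mean", "median"):
        raise ValueError("mode must be 'mean' or 'median'")
    known = set(table["well"])
    out = table.copy()
    extra_rows = []
    for gname, wells in groups.items():
        missing = [w for w in wells if w not in known]
        if missing:
            raise ValueError(f"group {gname!r} references unknown wells {missing}")
        sub = table[table["well"].isin(wells)][ENDPOINT_COLUMNS]
        if mode == "mean":
            center = sub.mean()
            n = len(sub)
            spread = sub.std(ddof=1) / np.sqrt(n) if n > 1 else pd.Series(
                np.nan, index=ENDPOINT_COLUMNS
            )
            labels = (f"group:{gname}:mean", f"group:{gname}:sem")
        else:
            center = sub.median()
            q25 = sub.quantile(0.25, interpolation="linear")
            q75 = sub.quantile(0.75, interpolation="linear")
            labels = (f"group:{gname}:median", f"group:{gname}:q25", f"group:{gname}:q75")
            spread = None
        r1 = dict(center)
        r1["well"] = labels[0]
        extra_rows.append(r1)
        if mode == "mean":
            r2 = dict(spread)
            r2["well"] = labels[1]
            extra_rows.append(r2)
        else:
            r2 = dict(q25)
            r2["well"] = labels[1]
            r3 = dict(q75)
            r3["well"] = labels[2]
            extra_rows.extend([r2, r3])
    if extra_rows:
        out = pd.concat([out, pd.DataFrame(extra_rows)], ignore_index=True)
    return out[["well", *ENDPOINT_COLUMNS]]
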
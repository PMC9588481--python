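"""Array-wide network-burst detection from per-channel bursts.

A network burst is a set of near-simultaneous single-channel bursts (SCBs):
(1) SCBs whose first-spike times fall within a synchronization window of
each other on at least two distinct channels seed a synchronized burst;
(2) its span runs from the earliest to the latest member spike;
(3) any SCB whose first spike falls inside the span is absorbed, re-expanding
the span until a fixpoint; (4) candidates in which fewer than a minimum
percentage of the active channels participate are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from meakit.bursts import Burst
from meakit.containers import SpikeTrain


@dataclass
class NetworkBurstParams:
    sync_window_s: float = 0.1
    min_sync_burst_count: int = 2
    min_participation_pct: float = 25.0
    absorb_to_fixpoint: bool = True

    def __post_init__(self) -> None:
        if self.sync_window_s <= 0 or self.min_sync_burst_count <= 0:
            raise ValueError("window and burst count must be positive")
        if not 0 < self.min_participation_pct <= 100:
            raise ValueError("participation must be in (0, 100]")


@dataclass
class NetworkBurst:
    start_s: float
    end_s: float
    member_bursts: list[tuple[str, int]] = field(default_factory=list)
    n_channels: int = 0
    participation_pct: float = 0.0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def detect_network_bursts(
    scbs: dict[str, list[Burst]],
    active_channels: int,
    p: NetworkBurstParams | None = None,
) -> list[NetworkBurst]:
    """Detect network bursts from per-channel SCB lists.

    ``scbs`` maps channel id -> its burst list (only active channels should
    be passed); ``active_channels`` is the denominator for participation.
    Step-1 grouping sorts all first-spike times and takes maximal runs where
    consecutive first spikes differ by at most the synchronization window;
    a run qualifies when it spans at least ``min_sync_burst_count`` distinct
    channels.  Overlapping survivors are merged and participation re-checked
    jointly.  A channel counts once toward participation however many of its
    SCBs are members.
    """
    p = p or NetworkBurstParams()
    entries = []  # (first_spike, channel, burst_index, burst)
    for ch, blist in scbs.items():
        for bi, b in enumerate(blist):
            entries.append((b.start_s, ch, bi, b))
    if not entries:
        return []
    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    firsts = np.array([e[0] for e in entries])

    # step 1: maximal runs of consecutive first-spikes within the window
    groups: list[list[int]] = []
    start = 0
    for k in range(1, len(entries) + 1):
        if k == len(entries) or firsts[k] - firsts[k - 1] > p.sync_window_s:
            groups.append(list(range(start, k)))
            start = k
    candidates = []
    for g in groups:
        chans = {entries[i][1] for i in g}
        if len(chans) >= max(p.min_sync_burst_count, 2):
            candidates.append(set(g))

    # steps 2-3: span from member spikes, absorb SCBs starting inside it
    results: list[NetworkBurst] = []
    for members in candidates:
        while True:
            span_lo = min(entries[i][3].start_s for i in members)
            span_hi = max(entries[i][3].end_s for i in members)
            absorbed = {
                i
                for i in range(len(entries))
                if i not in members and span_lo <= entries[i][3].start_s <= span_hi
            }
            if not absorbed or not p.absorb_to_fixpoint:
                members |= absorbed
                break
            members |= absorbed
        span_lo = min(entries[i][3].start_s for i in members)
        span_hi = max(entries[i][3].end_s for i in members)
        chans = {entries[i][1] for i in members}
        results.append(
            NetworkBurst(
                start_s=span_lo,
                end_s=span_hi,
                member_bursts=sorted((entries[i][1], entries[i][2]) for i in members),
                n_channels=len(chans),
                participation_pct=100.0 * len(chans) / active_channels
                if active_channels
                else 0.0,
            )
        )

    # merge overlapping candidates, re-checking participation jointly
    results.sort(key=lambda nb: nb.start_s)
    merged: list[NetworkBurst] = []
    for nb in results:
        if merged and nb.start_s <= merged[-1].end_s:
            prev = merged[-1]
            members = sorted(set(prev.member_bursts) | set(nb.member_bursts))
            chans = {ch for ch, _ in members}
            merged[-1] = NetworkBurst(
                start_s=prev.start_s,
                end_s=max(prev.end_s, nb.end_s),
                member_bursts=members,
                n_channels=len(chans),
                participation_pct=100.0 * len(chans) / active_channels
                if active_channels
                else 0.0,
            )
        else:
            merged.append(nb)

    # step 4: participation bound
    return [nb for nb in merged if nb.participation_pct >= p.min_participation_pct]


def network_burst_stats(
    nbs: list[NetworkBurst],
    duration: float,
    trains: dict[str, SpikeTrain] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-network-burst rows plus summary statistics.

    Rows hold start, end, duration, channel count and participation, and —
    when ``trains`` is given — the spike count, fire rate and mean ISI of
    spikes inside each network burst.  The summary reports the NB rate per
    minute, mean duration, mean inter-NB interval (next start minus previous
    end) and its coefficient of variation (sample SD / mean); with fewer
    than two NBs the mean IBI is NaN, and with fewer than three so is the CV.
    """
    rows = []
    for k, nb in enumerate(nbs):
        row = {
            "nb_index": k,
            "start_s": nb.start_s,
            "end_s": nb.end_s,
            "duration_s": nb.duration_s,
            "n_channels": nb.n_channels,
            "participation_pct": nb.participation_pct,
        }
        if trains is not None:
            spikes = np.sort(
                np.concatenate(
                    [
                        t.times[(t.times >= nb.start_s) & (t.times <= nb.end_s)]
                        for t in trains.values()
                    ]
                    or [np.empty(0)]
                )
            )
            row["n_spikes"] = int(len(spikes))
            row["fire_rate_hz"] = (
                len(spikes) / nb.duration_s if nb.duration_s > 0 else float("nan")
            )
            isis = np.diff(spikes)
            row["mean_isi_s"] = float(np.mean(isis)) if isis.size else float("nan")
        rows.append(row)
    table = pd.DataFrame(rows)

    summary = {
        "n_network_bursts": float(len(nbs)),
        "nb_rate_per_min": len(nbs) / duration * 60.0 if duration > 0 else 0.0,
        "mean_duration_s": float(np.mean([nb.duration_s for nb in nbs]))
        if nbs
        else float("nan"),
        "mean_ibi_s": float("nan"),
        "cv_ibi": float("nan"),
    }
    if len(nbs) >= 2:
        ibis = np.array(
            [nbs[k + 1].start_s - nbs[k].end_s for k in range(len(nbs) - 1)]
        )
        summary["mean_ibi_s"] = float(np.mean(ibis))
        if len(ibis) >= 2 and np.mean(ibis) > 0:
            summary["cv_ibi"] = float(np.std(ibis, ddof=1) / np.mean(ibis))
        elif len(ibis) == 1:
            summary["cv_ibi"] = float("nan")
    return table, summary
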
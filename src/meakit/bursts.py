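"""Single-channel burst (SCB) detection: max-interval and logISI methods.

A single-channel burst is a run of consecutive spikes with short inter-spike
intervals (ISIs) on one electrode.  The max-interval detector is governed by
five parameters (start interval, spike count, inter/intra-burst interval,
minimum duration); the logISI detector derives an intra-burst ISI cutoff
from the valley between peaks of the log10-ISI histogram, accepting the
valley only when the "void" separation statistic reaches a threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from meakit.containers import SpikeTrain


@dataclass
class MaxIntervalParams:
    start_interval_s: float = 0.05
    n_spikes: int = 3
    inter_burst_interval_s: float = 0.1
    intra_burst_interval_s: float = 0.1
    min_burst_duration_s: float = 0.03

    def __post_init__(self) -> None:
        if self.n_spikes < 2:
            raise ValueError("n_spikes must be at least 2")
        for name in (
            "start_interval_s",
            "inter_burst_interval_s",
            "intra_burst_interval_s",
            "min_burst_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LogISIParams:
    n_spikes: int = 3
    void_threshold_pct: float = 70.0
    # histogram construction (Pasquale-style defaults)
    bin_decades: float = 0.1
    smooth_bins: int = 3
    peak_min_height_frac: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.void_threshold_pct < 100:
            raise ValueError("void_threshold_pct must be in (0, 100)")
        if self.n_spikes < 2:
            raise ValueError("n_spikes must be at least 2")


@dataclass
class Burst:
    """A detected burst: a contiguous index range into its channel's train."""

    channel_id: str
    start_s: float
    end_s: float
    start_index: int
    end_index: int  # inclusive

    @property
    def n_spikes(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def spike_times(self, train: SpikeTrain) -> np.ndarray:
        return train.times[self.start_index : self.end_index + 1]


@dataclass
class BurstStats:
    n_bursts: int
    mean_duration_s: float
    mean_spikes_per_burst: float
    burst_rate_per_min: float
    mean_intra_burst_isi_s: float
    pct_spikes_in_bursts: float


def detect_max_interval(
    train: SpikeTrain, p: MaxIntervalParams | None = None
) -> list[Burst]:
    """Max-interval burst detection.

    Greedy left-to-right scan: a seed opens when two consecutive spikes have
    ISI <= ``start_interval_s``; subsequent spikes join while the ISI stays
    <= ``intra_burst_interval_s``.  A candidate is kept iff it has at least
    ``n_spikes`` spikes and lasts at least ``min_burst_duration_s``; kept
    bursts separated by a gap < ``inter_burst_interval_s`` are then merged
    (spikes falling in the merged gap are included).  ISI comparisons are
    inclusive.  The output is non-overlapping and time-ordered.
    """
    p = p or MaxIntervalParams()
    t = train.times
    n = len(t)
    seeds: list[tuple[int, int]] = []
    i = 0
    while i < n - 1:
        if t[i + 1] - t[i] <= p.start_interval_s:
            j = i + 1
            while j + 1 < n and t[j + 1] - t[j] <= p.intra_burst_interval_s:
                j += 1
            seeds.append((i, j))
            i = j + 1
        else:
            i += 1
    kept = [
        (a, b)
        for a, b in seeds
        if (b - a + 1) >= p.n_spikes and (t[b] - t[a]) >= p.min_burst_duration_s
    ]
    merged: list[list[int]] = []
    for a, b in kept:
        if merged and t[a] - t[merged[-1][1]] < p.inter_burst_interval_s:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [
        Burst(
            channel_id=train.channel_id,
            start_s=float(t[a]),
            end_s=float(t[b]),
            start_index=a,
            end_index=b,
        )
        for a, b in merged
    ]


def logisi_cutoff(isis: np.ndarray, p: LogISIParams) -> float | None:
    """Derive the intra-burst ISI cutoff from the log10-ISI histogram.

    Builds a fixed-width-decade histogram of log10(ISI), smooths it with a
    short moving average, and finds strict local maxima at least
    ``peak_min_height_frac`` of the tallest bin.  Scanning peak pairs in
    order, the void statistic at the inter-peak minimum,

        void = (1 - h_min / sqrt(h_peak1 * h_peak2)) * 100,

    is compared against ``void_threshold_pct``; the first qualifying valley
    gives the cutoff (the ISI at the minimum).  Returns None when fewer than
    two peaks exist or no valley is deep enough.
    """
    isis = isis[isis > 0]
    if len(isis) < 2:
        return None
    log_isi = np.log10(isis)
    # pad the range by one bin each side so boundary peaks are detectable
    lo = math.floor(log_isi.min() / p.bin_decades) * p.bin_decades - p.bin_decades
    hi = math.ceil(log_isi.max() / p.bin_decades) * p.bin_decades + p.bin_decades
    n_bins = max(int(round((hi - lo) / p.bin_decades)), 1)
    counts, edges = np.histogram(log_isi, bins=n_bins, range=(lo, hi))
    if p.smooth_bins > 1:
        kernel = np.ones(p.smooth_bins) / p.smooth_bins
        h = np.convolve(counts.astype(float), kernel, mode="same")
    else:
        h = counts.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2

    # find_peaks handles flat-topped (plateau) peaks that a strict
    # neighbour comparison would miss
    peaks_arr, _ = sp_signal.find_peaks(h, height=p.peak_min_height_frac * h.max())
    peaks = list(peaks_arr)
    if len(peaks) < 2:
        return None
    for a_pos in range(len(peaks) - 1):
        for b_pos in range(a_pos + 1, len(peaks)):
            pa, pb = peaks[a_pos], peaks[b_pos]
            between = h[pa + 1 : pb]
            if between.size == 0:
                continue
            k_min = pa + 1 + int(np.argmin(between))
            void = (1.0 - h[k_min] / math.sqrt(h[pa] * h[pb])) * 100.0
            if void >= p.void_threshold_pct:
                return float(10 ** centers[k_min])
    return None


def detect_logisi(train: SpikeTrain, p: LogISIParams | None = None) -> list[Burst]:
    """logISI burst detection.

    When a qualifying valley exists, runs of spikes whose ISIs are all
    <= the derived cutoff and containing at least ``n_spikes`` spikes become
    bursts; otherwise (unimodal histogram or shallow valley) no bursts are
    returned.
    """
    p = p or LogISIParams()
    t = train.times
    if len(t) < 3:
        return []
    isis = np.diff(t)
    cutoff = logisi_cutoff(isis, p)
    if cutoff is None:
        return []
    bursts: list[Burst] = []
    in_run = isis <= cutoff
    i = 0
    n_isi = len(isis)
    while i < n_isi:
        if in_run[i]:
            j = i
            while j + 1 < n_isi and in_run[j + 1]:
                j += 1
            # spikes i .. j+1
            if (j + 1 - i + 1) >= p.n_spikes:
                bursts.append(
                    Burst(
                        channel_id=train.channel_id,
                        start_s=float(t[i]),
                        end_s=float(t[j + 1]),
                        start_index=i,
                        end_index=j + 1,
                    )
                )
            i = j + 1
        else:
            i += 1
    return bursts


def burst_stats(
    bursts: list[Burst], train: SpikeTrain, duration: float
) -> BurstStats:
    """Per-channel burst statistics.

    With no bursts, counts and rates are zero and the means are NaN
    (reported missing downstream).
    """
    if not bursts:
        return BurstStats(0, float("nan"), float("nan"), 0.0, float("nan"), 0.0)
    durations = [b.duration_s for b in bursts]
    counts = [b.n_spikes for b in bursts]
    intra_isis = np.concatenate(
        [np.diff(b.spike_times(train)) for b in bursts if b.n_spikes >= 2]
    )
    n_in = sum(counts)
    total = train.n_spikes
    return BurstStats(
        n_bursts=len(bursts),
        mean_duration_s=float(np.mean(durations)),
        mean_spikes_per_burst=float(np.mean(counts)),
        burst_rate_per_min=len(bursts) / duration * 60.0 if duration > 0 else 0.0,
        mean_intra_burst_isi_s=float(np.mean(intra_isis)) if intra_isis.size else float("nan"),
        pct_spikes_in_bursts=100.0 * n_in / total if total else 0.0,
    )
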
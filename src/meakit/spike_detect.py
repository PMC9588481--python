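"""Spike detection: filtering, baseline-noise estimation, thresholding,
artifact rejection and active-channel flagging.

The detection threshold is 5x the RMS of "pure noise", found by splitting the
high-passed trace into 50-ms windows, estimating a Gaussian sigma per window
(the sample SD), and locating up to two disjoint 2-s stretches whose window
SDs all fall strictly below the per-channel median SD.  A channel with no
such stretch is considered too noisy and is excluded.  Spikes are local
extrema whose absolute value strictly exceeds the threshold on either
polarity; waveform-shape tests then remove artifacts, and channels firing
below 0.1 Hz are flagged inactive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from meakit.containers import SpikeTrain, SpikeTrainSet


@dataclass
class SpikeDetectParams:
    """Detection parameters (defaults are the standard analysis settings)."""

    filter_cutoff_hz: float = 200.0
    filter_order: int = 2
    noise_window_ms: float = 50.0
    pure_noise_stretch_s: float = 2.0
    threshold_factor: float = 5.0
    dead_time_ms: float = 0.0
    min_amplitude_uv: float = 0.0
    min_rate_hz: float = 0.1
    snippet_halfwidth_ms: float = 1.0
    # tolerance on the sub-median pure-noise test: a window counts as pure
    # noise when its SD < sub_median_tolerance x median SD.  The default
    # allows ~3 standard errors of a 50-ms window's SD estimate, so that a
    # 2-s all-pure-noise run exists on stationary noise; spike-laden windows
    # sit far above it.  Set to 1.0 for the strict sub-median rule.
    sub_median_tolerance: float = 1.1

    def __post_init__(self) -> None:
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be positive")
        for name in (
            "filter_cutoff_hz",
            "noise_window_ms",
            "pure_noise_stretch_s",
            "dead_time_ms",
            "min_amplitude_uv",
            "min_rate_hz",
            "snippet_halfwidth_ms",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class NoiseEstimate:
    """Baseline-noise statistics of one channel."""

    window_ms: float
    window_sds: np.ndarray
    median_sd: float
    pure_noise_spans: list[tuple[float, float]] = field(default_factory=list)
    rms: float = float("nan")
    threshold: float = float("nan")
    usable: bool = False


def highpass(
    trace: np.ndarray, sample_rate: float, cutoff: float = 200.0, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth high-pass filter.

    Forward-backward (``sosfiltfilt``) filtering preserves spike timing; the
    ``order`` is that of the one-pass design.
    """
    nyq = sample_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff, btype="highpass", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def _consecutive_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """[start, end) index ranges of True-runs of at least min_len windows."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and len(mask) - start >= min_len:
        runs.append((start, len(mask)))
    return runs


def estimate_noise(
    trace: np.ndarray, sample_rate: float, params: SpikeDetectParams | None = None
) -> NoiseEstimate:
    """Estimate baseline noise and the spike threshold for one channel.

    The per-window Gaussian sigma is the window sample SD.  Windows are
    non-overlapping; a pure-noise stretch is a run of consecutive windows,
    each with SD below the (tolerance-scaled) channel median, lasting at
    least ``pure_noise_stretch_s``.  The RMS is computed over the pooled samples of
    the first two disjoint stretches (one suffices; none marks the channel
    unusable), and the threshold is ``threshold_factor`` times that RMS.
    """
    p = params or SpikeDetectParams()
    trace = np.asarray(trace, dtype=float)
    win_n = int(round(p.noise_window_ms / 1000.0 * sample_rate))
    if win_n < 2 or len(trace) < win_n:
        raise ValueError("trace shorter than one noise window")
    n_win = len(trace) // win_n
    windows = trace[: n_win * win_n].reshape(n_win, win_n)
    sds = windows.std(axis=1, ddof=0)
    median_sd = float(np.median(sds))
    sub_median = sds < p.sub_median_tolerance * median_sd
    min_len = int(np.ceil(p.pure_noise_stretch_s * 1000.0 / p.noise_window_ms))
    runs = _consecutive_runs(sub_median, min_len)[:2]

    est = NoiseEstimate(window_ms=p.noise_window_ms, window_sds=sds, median_sd=median_sd)
    if not runs:
        return est
    samples = np.concatenate(
        [trace[a * win_n : b * win_n] for a, b in runs]
    )
    est.pure_noise_spans = [
        (a * win_n / sample_rate, b * win_n / sample_rate) for a, b in runs
    ]
    est.rms = float(np.sqrt(np.mean(samples**2)))
    est.threshold = p.threshold_factor * est.rms
    est.usable = True
    return est


def detect_spikes(
    trace: np.ndarray,
    sample_rate: float,
    noise: NoiseEstimate,
    params: SpikeDetectParams | None = None,
    channel_id: str = "",
) -> SpikeTrain:
    """Detect threshold-crossing spikes on one (already filtered) trace.

    Candidates are local extrema with ``|value|`` strictly above the
    threshold on either polarity; the spike time is the extremum sample.
    Candidates closer than the dead time collapse to the larger-amplitude
    one, sub-``min_amplitude_uv`` candidates are dropped, and a snippet of
    +/- ``snippet_halfwidth_ms`` is stored per spike (extrema too close to
    the trace edge for a full snippet are discarded).
    """
    p = params or SpikeDetectParams()
    if not noise.usable:
        raise ValueError("noise estimate unusable: channel excluded")
    trace = np.asarray(trace, dtype=float)
    thr = noise.threshold
    # strict exceedance on either polarity
    height = np.nextafter(thr, np.inf)
    pos, _ = signal.find_peaks(trace, height=height)
    neg, _ = signal.find_peaks(-trace, height=height)
    idx = np.sort(np.concatenate([pos, neg]))
    amps = trace[idx]

    if p.dead_time_ms > 0 and len(idx) > 1:
        dead_n = p.dead_time_ms / 1000.0 * sample_rate
        keep: list[int] = []
        for k in range(len(idx)):
            if keep and idx[k] - idx[keep[-1]] < dead_n:
                if abs(amps[k]) > abs(amps[keep[-1]]):
                    keep[-1] = k
            else:
                keep.append(k)
        idx, amps = idx[keep], amps[keep]

    if p.min_amplitude_uv > 0:
        m = np.abs(amps) >= p.min_amplitude_uv
        idx, amps = idx[m], amps[m]

    half_n = int(round(p.snippet_halfwidth_ms / 1000.0 * sample_rate))
    in_bounds = (idx >= half_n) & (idx < len(trace) - half_n)
    idx, amps = idx[in_bounds], amps[in_bounds]
    if len(idx):
        offsets = np.arange(-half_n, half_n + 1)
        waveforms = trace[idx[:, None] + offsets[None, :]]
    else:
        waveforms = np.empty((0, 2 * half_n + 1))
    return SpikeTrain(
        channel_id=channel_id,
        times=idx / sample_rate,
        amplitudes=amps,
        waveforms=waveforms,
        sample_rate=sample_rate,
    )


def _secondary_peak_excursion(snippet: np.ndarray, center: int) -> float:
    """Largest prominence of any local extremum other than the center.

    Prominence (how far a peak rises above its surroundings) rather than raw
    |value| is used so that noise ripples riding on the flank of a genuine
    spike lobe do not register as secondary peaks.
    """
    peaks, props = signal.find_peaks(np.abs(snippet), prominence=0.0)
    best = 0.0
    for p, prom in zip(peaks, props["prominences"]):
        if p != center:
            best = max(best, float(prom))
    return best


def reject_artifacts(train: SpikeTrain, window_ms: float = 1.0) -> SpikeTrain:
    """Drop detected spikes whose waveform fails the shape tests.

    A spike is kept iff, within its +/- ``window_ms`` snippet window:

    1. its extremum is the unique largest ``|value|``,
    2. no other local extremum has a prominence above 50% of the spike
       amplitude (the no-secondary-peak test; prominence is used so noise
       ripples on a spike lobe's flank do not count as peaks), and
    3. the waveform returns below 50% of the amplitude on each side of the
       extremum inside the window (more than half of the amplitude
       excursion falls within the window); slow drift bumps that stay
       elevated across the window fail this.
    """
    if train.waveforms is None or train.sample_rate is None:
        raise ValueError("artifact rejection requires waveform snippets")
    wf = train.waveforms
    half_n = (wf.shape[1] - 1) // 2
    win_n = int(round(window_ms / 1000.0 * train.sample_rate))
    if win_n > half_n:
        raise ValueError("snippets narrower than the artifact test window")
    center = half_n
    lo, hi = center - win_n, center + win_n + 1
    keep = np.ones(train.n_spikes, dtype=bool)
    for k in range(train.n_spikes):
        w = wf[k, lo:hi]
        c = win_n  # center within w
        amp = abs(w[c])
        others = np.abs(np.delete(w, c))
        if others.size and others.max() >= amp:
            keep[k] = False
            continue
        if _secondary_peak_excursion(w, c) > 0.5 * amp:
            keep[k] = False
            continue
        left_min = np.abs(w[:c]).min() if c > 0 else 0.0
        right_min = np.abs(w[c + 1 :]).min() if c < len(w) - 1 else 0.0
        if max(left_min, right_min) >= 0.5 * amp:
            keep[k] = False
    return train.subset(keep)


def flag_active(tset: SpikeTrainSet, min_rate_hz: float = 0.1) -> SpikeTrainSet:
    """Flag channels firing at >= ``min_rate_hz`` (inclusive) as active.

    Inactive channels are excluded from all downstream burst, network-burst
    and connectivity computations.
    """
    for ch in tset.layout.channel_ids:
        train = tset.trains.get(ch)
        if train is None:
            tset.active_flags[ch] = False
        else:
            tset.active_flags[ch] = train.rate(tset.duration) >= min_rate_hz
    return tset
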
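"""Synthetic MEA data with machine-checkable ground truth.

Generates the statistical structure every analysis stage assumes: Gaussian
baseline noise of per-channel sigma, injected biphasic spike templates,
Poisson and burst-structured firing, array-wide synchronized bursting,
cross-channel latency coupling of known strength, and multi-unit channels
mixing several waveform templates.  Every generator is deterministic for a
fixed seed and returns the ground truth (burst membership, network-burst
windows, coupling table, per-spike unit labels, injection times) consumed by
the test suites of the other modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import h5py
import numpy as np

from meakit.containers import Recording, SpikeTrain, SpikeTrainSet
from meakit.io_formats import write_spike_csv
from meakit.layouts import ChannelLayout, get_layout


@dataclass
class ChannelSpec:
    """Firing and waveform description of one synthetic channel."""

    noise_sigma_uv: float = 10.0
    firing: dict[str, Any] = field(
        default_factory=lambda: {"model": "poisson", "rate_hz": 2.0}
    )
    template_amplitudes_uv: tuple[float, ...] = (100.0,)


@dataclass
class Coupling:
    source: str
    target: str
    latency_s: float
    transmission_prob: float = 1.0
    jitter_s: float = 0.001

    def __post_init__(self) -> None:
        if not 0 <= self.transmission_prob <= 1:
            raise ValueError("transmission_prob must be in [0, 1]")
        if self.latency_s < 0:
            raise ValueError("latency must be non-negative")


@dataclass
class SynthSpec:
    seed: int = 0
    duration_s: float = 60.0
    sample_rate_hz: float = 10_000.0
    layout: str = "multiwell-12x12"
    channels: dict[str, ChannelSpec] = field(default_factory=dict)
    couplings: list[Coupling] = field(default_factory=list)
    # array-wide synchronized bursting shared by the listed channels
    network: dict[str, Any] | None = None


@dataclass
class GroundTruth:
    """Everything the generators know that the detectors must recover."""

    burst_windows: dict[str, list[tuple[float, float, int]]] = field(default_factory=dict)
    nb_windows: list[tuple[float, float]] = field(default_factory=list)
    couplings: list[Coupling] = field(default_factory=list)
    unit_labels: dict[str, np.ndarray] = field(default_factory=dict)
    injected_times: dict[str, np.ndarray] = field(default_factory=dict)
    injected_amplitudes: dict[str, np.ndarray] = field(default_factory=dict)
    overlapping_injections: dict[str, np.ndarray] = field(default_factory=dict)


def _poisson_times(rng: np.random.Generator, rate_hz: float, duration: float) -> np.ndarray:
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _burst_times(
    rng: np.random.Generator,
    duration: float,
    burst_rate_hz: float,
    spikes_per_burst: int,
    intra_isi_s: float,
    background_rate_hz: float = 0.0,
) -> tuple[np.ndarray, list[tuple[float, float, int]]]:
    burst_len = (spikes_per_burst - 1) * intra_isi_s
    onsets = _poisson_times(rng, burst_rate_hz, max(duration - burst_len, 0.0))
    # enforce non-overlapping bursts so ground-truth membership is unambiguous
    kept = []
    last_end = -np.inf
    for o in onsets:
        if o > last_end + intra_isi_s:
            kept.append(o)
            last_end = o + burst_len
    times, windows = [], []
    for o in kept:
        spikes = o + np.arange(spikes_per_burst) * intra_isi_s
        times.append(spikes)
        windows.append((float(spikes[0]), float(spikes[-1]), spikes_per_burst))
    bg = _poisson_times(rng, background_rate_hz, duration)
    # keep background spikes well away from bursts
    for (a, b, _) in windows:
        bg = bg[(bg < a - 2 * intra_isi_s) | (bg > b + 2 * intra_isi_s)]
    all_t = np.unique(np.concatenate(times + [bg]) if times else bg)
    return all_t[all_t < duration], windows


def gen_trains(spec: SynthSpec) -> tuple[SpikeTrainSet, GroundTruth]:
    """Generate spike trains plus ground truth per the spec.

    Couplings copy source spikes onto the target with the stated latency and
    Gaussian jitter, each with the stated transmission probability.  A
    ``network`` block of the form ``{"rate_hz", "spikes_per_burst",
    "intra_isi_s", "channels", "jitter_s"}`` gives the listed channels
    synchronized bursts at shared onsets.
    """
    rng = np.random.default_rng(spec.seed)
    layout = get_layout(spec.layout)
    gt = GroundTruth(couplings=list(spec.couplings))
    per_channel: dict[str, np.ndarray] = {}

    for ch, cs in spec.channels.items():
        model = cs.firing.get("model", "poisson")
        if model == "poisson":
            t = _poisson_times(rng, cs.firing.get("rate_hz", 2.0), spec.duration_s)
            gt.burst_windows[ch] = []
        elif model == "burst":
            t, windows = _burst_times(
                rng,
                spec.duration_s,
                cs.firing.get("burst_rate_hz", 0.2),
                cs.firing.get("spikes_per_burst", 5),
                cs.firing.get("intra_isi_s", 0.01),
                cs.firing.get("background_rate_hz", 0.0),
            )
            gt.burst_windows[ch] = windows
        elif model == "silent":
            t = np.empty(0)
            gt.burst_windows[ch] = []
        else:
            raise ValueError(f"unknown firing model {model!r}")
        per_channel[ch] = t

    if spec.network:
        nw = spec.network
        onsets = _poisson_times(rng, nw["rate_hz"], spec.duration_s * 0.95)
        spb = nw.get("spikes_per_burst", 5)
        intra = nw.get("intra_isi_s", 0.01)
        jitter = nw.get("jitter_s", 0.01)
        min_gap = 2 * ((spb - 1) * intra + 3 * jitter)
        kept = []
        last = -np.inf
        for o in onsets:
            if o - last > min_gap:
                kept.append(o)
                last = o
        for o in kept:
            starts, ends = [], []
            for ch in nw["channels"]:
                shift = abs(rng.normal(0.0, jitter))
                spikes = o + shift + np.arange(spb) * intra
                spikes = spikes[spikes < spec.duration_s]
                if spikes.size < 2:
                    continue
                per_channel[ch] = np.concatenate([per_channel.get(ch, np.empty(0)), spikes])
                gt.burst_windows.setdefault(ch, []).append(
                    (float(spikes[0]), float(spikes[-1]), int(spikes.size))
                )
                starts.append(spikes[0])
                ends.append(spikes[-1])
            if starts:
                gt.nb_windows.append((float(min(starts)), float(max(ends))))
        for ch in nw["channels"]:
            gt.burst_windows[ch] = sorted(gt.burst_windows.get(ch, []))

    for c in spec.couplings:
        src = per_channel.get(c.source, np.empty(0))
        fired = rng.random(len(src)) < c.transmission_prob
        echoes = src[fired] + c.latency_s + rng.normal(0.0, c.jitter_s, size=fired.sum())
        echoes = echoes[(echoes > 0) & (echoes < spec.duration_s)]
        per_channel[c.target] = np.concatenate(
            [per_channel.get(c.target, np.empty(0)), echoes]
        )

    trains = {
        ch: SpikeTrain(channel_id=ch, times=np.unique(t))
        for ch, t in per_channel.items()
        if len(t)
    }
    tset = SpikeTrainSet(layout=layout, duration=spec.duration_s, trains=trains)
    return tset, gt


def biphasic_template(
    sample_rate_hz: float,
    amplitude_uv: float = 100.0,
    neg_ms: float = 1.0,
    pos_ms: float = 0.5,
    pos_frac: float = 0.2,
) -> tuple[np.ndarray, int]:
    """Typical extracellular spike shape: negative lobe then smaller positive.

    Returns (template, peak_index); the negative peak has |value| equal to
    ``amplitude_uv`` and the trailing positive lobe ``pos_frac`` of it.
    """
    n_neg = max(int(round(neg_ms / 1000 * sample_rate_hz)), 3) | 1  # odd: unique peak
    n_pos = max(int(round(pos_ms / 1000 * sample_rate_hz)), 2)
    neg = -amplitude_uv * np.sin(np.linspace(0, np.pi, n_neg))
    pos = pos_frac * amplitude_uv * np.sin(np.linspace(0, np.pi, n_pos))
    tmpl = np.concatenate([neg, pos])
    return tmpl, int(np.argmin(tmpl))


def gen_voltage(
    tset: SpikeTrainSet, spec: SynthSpec, gt: GroundTruth | None = None
) -> tuple[Recording, GroundTruth]:
    """Render spike trains into noisy voltage traces.

    Per channel: Gaussian noise of the specified sigma plus one template per
    spike, peak-aligned at the spike time.  Multi-unit channels draw each
    spike's template uniformly among the channel's amplitudes; the exact
    injected times, signed amplitudes and unit labels land in the ground
    truth, and injections whose templates overlap a neighbour are flagged.
    """
    rng = np.random.default_rng(spec.seed + 1)
    layout = get_layout(spec.layout)
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    gt = gt or GroundTruth()
    traces: dict[str, np.ndarray] = {}
    for ch, cs in spec.channels.items():
        trace = rng.normal(0.0, cs.noise_sigma_uv, size=n)
        times = tset.trains[ch].times if ch in tset.trains else np.empty(0)
        units = (
            rng.integers(0, len(cs.template_amplitudes_uv), size=len(times))
            if len(cs.template_amplitudes_uv) > 1
            else np.zeros(len(times), dtype=int)
        )
        templates = [
            biphasic_template(spec.sample_rate_hz, amplitude_uv=a)
            for a in cs.template_amplitudes_uv
        ]
        kept_t, kept_a, kept_u = [], [], []
        for t, u in zip(times, units):
            tmpl, peak = templates[u]
            start = int(round(t * spec.sample_rate_hz)) - peak
            if start < 0 or start + len(tmpl) > n:
                continue
            trace[start : start + len(tmpl)] += tmpl
            kept_t.append((start + peak) / spec.sample_rate_hz)
            kept_a.append(-cs.template_amplitudes_uv[u])
            kept_u.append(u)
        kept_t = np.asarray(kept_t)
        span = max(len(tmpl) for tmpl, _ in templates) / spec.sample_rate_hz if templates else 0.0
        overlap = np.zeros(len(kept_t), dtype=bool)
        if len(kept_t) > 1:
            d = np.diff(kept_t)
            overlap[1:] |= d < span
            overlap[:-1] |= d < span
        gt.injected_times[ch] = kept_t
        gt.injected_amplitudes[ch] = np.asarray(kept_a)
        gt.unit_labels[ch] = np.asarray(kept_u, dtype=int)
        gt.overlapping_injections[ch] = overlap
        traces[ch] = trace
    rec = Recording(
        layout=layout,
        sample_rate=spec.sample_rate_hz,
        duration=spec.duration_s,
        traces=traces,
        source_path="<synthetic>",
    )
    return rec, gt


def write_fixture(obj: Recording | SpikeTrainSet, path: str, fmt: str) -> None:
    """Write a fixture file in a documented format: ``hdf5`` or ``csv``."""
    if fmt == "hdf5":
        if not isinstance(obj, Recording):
            raise ValueError("hdf5 fixtures hold Recording objects")
        with h5py.File(path, "w") as f:
            f.create_dataset("/meta/sample_rate_hz", data=float(obj.sample_rate))
            f.create_dataset("/meta/layout", data=obj.layout.name)
            for ch, tr in obj.traces.items():
                well = obj.layout.well_names[obj.layout.well_of_channel[ch]]
                f.create_dataset(f"/wells/{well}/channels/{ch}/voltage_uv", data=tr)
    elif fmt == "csv":
        if not isinstance(obj, SpikeTrainSet):
            raise ValueError("csv fixtures hold SpikeTrainSet objects")
        write_spike_csv(obj, path)
    else:
        raise ValueError(f"unknown fixture format {fmt!r}; use 'hdf5' or 'csv'")
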
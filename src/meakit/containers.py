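"""Core in-memory containers shared by every analysis stage.

Conventions: times in seconds (float64), voltages in microvolts, channel
labels as displayed, channel/well indices 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from meakit.layouts import ChannelLayout


@dataclass
class Recording:
    """Continuous per-channel voltage traces plus plate metadata."""

    layout: ChannelLayout
    sample_rate: float
    duration: float
    traces: dict[str, np.ndarray]
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        n_expected = round(self.duration * self.sample_rate)
        for ch, tr in self.traces.items():
            if ch not in self.layout.channel_ids:
                raise ValueError(f"trace channel {ch!r} not in layout {self.layout.name}")
            if len(tr) != n_expected:
                raise ValueError(
                    f"channel {ch}: {len(tr)} samples, expected {n_expected}"
                )

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.sample_rate)


@dataclass
class SpikeTrain:
    """Spike times on one channel, optionally with amplitudes and waveforms."""

    channel_id: str
    times: np.ndarray
    amplitudes: np.ndarray | None = None
    waveforms: np.ndarray | None = None  # spikes x snippet samples, uV
    sample_rate: float | None = None  # of the waveform snippets

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"channel {self.channel_id}: times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("negative spike time")
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
            if len(self.amplitudes) != len(self.times):
                raise ValueError("amplitudes length mismatch")
        if self.waveforms is not None:
            self.waveforms = np.asarray(self.waveforms, dtype=float)
            if self.waveforms.shape[0] != len(self.times):
                raise ValueError("waveform row count must equal spike count")

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def rate(self, duration: float) -> float:
        return self.n_spikes / duration if duration > 0 else 0.0

    def isis(self) -> np.ndarray:
        return np.diff(self.times)

    def subset(self, mask: np.ndarray) -> "SpikeTrain":
        return SpikeTrain(
            channel_id=self.channel_id,
            times=self.times[mask],
            amplitudes=None if self.amplitudes is None else self.amplitudes[mask],
            waveforms=None if self.waveforms is None else self.waveforms[mask],
            sample_rate=self.sample_rate,
        )


@dataclass
class SpikeTrainSet:
    """All spike trains of one recording plus per-channel activity flags."""

    layout: ChannelLayout
    duration: float
    trains: dict[str, SpikeTrain] = field(default_factory=dict)
    active_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.trains) - set(self.layout.channel_ids)
        if unknown:
            raise ValueError(f"train channels not in layout: {sorted(unknown)}")

    def active_channels(self) -> list[str]:
        """Channels flagged active, in layout order."""
        return [c for c in self.layout.channel_ids if self.active_flags.get(c, False)]

    def active_trains(self) -> dict[str, SpikeTrain]:
        return {c: self.trains[c] for c in self.active_channels() if c in self.trains}
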
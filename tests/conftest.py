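"""Shared fixtures: small synthetic recordings and spike-train constructions."""

from __future__ import annotations

import numpy as np
import pytest

from meakit.containers import SpikeTrain
from meakit.layouts import get_layout
from meakit.synth import ChannelSpec, SynthSpec, gen_trains, gen_voltage


@pytest.fixture(scope="session")
def small_recording():
    """12-channel, 10 kHz, 10 s noisy recording with sparse injected spikes."""
    layout = get_layout("multiwell-12x12")
    chans = {
        c: ChannelSpec(noise_sigma_uv=5.0, firing={"model": "poisson", "rate_hz": 0.5})
        for c in layout.channels_of_well(0)
    }
    spec = SynthSpec(seed=42, duration_s=10.0, layout="multiwell-12x12", channels=chans)
    tset, gt = gen_trains(spec)
    rec, gt = gen_voltage(tset, spec, gt)
    return rec, tset, gt


def poisson_train(seed: int, rate_hz: float, duration: float, channel: str = "x") -> SpikeTrain:
    rng = np.random.default_rng(seed)
    n = max(rng.poisson(rate_hz * duration), 2)
    return SpikeTrain(channel, np.unique(rng.uniform(0.0, duration, n)))
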
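"""Filtering, noise estimation, spike detection and artifact rejection."""

import numpy as np
import pytest

from meakit.containers import SpikeTrain, SpikeTrainSet
from meakit.layouts import get_layout
from meakit.spike_detect import (
    SpikeDetectParams,
    detect_spikes,
    estimate_noise,
    flag_active,
    highpass,
    reject_artifacts,
)
from meakit.synth import ChannelSpec, SynthSpec, biphasic_template, gen_trains, gen_voltage

FS = 10_000.0


def _butter_hp_gain(f_hz: float, cutoff: float = 200.0, order: int = 2) -> float:
    """Analytic two-pass magnitude response of the Butterworth high-pass."""
    ratio = (cutoff / f_hz) ** (2 * order)
    return (1.0 + ratio) ** -0.5  # single-pass |H|

def test_highpass_kills_dc():
    out = highpass(np.full(int(FS), 123.0), FS)
    assert np.max(np.abs(out)) < 1e-6 * 123.0


@pytest.mark.parametrize(
    ("freq", "check"),
    [
        (1000.0, lambda atten: atten < 0.05),  # passband: < 5% attenuation
        (10.0, lambda atten: atten > 0.99),  # stopband: > 99% attenuation
    ],
)
def test_highpass_matches_analytic_butterworth_response(freq, check):
    t = np.arange(int(5 * FS)) / FS
    out = highpass(np.sin(2 * np.pi * freq * t), FS)
    mid = out[int(FS) : -int(FS)]  # avoid filter edge transients
    amp = np.sqrt(2) * np.std(mid)  # sine amplitude via RMS (max misses the crest)
    # zero-phase filtering applies |H|^2
    expected = _butter_hp_gain(freq) ** 2
    atten = 1.0 - amp
    assert check(atten)
    assert amp == pytest.approx(expected, abs=0.02)


def test_highpass_rejects_cutoff_at_nyquist():
    with pytest.raises(ValueError, match="Nyquist"):
        highpass(np.zeros(100), 1000.0, cutoff=600.0)


def test_noise_estimate_on_iid_gaussian():
    """RMS of pooled pure-noise spans tracks the true sigma within 10%."""
    rng = np.random.default_rng(0)
    trace = rng.normal(0, 10.0, int(60 * FS))
    ne = estimate_noise(trace, FS)
    assert ne.usable
    assert 1 <= len(ne.pure_noise_spans) <= 2
    for a, b in ne.pure_noise_spans:
        assert b - a >= 2.0
    assert ne.rms == pytest.approx(10.0, rel=0.10)
    assert ne.threshold == pytest.approx(5 * ne.rms, rel=1e-12)
    # oracle: RMS recomputed directly from the span samples
    samples = np.concatenate(
        [trace[int(a * FS) : int(b * FS)] for a, b in ne.pure_noise_spans]
    )
    assert ne.rms == pytest.approx(float(np.sqrt(np.mean(samples**2))), rel=1e-12)


def test_noise_spans_avoid_spiky_half():
    """Spikes confined to the second half push both spans into the first."""
    rng = np.random.default_rng(1)
    trace = rng.normal(0, 5.0, int(20 * FS))
    tmpl, peak = biphasic_template(FS, 100.0)
    inj = np.arange(10.5, 19.5, 0.15)  # dense spikes, second half only
    for t in inj:
        k = int(t * FS) - peak
        trace[k : k + len(tmpl)] += tmpl
    ne = estimate_noise(trace, FS)
    assert ne.usable
    for a, b in ne.pure_noise_spans:
        assert b <= 10.5


def test_identical_windows_tie_is_unusable_under_strict_rule():
    """With the strict sub-median comparison, all-equal window SDs tie."""
    block = np.tile(np.array([1.0, -1.0]), int(FS * 0.05) // 2)
    trace = np.tile(block, 100)
    params = SpikeDetectParams(sub_median_tolerance=1.0)
    ne = estimate_noise(trace, FS, params)
    assert not ne.usable
    assert ne.pure_noise_spans == []


def test_trace_shorter_than_window_rejected():
    with pytest.raises(ValueError, match="shorter"):
        estimate_noise(np.zeros(10), FS)


def _usable_noise(seed: int = 0, sigma: float = 5.0):
    rng = np.random.default_rng(seed)
    return estimate_noise(rng.normal(0, sigma, int(30 * FS)), FS)


def test_detect_spikes_empty_on_zero_trace():
    ne = _usable_noise()
    train = detect_spikes(np.zeros(int(FS)), FS, ne)
    assert train.n_spikes == 0


def test_threshold_exceedance_is_strict():
    ne = _usable_noise()
    trace = np.zeros(int(FS))
    trace[5000] = ne.threshold  # exactly at threshold: not a spike
    assert detect_spikes(trace, FS, ne).n_spikes == 0
    trace[5000] = np.nextafter(ne.threshold, np.inf)
    assert detect_spikes(trace, FS, ne).n_spikes == 1


def test_both_polarities_detected():
    ne = _usable_noise()
    trace = np.zeros(int(FS))
    trace[2000] = 2 * ne.threshold
    trace[7000] = -2 * ne.threshold
    train = detect_spikes(trace, FS, ne)
    assert train.n_spikes == 2
    assert train.amplitudes[0] > 0 > train.amplitudes[1]


def test_injected_spike_recovery_with_artifact_rejection():
    """20 injected 100-uV biphasic spikes on sigma=5 noise: all recovered."""
    spec = SynthSpec(
        seed=5,
        duration_s=60.0,
        layout="multiwell-12x12",
        channels={
            "A1-01": ChannelSpec(
                noise_sigma_uv=5.0, firing={"model": "poisson", "rate_hz": 20 / 60}
            )
        },
    )
    tset, gt = gen_trains(spec)
    rec, gt = gen_voltage(tset, spec, gt)
    filtered = highpass(rec.traces["A1-01"], FS)
    ne = estimate_noise(filtered, FS)
    assert ne.usable
    train = reject_artifacts(detect_spikes(filtered, FS, ne, channel_id="A1-01"))
    true = gt.injected_times["A1-01"]
    matched = sum(1 for t in true if np.min(np.abs(train.times - t)) <= 0.0002)
    assert matched == len(true)
    assert train.n_spikes == len(true)  # no extras


def test_artifact_rejection_examples():
    fs = FS
    tmpl, peak = biphasic_template(fs, 100.0)
    half = int(0.001 * fs)
    width = 2 * half + 1

    def as_train(snippet, amp):
        return SpikeTrain(
            "c", np.array([0.01]), amplitudes=np.array([amp]),
            waveforms=snippet.reshape(1, -1), sample_rate=fs,
        )

    # clean biphasic template: kept
    snip = np.zeros(width)
    snip[half - peak : half - peak + len(tmpl)] = tmpl
    assert reject_artifacts(as_train(snip, -100.0)).n_spikes == 1

    # two equal-height peaks 0.8 ms apart: rejected (not the unique maximum)
    snip = np.zeros(width)
    snip[half] = -100.0
    snip[half + int(0.0008 * fs)] = -100.0
    assert reject_artifacts(as_train(snip, -100.0)).n_spikes == 0

    # slow 5-ms drift bump: amplitude barely decays inside +/-1 ms, rejected
    n_bump = int(0.005 * fs)
    bump = 100.0 * np.sin(np.linspace(0, np.pi, n_bump))
    c = n_bump // 2
    snip = bump[c - half : c + half + 1].copy()
    assert reject_artifacts(as_train(snip, 100.0)).n_spikes == 0

    # genuine secondary peak at 60% amplitude: rejected
    snip = np.zeros(width)
    snip[half - peak : half - peak + len(tmpl)] = tmpl
    snip[half + int(0.0008 * fs)] = -60.0
    assert reject_artifacts(as_train(snip, -100.0)).n_spikes == 0


def test_artifact_rejection_requires_waveforms():
    train = SpikeTrain("c", np.array([0.5]))
    with pytest.raises(ValueError, match="waveform"):
        reject_artifacts(train)


def test_false_positive_rate_on_pure_noise():
    """On spike-free noise the detected rate stays below 0.01 Hz."""
    total_spikes, total_s = 0, 0.0
    for seed in range(3):
        rng = np.random.default_rng(100 + seed)
        trace = highpass(rng.normal(0, 5.0, int(100 * FS)), FS)
        ne = estimate_noise(trace, FS)
        train = reject_artifacts(detect_spikes(trace, FS, ne))
        total_spikes += train.n_spikes
        total_s += 100.0
    assert total_spikes / total_s < 0.01


@pytest.mark.parametrize(
    ("n_spikes", "duration", "active"),
    [(1, 10.0, True), (0, 10.0, False), (5, 100.0, False)],
)
def test_flag_active_boundaries(n_spikes, duration, active):
    layout = get_layout("multiwell-12x12")
    ch = layout.channel_ids[0]
    trains = {}
    if n_spikes:
        trains[ch] = SpikeTrain(ch, np.linspace(1.0, duration - 1.0, n_spikes))
    tset = SpikeTrainSet(layout=layout, duration=duration, trains=trains)
    flag_active(tset, 0.1)
    assert tset.active_flags[ch] is active
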
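"""Single-channel burst detection: max-interval oracle equivalence and
logISI behaviour."""

import numpy as np
import pytest

from meakit.bursts import (
    Burst,
    LogISIParams,
    MaxIntervalParams,
    burst_stats,
    detect_logisi,
    detect_max_interval,
)
from meakit.containers import SpikeTrain


def brute_force_max_interval(times, p: MaxIntervalParams):
    """Independent reference implementation of the five max-interval rules.

    Seeds are located by an explicit chain-growing loop over candidate start
    pairs; filters and the merge pass are applied in the documented order.
    """
    times = list(times)
    n = len(times)
    used_until = -1
    seeds = []
    for i in range(n - 1):
        if i <= used_until:
            continue
        if times[i + 1] - times[i] <= p.start_interval_s:
            j = i + 1
            while j + 1 < n and times[j + 1] - times[j] <= p.intra_burst_interval_s:
                j += 1
            seeds.append((i, j))
            used_until = j
    kept = [
        (a, b)
        for (a, b) in seeds
        if b - a + 1 >= p.n_spikes and times[b] - times[a] >= p.min_burst_duration_s
    ]
    out = []
    for a, b in kept:
        if out and times[a] - times[out[-1][1]] < p.inter_burst_interval_s:
            out[-1] = (out[-1][0], b)
        else:
            out.append((a, b))
    return out


def random_train(rng):
    """Random short train mixing dense and sparse ISIs around the defaults."""
    n = rng.integers(2, 50)
    isis = rng.choice(
        [0.01, 0.03, 0.05, 0.08, 0.1, 0.12, 0.3, 1.0], size=n - 1
    ) * rng.uniform(0.5, 1.5, size=n - 1)
    return np.concatenate([[0.0], np.cumsum(isis)])


def test_max_interval_matches_brute_force_on_random_trains():
    rng = np.random.default_rng(12345)
    p = MaxIntervalParams()
    for _ in range(1000):
        times = random_train(rng)
        got = detect_max_interval(SpikeTrain("c", times), p)
        want = brute_force_max_interval(times, p)
        assert [(b.start_index, b.end_index) for b in got] == want


def test_max_interval_examples():
    p = MaxIntervalParams()
    b = detect_max_interval(SpikeTrain("c", [0.0, 0.02, 0.04, 0.06]), p)
    assert len(b) == 1
    assert b[0].n_spikes == 4
    assert b[0].duration_s == pytest.approx(0.06)

    assert detect_max_interval(SpikeTrain("c", [0.0, 0.02]), p) == []

    # two qualifying bursts separated by a gap below the inter-burst interval
    # (gap must exceed the intra-burst interval so they are distinct seeds)
    p2 = MaxIntervalParams(inter_burst_interval_s=0.3, intra_burst_interval_s=0.05)
    t = [0.0, 0.02, 0.04, 0.24, 0.26, 0.28]
    merged = detect_max_interval(SpikeTrain("c", t), p2)
    assert len(merged) == 1
    assert merged[0].n_spikes == 6
    # with a strict inter-burst rule they stay separate
    p3 = MaxIntervalParams(inter_burst_interval_s=0.1, intra_burst_interval_s=0.05)
    assert len(detect_max_interval(SpikeTrain("c", t), p3)) == 2


@pytest.mark.parametrize("n_spikes_lo,n_spikes_hi", [(2, 3), (3, 4), (4, 6)])
def test_raising_min_spike_count_never_adds_bursts(n_spikes_lo, n_spikes_hi):
    rng = np.random.default_rng(7)
    for _ in range(200):
        times = random_train(rng)
        lo = detect_max_interval(SpikeTrain("c", times), MaxIntervalParams(n_spikes=n_spikes_lo))
        hi = detect_max_interval(SpikeTrain("c", times), MaxIntervalParams(n_spikes=n_spikes_hi))
        assert len(hi) <= len(lo)


def test_widening_intra_interval_never_loses_burst_spikes():
    rng = np.random.default_rng(8)
    for _ in range(200):
        times = random_train(rng)
        narrow = detect_max_interval(
            SpikeTrain("c", times), MaxIntervalParams(intra_burst_interval_s=0.05)
        )
        wide = detect_max_interval(
            SpikeTrain("c", times), MaxIntervalParams(intra_burst_interval_s=0.15)
        )
        assert sum(b.n_spikes for b in wide) >= sum(b.n_spikes for b in narrow)


def test_bursts_ordered_and_non_overlapping():
    rng = np.random.default_rng(9)
    for _ in range(300):
        times = random_train(rng)
        bursts = detect_max_interval(SpikeTrain("c", times))
        for b0, b1 in zip(bursts, bursts[1:]):
            assert b0.end_s < b1.start_s
            assert b0.end_index < b1.start_index


def _bimodal_train(seed=0, n_bursts=40, spb=5, intra=0.01, gap=2.0):
    rng = np.random.default_rng(seed)
    times, truth = [], []
    t0 = 0.0
    for _ in range(n_bursts):
        burst = t0 + np.arange(spb) * intra
        times.append(burst)
        truth.append((burst[0], burst[-1]))
        t0 = burst[-1] + gap + rng.uniform(-0.2, 0.2)
    return np.concatenate(times), truth


def test_logisi_recovers_bimodal_bursts():
    times, truth = _bimodal_train()
    bursts = detect_logisi(SpikeTrain("c", times))
    assert len(bursts) == len(truth)
    for b, (s, e) in zip(bursts, truth):
        assert b.start_s == pytest.approx(s)
        assert b.end_s == pytest.approx(e)
        # self-consistency: internal ISIs at or below an in-range cutoff
        isis = np.diff(times[b.start_index : b.end_index + 1])
        assert np.all(isis <= 2.0)
        assert np.all(isis >= 0.009)


def test_logisi_cutoff_lies_between_modes():
    from meakit.bursts import logisi_cutoff

    times, _ = _bimodal_train()
    cutoff = logisi_cutoff(np.diff(times), LogISIParams())
    assert 0.01 < cutoff < 2.0


def test_logisi_mostly_silent_on_poisson_trains():
    """Unimodal log-ISI histograms should rarely produce any burst."""
    seeds_with_bursts = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        times = np.unique(rng.uniform(0, 100, 100))
        if detect_logisi(SpikeTrain("c", times)):
            seeds_with_bursts += 1
    assert seeds_with_bursts <= 2


def test_logisi_needs_at_least_three_spikes():
    assert detect_logisi(SpikeTrain("c", [0.0, 1.0])) == []


def test_burst_stats_arithmetic():
    times = np.concatenate([[0.0, 0.02, 0.04, 0.06], np.arange(10.0, 16.0)])
    train = SpikeTrain("c", times)
    bursts = [Burst("c", 0.0, 0.06, 0, 3)]
    s = burst_stats(bursts, train, 60.0)
    assert s.n_bursts == 1
    assert s.pct_spikes_in_bursts == pytest.approx(40.0)
    assert s.burst_rate_per_min == pytest.approx(1.0)
    assert s.mean_duration_s == pytest.approx(0.06)
    assert s.mean_intra_burst_isi_s == pytest.approx(0.02)

    empty = burst_stats([], train, 60.0)
    assert empty.n_bursts == 0
    assert empty.pct_spikes_in_bursts == 0.0
    assert np.isnan(empty.mean_duration_s)

    two = [Burst("c", 0.0, 0.04, 0, 2), Burst("c", 10.0, 14.0, 4, 8)]
    assert burst_stats(two, train, 60.0).mean_spikes_per_burst == pytest.approx(4.0)
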
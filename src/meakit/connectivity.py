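"""Functional connectivity via conditional firing probability (CFP).

For an ordered electrode pair (i, j) the CFP curve gives, per 0.5-ms lag bin
up to 500 ms, the probability that j fires at lag tau given that i fired at
lag 0: the count of (i, j) spike pairs with lag in the bin divided by the
number of source spikes N_i.  Each curve is summarized by fitting the
four-parameter peaked function

    CFP_fit[tau] = M / (1 + ((tau - T) / w)^2) + offset

by Nelder-Mead minimization of the mean squared error; M is the connection
strength, T the latency, w the peak width and offset the uncorrelated
background level.  The recording is split into fixed-spike-count chunks
(spikes summed over all channels), curves fitted per chunk, and connection
strength/latency matrices assembled from the chunk-averaged M and T.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from meakit.containers import SpikeTrain, SpikeTrainSet


@dataclass
class CFPCurve:
    source: str
    target: str
    bin_s: float
    max_lag_s: float
    probabilities: np.ndarray
    n_source_spikes: int

    @property
    def n_bins(self) -> int:
        return len(self.probabilities)

    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_s


@dataclass
class CFPFit:
    M: float
    T_s: float
    w_s: float
    offset: float
    mse: float


@dataclass
class ConnectivityMatrix:
    channels: list[str]
    strength: np.ndarray
    latency: np.ndarray
    mask: np.ndarray

    def top_connections(self, k: int = 60) -> list[tuple[str, str, float, float]]:
        """The k strongest accepted connections as (source, target, M, T)."""
        pairs = []
        n = len(self.channels)
        for i, j in itertools.product(range(n), repeat=2):
            if i != j and self.mask[i, j]:
                pairs.append(
                    (
                        self.channels[i],
                        self.channels[j],
                        float(self.strength[i, j]),
                        float(self.latency[i, j]),
                    )
                )
        pairs.sort(key=lambda p: -p[2])
        return pairs[:k]


def compute_cfp(
    train_i: SpikeTrain,
    train_j: SpikeTrain,
    bin_s: float = 0.0005,
    max_lag_s: float = 0.5,
) -> CFPCurve:
    """CFP curve for the ordered pair (source i, target j).

    A target spike at lag tau with 0 < tau <= max_lag_s after a source spike
    increments bin floor(tau / bin_s) (tau == max_lag_s lands in the last
    bin); coincident spikes (tau == 0) are excluded.  Bins are divided by
    the source spike count.
    """
    ti, tj = train_i.times, train_j.times
    n_i = len(ti)
    if n_i == 0:
        raise ValueError(f"CFP undefined: source {train_i.channel_id} has no spikes")
    n_bins = int(round(max_lag_s / bin_s))
    counts = np.zeros(n_bins)
    lo = np.searchsorted(tj, ti, side="right")  # first target strictly after
    hi = np.searchsorted(tj, ti + max_lag_s, side="right")
    for a, b, t0 in zip(lo, hi, ti):
        if b > a:
            lags = tj[a:b] - t0
            bins = np.minimum((lags / bin_s).astype(int), n_bins - 1)
            np.add.at(counts, bins, 1)
    return CFPCurve(
        source=train_i.channel_id,
        target=train_j.channel_id,
        bin_s=bin_s,
        max_lag_s=max_lag_s,
        probabilities=counts / n_i,
        n_source_spikes=n_i,
    )


def chunk_edges(tset: SpikeTrainSet, chunk_spikes: int) -> list[tuple[float, float]]:
    """Partition [0, duration] at array-wide cumulative spike-count multiples.

    The trailing partial chunk is kept iff it is at least half full; with
    fewer spikes than half a chunk the whole recording is one chunk.
    """
    all_times = np.sort(
        np.concatenate([t.times for t in tset.active_trains().values()] or [np.empty(0)])
    )
    total = len(all_times)
    if total < chunk_spikes // 2 or total == 0:
        return [(0.0, tset.duration)]
    edges = [0.0]
    k = chunk_spikes
    while k < total:
        edges.append(float(all_times[k]))
        k += chunk_spikes
    remainder = total - (len(edges) - 1) * chunk_spikes
    if remainder >= chunk_spikes / 2 or len(edges) == 1:
        edges.append(tset.duration)
    else:
        edges[-1] = tset.duration
    return list(zip(edges[:-1], edges[1:]))


def chunk_and_average(
    tset: SpikeTrainSet,
    chunk_spikes: int = 10_000,
    bin_s: float = 0.0005,
    max_lag_s: float = 0.5,
) -> dict[tuple[str, str], list[CFPCurve]]:
    """CFP curves per ordered active-channel pair, one per chunk.

    Chunks are defined by the array-wide spike count; within each chunk a
    curve is computed for every ordered pair whose source fires at least
    once in the chunk.
    """
    active = tset.active_trains()
    spans = chunk_edges(tset, chunk_spikes)
    out: dict[tuple[str, str], list[CFPCurve]] = {
        (i, j): [] for i in active for j in active if i != j
    }
    for t0, t1 in spans:
        clipped = {
            ch: SpikeTrain(channel_id=ch, times=t.times[(t.times >= t0) & (t.times < t1)])
            for ch, t in active.items()
        }
        for (i, j) in out:
            if clipped[i].n_spikes == 0:
                continue
            out[(i, j)].append(
                compute_cfp(clipped[i], clipped[j], bin_s=bin_s, max_lag_s=max_lag_s)
            )
    return out


def _cfp_model(tau: np.ndarray, M: float, T: float, w: float, offset: float) -> np.ndarray:
    return M / (1.0 + ((tau - T) / w) ** 2) + offset


def fit_cfp(
    curve: CFPCurve,
    maxiter: int = 4000,
    xatol: float = 1e-10,
    fatol: float = 1e-14,
) -> CFPFit:
    """Fit the four-parameter peaked function to a CFP curve.

    Nelder-Mead multistart: T0 at the argmax bin center, M0 = max - median,
    offset0 = median, and widths w0 of 2, 10 and 50 ms; each start is run
    and the best simplex result is polished by one tightened restart.  The
    returned fit carries its residual MSE.  An all-zero curve raises (the
    caller records "no connection").
    """
    y = curve.probabilities
    if not np.any(y):
        raise ValueError("degenerate all-zero CFP curve")
    tau = curve.bin_centers()
    med = float(np.median(y))
    m0 = max(float(y.max()) - med, 1e-6)
    t0 = float(tau[int(np.argmax(y))])

    def loss(x: np.ndarray) -> float:
        M, T, w, off = x
        if w <= 0 or M < 0 or off < 0:
            return 1e9 * (1 + abs(float(M)) + abs(float(w)) + abs(float(off)))
        return float(np.mean((_cfp_model(tau, M, T, w, off) - y) ** 2))

    best = None
    for w0 in (0.002, 0.010, 0.050):
        res = optimize.minimize(
            loss,
            np.array([m0, t0, w0, max(med, 1e-6)]),
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol},
        )
        if best is None or res.fun < best.fun:
            best = res
    # tightened restart from the best point (still Nelder-Mead)
    res = optimize.minimize(
        loss,
        best.x,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": xatol / 100, "fatol": fatol / 100},
    )
    if res.fun <= best.fun:
        best = res
    M, T, w, off = best.x
    return CFPFit(M=float(M), T_s=float(T), w_s=float(abs(w)), offset=float(off), mse=float(best.fun))


def accept_fit(
    fit: CFPFit, curve: CFPCurve, snr_factor: float = 2.0
) -> bool:
    """Connection acceptance rule.

    Accept iff the fitted peak is inside the lag range, is physically
    plausible (CFP values are probabilities, so M + offset <= 1, and a real
    peak spans more than one lag bin, so w >= bin width), and the strength M
    exceeds ``snr_factor`` times the background noise level, estimated as
    the SD of the bins outside T +/- 5w.
    """
    if not (0 < fit.T_s <= curve.max_lag_s) or fit.M <= 0:
        return False
    if fit.M + fit.offset > 1.0 or fit.w_s < curve.bin_s:
        return False
    tau = curve.bin_centers()
    outside = np.abs(tau - fit.T_s) > 5 * fit.w_s
    if outside.sum() < 10:
        return False
    noise_sd = float(np.std(curve.probabilities[outside]))
    return fit.M > snr_factor * max(noise_sd, 1e-12)


def build_matrix(
    fits: dict[tuple[str, str], list[tuple[CFPFit, bool]]],
    channels: list[str],
) -> ConnectivityMatrix:
    """Assemble strength/latency matrices from per-pair per-chunk fits.

    ``fits`` maps (source, target) to a list of (fit, accepted) per chunk;
    strength and latency are the means over accepted chunk fits, and the
    mask is False where no chunk was accepted.  The diagonal is excluded.
    """
    n = len(channels)
    idx = {c: k for k, c in enumerate(channels)}
    strength = np.full((n, n), np.nan)
    latency = np.full((n, n), np.nan)
    mask = np.zeros((n, n), dtype=bool)
    for (src, tgt), chunk_fits in fits.items():
        if src == tgt:
            continue
        accepted = [f for f, ok in chunk_fits if ok]
        if not accepted:
            continue
        i, j = idx[src], idx[tgt]
        strength[i, j] = float(np.mean([f.M for f in accepted]))
        latency[i, j] = float(np.mean([f.T_s for f in accepted]))
        mask[i, j] = True
    return ConnectivityMatrix(channels=list(channels), strength=strength, latency=latency, mask=mask)


def connectivity_pipeline(
    tset: SpikeTrainSet,
    chunk_spikes: int = 10_000,
    bin_s: float = 0.0005,
    max_lag_s: float = 0.5,
    snr_factor: float = 2.0,
) -> ConnectivityMatrix:
    """Full connectivity analysis: chunked CFP curves, fits, matrix."""
    curves = chunk_and_average(tset, chunk_spikes=chunk_spikes, bin_s=bin_s, max_lag_s=max_lag_s)
    fits: dict[tuple[str, str], list[tuple[CFPFit, bool]]] = {}
    for pair, curve_list in curves.items():
        entries = []
        for c in curve_list:
            if not np.any(c.probabilities):
                continue
            f = fit_cfp(c)
            entries.append((f, accept_fit(f, c, snr_factor=snr_factor)))
        fits[pair] = entries
    return build_matrix(fits, tset.active_channels())
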
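"""GMM-based spike sorting: feature extraction, two-stage clustering,
cluster-stability traces.

Extracellular electrodes pick up several nearby neurons, so detected spike
waveforms on one channel are a mixture of units.  Candidate features (PC
scores, weighted-PC scores or wavelet coefficients) are ranked by how
multimodal their one-dimensional distributions are — measured with a
per-candidate Gaussian mixture (density peak count, inflection-point count,
distance between the component means) plus the candidate's variance — and
the five highest-ranked features are kept.  Clustering first deliberately
over-fits a Gaussian mixture with many components in that 5-D space, then
fits a second mixture to the stage-1 component centers to merge them; each
waveform is assigned to the merged component with the highest posterior,
and low-confidence spikes are left unsorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

N_FEATURES = 5


@dataclass
class FeatureMatrix:
    features: np.ndarray  # spikes x 5
    method: str
    ranking_scores: np.ndarray  # per-candidate combined score
    selected: np.ndarray  # indices of the retained candidates

    @property
    def n_spikes(self) -> int:
        return self.features.shape[0]


@dataclass
class ClusterModel:
    k: int
    means: np.ndarray  # k x 5 (mu)
    covariances: np.ndarray  # (S)
    weights: np.ndarray  # (alpha)
    assignments: np.ndarray  # per-spike cluster id, -1 = unsorted
    seed: int
    stage1_means: np.ndarray = field(default=None, repr=False)


@dataclass
class StabilityTrace:
    cluster_id: int
    time_bins: np.ndarray  # bin start times (s)
    peak_to_valley_uv: np.ndarray  # NaN where the bin is empty
    firing_rate_hz: np.ndarray


def _candidate_basis(waveforms: np.ndarray, method: str, seed: int) -> np.ndarray:
    n, m = waveforms.shape
    if method == "pca":
        p = PCA(n_components=min(n, m), random_state=seed)
        return p.fit_transform(waveforms)
    if method == "wpca":
        # weight each sample point by its SD across spikes before PCA
        w = waveforms.std(axis=0, ddof=0)
        p = PCA(n_components=min(n, m), random_state=seed)
        return p.fit_transform(waveforms * w)
    if method == "wavelet":
        coeffs = [
            np.concatenate(pywt.wavedec(row, "haar")) for row in waveforms
        ]
        return np.vstack(coeffs)
    raise ValueError(f"unknown feature method {method!r}; use pca, wpca or wavelet")


def _gmm_multimodality_scores(col: np.ndarray, seed: int) -> tuple[float, float, float]:
    """(peak count, inflection count, inter-Gaussian distance) of one candidate.

    A two-component 1-D Gaussian mixture is fitted to the candidate; its
    density is evaluated on a grid to count modes and inflection points, and
    the component separation is |mu1 - mu2| over the pooled sigma.
    """
    x = col.reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=1, reg_covar=1e-9)
    gm.fit(x)
    mu = gm.means_.ravel()
    var = gm.covariances_.ravel()
    lo, hi = col.min(), col.max()
    pad = 0.1 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, 512)
    dens = np.exp(gm.score_samples(grid.reshape(-1, 1)))
    d1 = np.diff(dens)
    peaks = int(np.sum((d1[:-1] > 0) & (d1[1:] <= 0)))
    d2 = np.diff(dens, 2)
    inflections = int(np.sum(np.diff(np.sign(d2)) != 0))
    sep = abs(mu[0] - mu[1]) / np.sqrt(var.mean() + 1e-24)
    return float(peaks), float(inflections), float(sep)


def extract_features(
    waveforms: np.ndarray, method: str = "pca", seed: int = 0
) -> FeatureMatrix:
    """Compute candidate features and retain the five highest ranked.

    The ranking is the sum of the standardized mixture-based scores (peak
    count, inflection count, component separation) and the standardized
    candidate variance.
    """
    waveforms = np.asarray(waveforms, dtype=float)
    if waveforms.ndim != 2 or waveforms.shape[0] < 10:
        raise ValueError("feature extraction needs at least 10 equal-length snippets")
    if np.allclose(waveforms.std(axis=0), 0):
        raise ValueError("degenerate input: identical waveforms have no features")
    cand = _candidate_basis(waveforms, method, seed)
    n_cand = cand.shape[1]
    raw = np.zeros((n_cand, 4))
    for c in range(n_cand):
        col = cand[:, c]
        if col.std() < 1e-12:
            raw[c] = (-np.inf, -np.inf, -np.inf, -np.inf)
            continue
        pk, infl, sep = _gmm_multimodality_scores(col, seed)
        raw[c] = (pk, infl, sep, col.var())
    finite = np.isfinite(raw).all(axis=1)
    z = np.zeros_like(raw)
    for col_idx in range(4):
        v = raw[finite, col_idx]
        mu, sd = v.mean(), v.std()
        z[finite, col_idx] = (v - mu) / sd if sd > 0 else 0.0
    scores = np.where(finite, z.sum(axis=1), -np.inf)
    order = np.argsort(-scores, kind="stable")
    selected = np.sort(order[:N_FEATURES])
    return FeatureMatrix(
        features=cand[:, selected],
        method=method,
        ranking_scores=scores,
        selected=selected,
    )


def cluster(features: FeatureMatrix, k_over: int = 8, seed: int = 0,
            unsorted_posterior: float = 0.5) -> ClusterModel:
    """Two-stage GMM clustering of the selected features.

    Stage 1 over-fits a ``k_over``-component mixture; stage 2 fits a second
    mixture to the stage-1 component centers, choosing its component count
    by BIC over 1..k_over (spherical covariances, ties toward fewer
    clusters).  Spikes are assigned to the stage-2 component with the
    highest posterior; a maximum posterior below ``unsorted_posterior``
    marks the spike unsorted (-1).  Deterministic for a fixed seed.
    """
    X = features.features
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    k_over = min(k_over, X.shape[0])
    stage1 = GaussianMixture(
        n_components=k_over, random_state=seed, n_init=3, reg_covar=1e-6
    )
    stage1.fit(X)
    centers = stage1.means_
    # floor the stage-2 component variance at the typical stage-1 cluster
    # width: centers closer than a real cluster's spread must merge, and no
    # stage-2 Gaussian may collapse onto a single center
    d = X.shape[1]
    within_var = float(
        np.mean([np.trace(np.atleast_2d(c)) / d for c in stage1.covariances_])
    )

    if k_over == 1:
        best = stage1
        k = 1
    else:
        best, best_bic, k = None, np.inf, 1
        for k2 in range(1, k_over + 1):
            if k2 > len(centers):
                break
            gm = GaussianMixture(
                n_components=k2,
                covariance_type="spherical",
                random_state=seed,
                n_init=3,
                reg_covar=within_var,
            )
            try:
                gm.fit(centers)
            except ValueError:
                continue
            bic = gm.bic(centers)
            if bic < best_bic - 1e-9:
                best, best_bic, k = gm, bic, k2
        if best is None:  # degenerate centers: fall back to one cluster
            best = GaussianMixture(1, covariance_type="spherical", random_state=seed)
            best.fit(centers)
            k = 1

    post = best.predict_proba(X)
    top = post.max(axis=1)
    # argmax with ties broken toward the lowest cluster id
    assign = post.argmax(axis=1)
    assign[top < unsorted_posterior] = -1
    cov = best.covariances_
    return ClusterModel(
        k=k,
        means=np.asarray(best.means_),
        covariances=np.asarray(cov),
        weights=np.asarray(best.weights_),
        assignments=assign,
        seed=seed,
        stage1_means=centers,
    )


def stability(
    model: ClusterModel,
    waveforms: np.ndarray,
    times: np.ndarray,
    duration: float,
    bin_s: float = 60.0,
) -> list[StabilityTrace]:
    """Per-cluster stability: binned mean peak-to-valley and firing rate.

    Peak-to-valley is max(waveform) - min(waveform); bins with no spikes of
    a cluster report NaN peak-to-valley and zero rate.
    """
    waveforms = np.asarray(waveforms, dtype=float)
    times = np.asarray(times, dtype=float)
    ptv = waveforms.max(axis=1) - waveforms.min(axis=1)
    n_bins = max(int(np.ceil(duration / bin_s)), 1)
    bin_starts = np.arange(n_bins) * bin_s
    traces = []
    for cid in range(model.k):
        mask = model.assignments == cid
        t_c, ptv_c = times[mask], ptv[mask]
        which = np.minimum((t_c / bin_s).astype(int), n_bins - 1)
        mean_ptv = np.full(n_bins, np.nan)
        rate = np.zeros(n_bins)
        for b in range(n_bins):
            sel = which == b
            width = min(bin_s, duration - bin_starts[b])
            rate[b] = sel.sum() / width if width > 0 else 0.0
            if sel.any():
                mean_ptv[b] = ptv_c[sel].mean()
        traces.append(
            StabilityTrace(
                cluster_id=cid,
                time_bins=bin_starts,
                peak_to_valley_uv=mean_ptv,
                firing_rate_hz=rate,
            )
        )
    return traces
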
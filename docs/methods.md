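# Methods

This note documents the models and procedures `meakit` implements, the
defaults and why they were chosen, the numerical conventions, what the
synthetic-data generators do and do not emulate, and the known limitations.

## Conventions

All times are seconds (float64), voltages microvolts, channel labels are the
display strings, channel/well indices are 0-based internally. Comparison
conventions are fixed once and used everywhere: threshold exceedance is
strict (`>`), the activity gate is inclusive (`≥ 0.1 Hz`), and ISI
comparisons in the burst detectors are inclusive (`≤`).

## Spike detection

Traces are high-pass filtered with a Butterworth design (cutoff 200 Hz,
order 2) applied forward-backward (`sosfiltfilt`), so filtering is
zero-phase and spike timing is preserved; the squared magnitude response is
the price, which is irrelevant far from the corner.

Baseline noise is estimated per channel from the filtered trace. The trace
is split into non-overlapping 50-ms windows and each window's Gaussian σ is
estimated by its sample SD (the maximum-likelihood estimator — an explicit
histogram fit adds machinery, not information). Windows whose SD falls
below the channel's median window SD count as "pure noise", and the first
two disjoint runs of such windows lasting at least 2 s become the baseline
spans; one span suffices, and a channel with none is excluded as too noisy.
The spike threshold is 5 × RMS over the pooled span samples (pooling is
equivalent to averaging the spans' power).

One tolerance is needed to make this operational: the SD *estimate* of a
500-sample window fluctuates with a relative standard error of
1/√(2·500) ≈ 3.2 %, so on stationary noise each window falls below the
median with probability ≈ ½ and a 40-window all-sub-median run essentially
never occurs — the rule read literally discards every channel, including
noise-only ones. The sub-median test therefore uses
`SD < sub_median_tolerance × median` with `sub_median_tolerance = 1.1`
(≈ 3 standard errors). Spike-contaminated 50-ms windows have SDs at roughly
twice the median or more, so their classification is unaffected;
`sub_median_tolerance = 1.0` restores the strict rule.

Detection takes local extrema of either polarity whose |value| strictly
exceeds the threshold; the spike time is the extremum sample (stable
latencies for connectivity), and a ±1-ms snippet is kept per spike.
Candidates nearer than the (default 0 ms) dead time collapse to the larger
one, and sub-minimum-amplitude candidates (default 0 µV) are dropped.

Artifact rejection keeps a spike iff, within the ±1-ms window: (1) its
extremum is the unique largest |value|; (2) no other local extremum has a
*prominence* above 50 % of the spike amplitude — prominence rather than raw
|value| because noise ripples riding on the flank of a wide lobe have
near-peak values but negligible prominence, and prominence is measured on
|v(t)| so a rebound lobe adjacent to a deep trough is not credited with the
trough's depth; (3) the waveform returns below 50 % of the amplitude on each
side of the extremum inside the window (the "more than half of the
amplitude falls within the window" condition), which rejects slow drift
bumps; the side-minimum form rather than the literal edge sample is used
because a single noise sample at the window edge should not veto a clean
spike. This combination removes both sub-threshold rebound detections (they
fail uniqueness) and genuine double-peak artifacts.

Channels firing below 0.1 Hz are flagged inactive and excluded from every
downstream burst, network, connectivity, and endpoint computation.

## Burst detection

**Max-interval.** Five parameters: start interval 0.05 s, minimum spike
count 3, inter-burst interval 0.1 s, intra-burst interval 0.1 s, minimum
duration 0.03 s. A greedy left-to-right scan opens a seed when two
consecutive spikes are within the start interval and extends it while ISIs
stay within the intra-burst interval; count/duration filters apply to seeds
first, then qualifying bursts closer than the inter-burst interval merge
(filter-then-merge, matching the order in which the rules are stated;
spikes falling in a merged gap are included). The default minimum spike
count is 3 — the value the burst-detection description states — although
the parameter-summary listing prints 4; the parameter is configurable.

**logISI.** The histogram of log₁₀(ISI) uses 0.1-decade bins (padded one
bin each side so boundary peaks are detectable) smoothed with a 3-bin
moving average; peaks are local maxima at least 5 % of the tallest bin
(plateau-aware). Scanning peak pairs in order, the void statistic at the
inter-peak minimum, `void = (1 − h_min/√(h_peak1·h_peak2)) × 100`, is
compared with the 70 % threshold; the first qualifying valley's ISI becomes
the intra-burst cutoff, and runs of ≥ 3 spikes with ISIs ≤ cutoff become
bursts. Fewer than two peaks, or no deep-enough valley, yields no bursts.

## Network bursts

Sorting all SCB first-spike times, a maximal run with consecutive gaps
≤ 0.1 s spanning ≥ 2 distinct channels seeds a synchronized burst (the
sliding-window pairwise rule is not transitive; the sorted-run reading is
deterministic and order-independent). The span runs from the earliest to
the latest member spike; any SCB whose first spike falls inside the span is
absorbed, iterating to a fixpoint because absorption can extend the span
(a single-pass variant is available via `absorb_to_fixpoint=false`).
Overlapping candidates merge, participation is re-checked jointly on the
merged membership, and candidates with fewer than 25 % of the active
channels participating are removed; a channel counts once regardless of how
many of its SCBs are members. NB inter-burst intervals are
`start_{k+1} − end_k` and their CV uses the sample SD (the convention under
which the documented worked values hold).

## Connectivity (conditional firing probability)

For an ordered pair (i, j), each source spike contributes the target spikes
at lags 0 < τ ≤ 500 ms to 0.5-ms bins (bin index ⌊τ/0.0005⌋, τ = 0
coincidences excluded); bin counts divide by the source spike count. The
recording is split into chunks of 10,000 array-wide spikes (the chunking
mechanism follows the fixed-spike-count convention of the CFP literature;
the trailing partial chunk is kept iff at least half full, and fewer spikes
than half a chunk fall back to a single chunk).

Each nonzero curve is fitted with `M/(1+((τ−T)/w)²) + offset` by
Nelder–Mead MSE minimization, multistarted from T₀ = argmax bin center,
M₀ = max − median, offset₀ = median, w₀ ∈ {2, 10, 50} ms; the best simplex
result seeds one tightened Nelder–Mead restart (budget: 4,000 iterations,
xatol 1e-10/1e-12, fatol 1e-14/1e-16). A fit is accepted as a connection iff
the peak is inside the lag range, physically plausible (M + offset ≤ 1,
since CFP values are probabilities, and w at least one bin wide — a
sub-bin-width peak is an unidentifiable single-bin artifact), and
M > 2 × the SD of the bins outside T ± 5w (the uncorrelated background).
The acceptance rule is a documented stand-in — the original tool does not
state one — and every piece of it is configurable. Strength and latency
matrices average M and T over accepted chunk fits; the diagonal is excluded
and a top-k helper supports the "strongest connections" display.

## ISI-distance synchrony

At time t, each train's instantaneous ISI is (first spike > t) − (last
spike ≤ t). The profile I(t) equals iISI⁽ˣ⁾/iISI⁽ʸ⁾ − 1 when
iISI⁽ˣ⁾ ≤ iISI⁽ʸ⁾ and −(iISI⁽ʸ⁾/iISI⁽ˣ⁾ − 1) otherwise, hence lies in
[−1, 1], is 0 for equally fast trains and negative when the first train is
faster. Both the temporal average of |I| (the mean ISI distance) and the
signed average (direction) are reported, reconciling the averaged-|I|
definition with the signed interpretation. I(t) is piecewise constant
between spikes, so alongside the default uniform 1-ms grid an exact
breakpoint integration is provided and used as the oracle in tests. The
evaluation grid is restricted to the common interior span of the two
trains, where both instantaneous ISIs are defined.

## Spike sorting

Candidate features are full PCA scores, weighted-PCA scores (each waveform
sample weighted by its SD across spikes before the PCA), or Haar wavelet
coefficients (full-depth decomposition). Each candidate's 1-D distribution
is scored by a 2-component Gaussian mixture: density peak count, density
inflection-point count, and inter-component separation |μ₁−μ₂|/σ̄, plus the
mixture-independent candidate variance; the ranking is the sum of the four
standardized scores (the exact combination rule is not published — this is
a documented stand-in) and the top five candidates are retained.

Clustering over-fits a GMM with `k_over = 8` components, then fits a second
GMM to the stage-1 component centers, selecting its component count by BIC
over 1..k_over with spherical covariances floored at the mean within-
component variance of stage 1 — the floor is what makes merging work:
centers closer together than a real cluster's spread cannot each claim a
degenerate delta component, so they merge. Spikes are assigned to the
stage-2 component with the highest posterior (ties to the lowest id);
a maximum posterior below 0.5 marks the spike unsorted. Everything is
deterministic for a fixed seed. Cluster stability is summarized per 60-s
bin as mean peak-to-valley amplitude (max − min of the waveform) and firing
rate.

## Synthetic data

The generators produce what the analysis assumes: i.i.d. Gaussian baseline
noise of per-channel σ (default 10 µV; the detection studies use 5 µV),
biphasic spike templates (1-ms negative half-sine then 0.5-ms positive
rebound at 20 % of the peak — a typical extracellular shape whose filtered
rebound stays clear of the 50 % secondary-peak bound), Poisson or
burst-structured firing, array-wide synchronized bursts at shared onsets
with ~10-ms jitter, directed couplings that copy source spikes to a target
with a fixed latency, 1-ms Gaussian jitter and a transmission probability,
and multi-unit channels mixing ≥ 2 templates. Every generator returns its
ground truth (burst membership, NB windows, coupling table, injected times
and unit labels), and everything is deterministic per seed.

What the generators do **not** emulate — and hence what passing tests do
not demonstrate about real recordings: 1/f and line noise, electrode drift
and amplitude nonstationarity, overlapping spikes from correlated units,
bursts with decelerating ISIs, LFP contamination, and stimulation
artifacts. Study scales were chosen to exercise the full pipeline at
desk-test sizes: 60-s single-channel traces at 10 kHz for detection
(≈ 0.4 Hz firing, i.e. ~24 spikes — sparse enough that 2-s spike-free
stretches exist, as the noise estimator requires), 120-s 8-channel sets for
connectivity, 500–1,500-spike waveform sets for sorting, and 12–30-s
multiwell plates for the end-to-end CLI checks.

## Degenerate inputs and edge cases

Empty trains are legal everywhere downstream of detection; statistics whose
preconditions fail (ISI metrics below 2 spikes, burst means with no bursts,
NB IBI with < 2 NBs, CV with < 3) are reported as missing (NaN, empty CSV
cells) rather than zero. All-zero CFP curves raise and the pair is recorded
unconnected. Identical waveforms (zero variance) are rejected by feature
extraction. Fixture CSV/HDF5 round-trips are bit-exact for the stored
numeric type.

## Limitations

The HDF5 schema is this package's own documented layout, not the
proprietary converter output it is shaped after; vendor binary formats are
out of scope. The endpoint list covers every metric the accompanying
documentation names and totals exactly 20, but naming follows this package.
Excel export is replaced by CSV. Interactive visualization (rasters,
heatmaps, animations) is out of scope; all outputs are tabular.
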
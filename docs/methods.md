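# Methods

This note documents the models, statistics and numerical choices behind
`spikenet`, the defaults that matter, and what the synthetic-data
generators do and do not emulate.

## Data model and binning

The universal input is a set of parallel spike trains with trial structure
(conditions: instructed/free-choice × power/precision grip) and two task
events per trial (cue onset, movement onset).  Analysis runs on two
event-aligned segments binned at 1 kHz: cue [−700, 1500) ms (2200 bins)
and movement [−300, 500) ms (800 bins), chosen because activity locks to
both events with a variable delay period in between.  Bins are half-open
[t, t+1); multiple spikes in one millisecond are clipped to 1 because the
correlogram arithmetic treats the binned train as a spike indicator (clip
events are counted and logged).  Trials missing either event are excluded
with a warning.  The two segments may overlap in short trials; they are
processed independently and spikes are not deduplicated across segments.

Epoch windows for rate summaries: fixation [−700, 0), cue [0, 300),
memory [300, 1500) on the cue segment, and the movement segment.

## Correlograms (cch.py)

CCH_ab(τ) = Σᵢ Σₜ x_a,i(t)·x_b,i(t+τ) / (M·(N−|τ|)·√(λ_a λ_b)), lags
±500 ms.  Notes on conventions:

* The denominator uses the geometric mean rate √(λ_a λ_b) (spikes/bin);
  this renders the one-trial, one-coincidence case exactly 1 coincidence
  per spike, and the zero-lag autocorrelogram exactly 1 for any rate.
* Histograms are computed per (condition, segment) group — λ is estimated
  within the group — and averaged, unweighted, across groups in which both
  units fired; groups where either unit is silent contribute nothing.
* The trial average 1/M is applied to the per-group sum; with a common
  within-group denominator the two possible placements coincide.
* Production counting runs over sparse sorted spike lists (numba); an
  independent dense-FFT route exists and the two agree to 1e-10.

Surrogate ensemble: for every unit, trial and replicate (default R = 1000;
configurable), an artificial spike train is drawn from an inhomogeneous
Poisson process using the unit's smoothed PSTH (per condition and segment)
as rate function, preserving the exact per-trial spike count.  Because all
units' counts are preserved simultaneously, trial-wise co-fluctuation and
event-locked rate structure survive into the surrogates and are removed by
the correction; precise pairwise timing is destroyed.  Draws that would
put two surrogate spikes into one millisecond are redrawn, so surrogate
trains are binary like the clipped real rasters — without this, surrogate
coincidence statistics are slightly inflated at small lags and the
spectrum cluster test becomes anticonservative.

Correction: corrected = raw − ensemble mean; every surrogate member is
corrected by the same mean (an "equally processed set") and everything is
smoothed with a Gaussian kernel, SD 3.66 ms (reflecting boundaries, so
histogram mass is conserved).  Smoothing precedes z-scoring.

## Cluster statistics and network construction (cluster.py, connectivity.py)

z(τ) = corrected(τ)/SD(τ) with the per-lag SD of the corrected smoothed
members (zero-SD lags masked).  Lags inside the ±200 ms test window with
|z| ≥ 2 form clusters by temporal adjacency, split at sign changes
(mixed-sign runs would cancel the accumulated statistic); the cluster
statistic is the accumulated z.  Each member contributes its largest
|cluster|; the two pair orderings are pooled into a 2R-value null (they
are time reversals of the same draws, so this duplicates R distinct
values and leaves p-values unchanged).  The cluster p-value is the plain
empirical fraction of the null at or above |stat| — a cluster larger than
every chance cluster gets p = 0, which keeps the subsequent
Benjamini–Hochberg step (q = 0.05, m = all clusters of all pairs of the
dataset) operable at moderate surrogate counts.

Direction rule: clusters only at positive (negative) lags → unidirectional
reference→target (target→reference); clusters on both sides or straddling
zero → the unsigned maximum of the corrected CCH decides, bidirectional
when it lies within 2 ms of zero (threshold configurable; sweeping it
0–5 ms leaves the connection set untouched and directional calls largely
stable).  Bidirectional edges set both adjacency entries.  Units outside
the largest weakly connected component are dropped (fraction reported)
before topology.

## Graph topology (topology.py)

Degree counts distinct connected partners (a bidirectional pair is one
partner), matching the undirected form of the rich-club count; path-based
measures (L, betweenness) run on the directed adjacency; clustering uses
the undirected skeleton.  L averages over reachable ordered pairs.  All
measures equal brute-force enumeration on graphs ≤ 8 nodes (tested).

Surrogate network ensembles (1000 members, rejection-sampled until
connected): *distance-preserving* — per distance group (same electrode /
same array / same area / each area pair) the connection count and the
bi-/unidirectional ratio are held constant while connected pairs are
redrawn; *degree-preserving* — connected double-edge swaps on the
skeleton.  A physical-distance grouping variant (3.6 mm bins, separate
maximum-distance group for area pairs whose Euclidean distance is
misleading) is available and agrees closely with the categorical grouping
on fixtures.

SW = (C/C̄rand)/(L/L̄rand) against the distance-preserving ensemble means
(a configuration-model null is available by config).  Modularity uses
greedy multi-level (Louvain) optimization, best of 100 seeded restarts,
with Q always re-evaluated exactly as Q = Σᵤ(eᵤᵤ − (Σᵥeᵤᵥ)²) on the
returned partition.  Rich club R(k) = 2E₍≥k₎/(N₍≥k₎(N₍≥k₎−1)), evaluated
only where at least 5 nodes qualify, normalized by the degree-preserving
ensemble mean, with cluster-based permutation significance across k.

Degree/betweenness distributions are binned, normalized to 100% area
(as plotted), averaged across datasets, and fitted by least squares with
four models: PL A·k^(−γ), EXP A·e^(−k/kc), EXPTPL A·k^(γ−1)·e^(−k/kc)
(the truncation exponent is negative — a positive exponent cannot produce
a decaying tail), GAUS; ranked by adjusted R².  Fitting the plotted
distribution rather than maximum likelihood on raw samples matches the
adjusted-R² model comparison the analysis is built around.

Hubs: normalized degree ≥ 9% of possible partners AND betweenness ≥ 0.03.
The conjunction is the default because the canonical test cases (a star's
center qualifies on both criteria while a large ring has no hubs despite
sizeable ring-node betweenness) are only consistent with it; the OR rule
is available via `hub_rule`.

## Spectra (spectra.py)

Power at 100 log-spaced frequencies (3–100 Hz) from frequency-matched
Hanning-windowed DFTs aligned on lag 0 — per-frequency windows because
physiological oscillations are not phase-stable, so the informative number
of correlogram side lobes scales with frequency.  CCH windows span four
periods (clipped to [150, 1000] ms, centered); ACH windows span two
periods (clipped to [75, 500] ms) over the non-negative lags with a
half-Hanning taper falling to zero at the window end, power doubled to
account for ACH evenness; every bin is divided by its window length.
CCHs have the ±5 ms range excised and linearly interpolated (between the
−6 and +6 ms bins) before the transform so sharp near-zero peaks do not
leak broadband power.  Significance re-uses the cluster machinery over
frequency bins (surrogate-member spectra provide mean, SD and the
largest-cluster null; α = 0.05 per histogram).  A unit is a beta / low /
both / none oscillator according to the significant bands of its ACH
spectrum; a threshold-based alternative classification is calibrated to
produce the same oscillator counts per band.

Oscillatory-state split: per-trial population ACHs (pooled spike counts of
all units, Eq-style normalization per trial, zero-lag self-count replaced
by its neighbours' mean) are summarized by mean beta+low band power;
trials are median-split within each condition (equal counts per condition
per block, odd trial dropped at random, seeded).  The caller re-runs
detection and topology per block; ≥ ~900 trials are recommended for
stable topology, enforced as a warning.

## Firing-rate prediction (prediction.py)

Inputs are the units with a significant edge into the target; each input's
binned train is convolved with the (0, +200] ms output part of the
corrected input→target CCH (the significance window; nothing is fitted),
contributions summed, and the result correlated (Pearson, 1 ms bins,
trial-concatenated segments) with the target's train smoothed with the
same SD 3.66 ms Gaussian.  Three permutation nulls, each catching a
distinct confound: trial shuffling (event-locked co-modulation; inputs
permuted jointly to preserve input–input correlations), kernel shuffling
among the target's inputs (kernel-unspecific signal; a single-input
target draws donor kernels from other pairs), input-unit replacement by
random non-connected units (network-unspecific signal).  A prediction is
significant only if it beats all applicable nulls at p < 0.05.
Condition-averaged rate curves (additional 40 ms smoothing for reporting)
are tested against the kernel- and input-shuffle nulls only.

## Ground-truth simulators (simulate.py)

**Equal-rate model.**  n neurons (default 100), per-neuron target rates
drawn log-normal — median 5 spikes/s, σ_log = 1 (≈ two decades of spread,
clipped to [0.3, 60] Hz), emulating recorded rate distributions; the
generator parameters are fixed, not per-dataset estimates.  Each directed
edge carries a gamma transfer kernel f(t|a,b) with a = 5, b ~ U(0, 3],
sampled at integer lags from t+1 ms (axonal delay), truncated at 1e-6
remaining mass and renormalized to integral 0.02 (the connection
strength; a 20 ms boxcar is selectable).  The network updates every
millisecond: each neuron fires Bernoulli(base + pending injected
probability, capped at 1), and every spike adds its kernels to the
targets' pending probability, allowing multi-step interactions.  Because
injection raises rates, base rates are deflated iteratively (per-unit
multiplicative correction, estimated on 120 calibration trials) until the
realized mean rate is within 0.5% of target (the printed criterion is a
correlation-residual phrasing; the mean-rate reading is implemented and
the target-vs-realized correlation is reported, typically > 0.99).
Default trial structure: 600 trials × 3.1 s with cue onset at 700 ms and
movement onset at 2600 ms, so both analysis segments are covered.

Topologies: SN draws out-connection counts Gaussian (mean 5.22,
SD 3.214, rounded, clipped at 0) with uniform targets; CN samples a
partner-degree sequence from EXPTPL (γ = 0.6839, kc = 8.657), wires it
richest-first (Havel–Hakimi, which interconnects hubs and clusters their
neighbourhoods), then relaxes 30% of edges by connected double-edge swaps
so the rich club stays weak; undirected connections become bidirectional
with the probability a mutual SN connection arises by chance (≈ 5.22/(n−1)),
otherwise randomly oriented.  Realized checks, not the construction, are
the contract: SN degree distributions fit Gaussian best, CN fit EXPTPL
best with normalized rich club > 1 over the top-degree quintile and a
small-world coefficient well above 1.

Detection scoring: ordered-pair confusion counts (directed), unordered
connection counts (undirected), and direction-given-detection over the
ordered pairings of detected connections — the true direction scores a
hit when the detection includes it (also within a bidirectional call),
the absent reverse of a unidirectional truth scores CR/FA.  For
truth-bidirectional and common-drive pairs (unconnected pairs sharing a
presynaptic input) the per-lag-SD-normalized CCH profiles are averaged
per group and the group-average maximum reported, plus zero-lag
maximum-peak counts (group-size normalized; Haldane–Anscombe +0.5 keeps
the fold ratio finite).

**Subsampling plane.**  2 areas × 5 array sub-regions × 160 electrode
positions × 20 neurons = 32,000 neurons; Bernoulli connectivity by
distance group with the reference densities (same electrode 56.7%, same
array 11.5%, same area 5.6%, inter-area 3.27% = mean of the three printed
area-pair densities, all scalable).  Adjacency is realized lazily per
requested node subset, so the full plane is never stored; subsamples
follow the recording configuration (both areas, 2 sub-regions per area,
32 electrode positions each).  The density sweep (×1/5 … ×5) reports the
power-law fit quality of subsampled degree distributions against the
plane's largest-component fraction and compartmentalization (P−1)/(N−1).
Component-level statistics at reduced plane scale (per_electrode < 20)
keep the same densities; the printed full-plane mean degree (~3000) is
not treated as a target since it is not reproducible from the printed
group densities.

**Oscillatory / non-oscillatory pairs.**  600 trials × 3.1 s.  Both units
draw spikes from a shared per-trial probability trace plus independent
Poisson background (0.5 Hz): oscillatory — a 20 Hz sinusoid with random
phase per trial, scaled so the total mean rate is ≈ 5 Hz (peak
probability 0.009/ms; a plain sinusoid cannot have a 0.05 peak and a 5 Hz
mean simultaneously, and the rate is the constraint that matters for the
sensitivity comparison); non-oscillatory — the same trace randomized in
time, low-passed at 50 Hz (4th-order Butterworth, non-causal) and
iteratively variance- and mean-matched after clipping at zero.  Unit 2's
trace is shifted by a per-trial offset uniform in ±jitter ms, so the
jitter alone sets coupling strength.  Peak heights are compared on the
unsmoothed surrogate-corrected CCH within ±25 ms: smoothing penalizes the
narrower non-oscillatory peak shape and the multi-lobed oscillatory CCH
biases a wide-window maximum, so this window isolates the matched
quantity.

## What the generators do not emulate

Simulated units carry no waveforms, no refractory periods, no
condition-specific tuning (PSTHs are flat in expectation), a single
pseudo-area without electrode geometry (equal-rate model), and purely
probabilistic rate injection rather than membrane dynamics.  Passing
tests therefore demonstrate correctness of the estimation machinery and
recoverability of designed network structure under realistic rates,
trial counts and connection strengths — not robustness to sorting
artifacts, non-stationarity, or biophysical dynamics.

## Problem sizes and determinism

Unit tests run reduced configurations (n = 30 networks, 150 trials,
60–80 surrogates); the acceptance script uses 3 networks per kind at
n = 50, 600 trials and R = 200 surrogates, which reproduces the benchmark
regime in about 12 minutes on one CPU.  All randomness flows from a
single seed through `numpy.random.Generator`; reruns are bit-identical.
Known limitations: empirical cluster p-values saturate at 0 (bounded
below only by the member count); the modularity optimizer is stochastic
with restarts, so Q is a lower bound on the optimum; surrogate network
generation can reject heavily on very fragile graphs (it aborts with a
diagnostic below 0.1% acceptance).
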
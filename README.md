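# spikenet

Functional network analysis for populations of simultaneously recorded
single neurons.  Given trial-structured parallel spike trains, `spikenet`
estimates which neurons functionally influence which others, characterizes
the topology of the resulting directed network (modularity, small-world
structure, hubs, rich club), classifies oscillatory synchrony in the beta
(18–35 Hz) and low (3–7 Hz) frequency bands, and predicts single-neuron
firing from the detected inputs.  Three ground-truth spiking simulators
make every stage testable end to end without any recorded data.

## The method

Connectivity is estimated from normalized cross-correlation histograms.
For units *a* and *b* with binary 1 ms spike trains *x* over M trials of N
bins,

    CCH_ab(τ) = Σᵢ Σₜ x_a,i(t) · x_b,i(t+τ) / ( M · (N−|τ|) · √(λ_a λ_b) )

in coincidences per spike, with λ the mean rates in spikes/bin.  A peak at
positive lag τ means *b* fires after *a* (an *a → b* influence).  Rate- and
event-locked correlation (common stimulus drive, trial-wise excitability)
is removed by subtracting the mean of 1000 surrogate CCHs built from
inhomogeneous-Poisson spike trains that keep each unit's PSTH and exact
per-trial spike counts but destroy precise pairwise timing.

Significance uses a cluster-based surrogate test: lags inside ±200 ms with
|z| ≥ 2 (z-scored by the per-lag surrogate SD) form contiguous same-sign
clusters whose accumulated z is compared against the largest chance
clusters of the surrogate ensemble; Benjamini–Hochberg FDR (q = 0.05)
across all clusters of all pairs controls the network-wide error.
Significant pairs become directed edges (positive-lag structure → a → b;
peaks within 2 ms of zero → bidirectional).  Graph measures (degree,
betweenness, clustering, path length, modularity Q, small-worldness SW,
rich-club R(k)) are tested against distance-preserving and
degree-preserving shuffled-network ensembles, oscillators are classified
from windowed Fourier spectra of auto-correlograms, and firing rates are
predicted by convolving input spike trains with the output parts of their
corrected CCHs (no fitted parameters; three permutation controls).

The simulators generate (i) equal-rate model networks — probabilistic
spiking networks with log-normal rates and gamma-kernel spike injection,
in a simple (Gaussian-degree) and a complex (truncated-power-law degree,
rich-club, small-world) variant, (ii) a 32,000-neuron two-area plane with
distance-dependent random connectivity for subsampling controls, and
(iii) oscillatory/non-oscillatory synchronized pairs with a jitter-
controlled coupling strength.

## Worked example

```python
import numpy as np
from spikenet import FunctionalConnectivityModel, RunConfig
from spikenet import simulate as sim

rng = np.random.default_rng(0)
net = sim.build_topology("CN", n=30, rng=rng)          # ground-truth network
net = sim.simulate_equal_rate(net, rng, n_trials=150)  # spiking dataset

model = FunctionalConnectivityModel(net.dataset, RunConfig())
res = model.fit(seed=1, n_surrogates=60, n_network_surrogates=100)
print(res.summary())
```

prints:

```
Functional network fit
======================================================
units: 30   trials: 150   spikes: 108432
significant connections: 36 (6 bidirectional)
largest component: 21/30 units (30.0% dropped)
density: 14.76%   C = 0.106 (p=0.97)   L = 2.604 (p=0.238)
small-world SW = 1.27 (p=0.594)   modularity Q = 0.401 (p=0.317, 4 modules)
hubs: 6/21 (degree-betweenness Spearman r=0.79, p=2.37e-05)
rich club: max normalized R = 1.31 (significant)
module area dominance: 100.0% (p=1)
```

Reading: 36 of the 435 possible pairings carry a significant timing
relationship; the largest connected component keeps 21 units at 14.8%
connection density.  At this deliberately small scale (30 neurons, 150
trials, 60 surrogates) the clustering and path-length contrasts against
the shuffled-network null are not individually significant, but the
degree–betweenness correlation (r = 0.79) and the significant normalized
rich-club excess (1.31) already recover the hub structure the CN
generator wired in; area dominance is trivially 100% because simulated
units share one pseudo-area.  `res.detection.edge_table()` gives the
directed edge list, `res.topology.node_table()` the per-unit
centralities, and `sim.score_detection(net, res.detection.adjacency(),
res.detection)` scores the fit against the generating truth.

A thin CLI covers simulation and end-to-end runs on TSV datasets:

```bash
spikenet simulate --kind cn --n 50 --trials 600 --seed 7 --out sim/
spikenet run sim/cn_00_spikes.tsv sim/cn_00_trials.tsv sim/cn_00_units.tsv \
    --seed 1 --out run/
```

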
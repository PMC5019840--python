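"""Ground-truth spiking-network simulators and the detection scoring harness.

Three generative models make every pipeline stage testable without recorded
data:

* **equal-rate model** -- directed networks of Poisson neurons whose
  log-normal base rates are iteratively deflated so that the network rates
  match the drawn targets; a presynaptic spike injects extra spike
  probability into its targets through a gamma transfer kernel
  ``f(t | a, b) = t^(a-1) e^(-t/b) / (b^a Gamma(a))`` sampled from t+1 ms
  (axonal delay) and normalized to a fixed integral (connection strength,
  default 0.02).  Two wiring kinds: SN (simple; Gaussian out-connection
  counts, mean 5.22, SD 3.214) and CN (complex; partner-degree sequence
  following the exponentially truncated power law gamma = 0.6839,
  kc = 8.657, with rich-club and small-world wiring).

* **subsampling plane** -- a two-area sheet of 32,000 neurons (5 array
  sub-regions per area, 160 electrode positions each, 20 neurons per
  electrode) with Poisson-distributed, distance-group-dependent
  connectivity; used to test whether electrode-style subsampling distorts
  the degree distribution.

* **oscillatory / non-oscillatory pair model** -- two neurons sharing a
  per-trial probability trace (a 20 Hz sinusoid, or its randomized,
  50 Hz-low-passed, variance-matched counterpart) plus independent Poisson
  background, with a per-trial timing jitter controlling coupling strength.

Signal-detection scoring (hits / misses / correct rejections / false
alarms, direction accuracy, common-drive statistics) compares a detected
network against the generating truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit
from scipy.signal import butter, filtfilt
from scipy.special import gamma as gamma_fn

from .config import RunConfig, DEFAULT_CONFIG
from .data import CONDITIONS, SpikeDataset

log = logging.getLogger(__name__)

# printed distance-group connection densities (fraction), nearest first:
# same electrode, same array, same area, and the three inter-area pairs
GROUP_DENSITIES = {
    "same_electrode": 0.567,
    "same_array": 0.115,
    "same_area": 0.056,
    "AIP-F5": 0.055,
    "F5-M1": 0.026,
    "AIP-M1": 0.017,
}
# mean of the three printed inter-area densities, for the two-area plane
INTER_AREA_DENSITY = (0.055 + 0.026 + 0.017) / 3.0

EXPTPL_GAMMA = 0.6839
EXPTPL_KC = 8.657
SN_OUT_MEAN = 5.22
SN_OUT_SD = 3.214

TRIAL_LENGTH_MS = 3100
CUE_ONSET_MS = 700.0
MOVEMENT_ONSET_MS = 2600.0


# -- transfer kernels ----------------------------------------------------

def gamma_kernel(b: float, a: float = 5.0, integral: float = 0.02,
                 tol: float = 1e-6) -> np.ndarray:
    """Discrete gamma transfer kernel over lags t = 1, 2, ... ms.

    The density is evaluated at integer lags starting one bin after the
    presynaptic spike (axonal delay), truncated once the remaining mass
    falls below ``tol`` of the total, and renormalized so the kernel sums
    to ``integral`` (the connection strength)."""
    if b <= 0:
        raise ValueError("b must be positive")
    # generous upper bound on support: mean + 10 SD
    t_max = int(np.ceil(a * b + 10.0 * np.sqrt(a) * b)) + 2
    t = np.arange(1, t_max + 1, dtype=float)
    dens = t ** (a - 1.0) * np.exp(-t / b) / (b ** a * gamma_fn(a))
    csum = np.cumsum(dens)
    total = csum[-1]
    keep = csum <= (1.0 - tol) * total
    n = max(int(keep.sum()) + 1, 1)
    dens = dens[:n]
    return integral * dens / dens.sum()


def boxcar_kernel(length_ms: int = 20, integral: float = 0.02) -> np.ndarray:
    """Flat alternative transfer kernel."""
    return np.full(length_ms, integral / length_ms)


# -- topologies ----------------------------------------------------------

@dataclass
class GroundTruthNetwork:
    """A simulated directed network and (optionally) its spike output."""

    label: str                     # "SN" | "CN"
    adjacency: np.ndarray          # boolean, adjacency[i, j]: i -> j
    kernels: dict                  # (i, j) -> kernel array
    target_rates: np.ndarray       # spikes/ms per neuron
    base_rates: np.ndarray | None = None
    dataset: SpikeDataset | None = None
    realized_rates: np.ndarray | None = None
    rate_correlation: float = np.nan

    @property
    def n(self):
        return self.adjacency.shape[0]

    def connected_pairs(self) -> np.ndarray:
        """Boolean matrix of unordered connections (either direction)."""
        return self.adjacency | self.adjacency.T

    def bidirectional_pairs(self) -> list[tuple[int, int]]:
        mut = self.adjacency & self.adjacency.T
        return [(i, j) for i, j in zip(*np.nonzero(np.triu(mut, 1)))]

    def common_drive_pairs(self) -> list[tuple[int, int]]:
        """Unconnected pairs sharing at least one presynaptic input."""
        a = self.adjacency
        shared = (a.T.astype(np.int32) @ a.astype(np.int32)) > 0
        unconnected = ~(a | a.T)
        np.fill_diagonal(unconnected, False)
        mask = shared & unconnected
        return [(i, j) for i, j in zip(*np.nonzero(np.triu(mask, 1)))]


def exptpl_degree_sequence(n: int, rng: np.random.Generator,
                           gamma: float = EXPTPL_GAMMA, kc: float = EXPTPL_KC,
                           k_max: int | None = None) -> np.ndarray:
    """Sample a partner-degree sequence from the EXPTPL distribution
    P(k) ~ k^(gamma-1) e^(-k/kc) over k = 1..k_max."""
    k_max = k_max or min(n - 1, 40)
    k = np.arange(1, k_max + 1, dtype=float)
    p = k ** (gamma - 1.0) * np.exp(-k / kc)
    p /= p.sum()
    for _ in range(200):
        deg = rng.choice(np.arange(1, k_max + 1), size=n, p=p)
        if deg.sum() % 2 == 1:
            deg[rng.integers(n)] += 1 if deg.min() > 1 else -1
        if nx.is_graphical(sorted(deg)):
            return np.sort(deg)[::-1]
    raise RuntimeError("could not realize an EXPTPL degree sequence")


def build_topology(kind: str, n: int = 100,
                   rng: np.random.Generator | None = None,
                   bidirectional_prob: float | None = None,
                   rewire_fraction: float = 0.3,
                   out_mean: float = SN_OUT_MEAN,
                   out_sd: float = SN_OUT_SD) -> GroundTruthNetwork:
    """Ground-truth adjacency for the two network kinds.

    SN: Gaussian out-connection counts (mean 5.22, SD 3.214, rounded,
    clipped at 0), targets uniform.  CN: partner-degree sequence from the
    EXPTPL model wired greedily richest-first (which interconnects hubs,
    producing the rich-club and locally clustered small-world structure),
    then relaxed by degree-preserving connected double-edge swaps on a
    ``rewire_fraction`` of edges so the rich-club stays weak; undirected
    connections become bidirectional with the same probability a mutual
    SN connection arises by chance, else a random orientation.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n < 20:
        raise ValueError("need n >= 20")
    adj = np.zeros((n, n), dtype=bool)
    if kind == "SN":
        n_out = np.clip(np.round(rng.normal(out_mean, out_sd, size=n)),
                        0, n - 1).astype(int)
        for i in range(n):
            if n_out[i] == 0:
                continue
            targets = rng.choice(np.delete(np.arange(n), i), size=n_out[i],
                                 replace=False)
            adj[i, targets] = True
    elif kind == "CN":
        if bidirectional_prob is None:
            bidirectional_prob = SN_OUT_MEAN / (n - 1)
        deg = exptpl_degree_sequence(n, rng)
        g = nx.havel_hakimi_graph([int(d) for d in deg])
        if not nx.is_connected(g):
            # attach stray components to the main hub without changing the
            # heavy tail noticeably
            comps = sorted(nx.connected_components(g), key=len, reverse=True)
            hub = max(g.degree, key=lambda kv: kv[1])[0]
            for comp in comps[1:]:
                g.add_edge(hub, next(iter(comp)))
        nswap = int(rewire_fraction * g.number_of_edges())
        if nswap:
            nx.connected_double_edge_swap(g, nswap=nswap,
                                          seed=int(rng.integers(2**31)))
        for u, v in g.edges:
            if rng.random() < bidirectional_prob:
                adj[u, v] = adj[v, u] = True
            elif rng.random() < 0.5:
                adj[u, v] = True
            else:
                adj[v, u] = True
    else:
        raise ValueError(f"unknown network kind {kind!r}")
    return GroundTruthNetwork(kind, adj, {}, np.zeros(n))


# -- equal rate model ----------------------------------------------------

def lognormal_rates(n: int, rng: np.random.Generator,
                    median_hz: float = 5.0, sigma_log: float = 1.0,
                    clip_hz: tuple[float, float] = (0.3, 60.0)) -> np.ndarray:
    """Per-neuron mean rates (spikes/ms), log-normal with ~2 decades of
    spread, emulating the recorded firing-rate distribution."""
    hz = np.exp(rng.normal(np.log(median_hz), sigma_log, size=n))
    return np.clip(hz, *clip_hz) / 1000.0


@njit(cache=True)
def _run_trials(base_p, edge_src_ptr, edge_dst, kern_ptr, kern_flat,
                n_trials, t_len, seed):  # pragma: no cover - numba
    """Millisecond-resolution probabilistic network simulation.

    Returns (unit, trial, bin) arrays of spikes.  Injected probability from
    presynaptic spikes is added to a pending buffer through each edge's
    kernel; total per-bin probability is capped at 1."""
    np.random.seed(seed)
    n = base_p.size
    max_kern = 0
    for e in range(kern_ptr.size - 1):
        length = kern_ptr[e + 1] - kern_ptr[e]
        if length > max_kern:
            max_kern = length
    cap = int(n_trials * t_len * (base_p.sum() * 2.0 + 0.01)) + 1024
    out_u = np.empty(cap, dtype=np.int32)
    out_i = np.empty(cap, dtype=np.int32)
    out_t = np.empty(cap, dtype=np.int32)
    m = 0
    pend = np.zeros((n, t_len + max_kern + 1))
    for trial in range(n_trials):
        pend[:, :] = 0.0
        for t in range(t_len):
            for u in range(n):
                p = base_p[u] + pend[u, t]
                if p > 1.0:
                    p = 1.0
                if np.random.random() < p:
                    if m == cap:
                        cap *= 2
                        nu = np.empty(cap, dtype=np.int32)
                        ni = np.empty(cap, dtype=np.int32)
                        nt = np.empty(cap, dtype=np.int32)
                        nu[:m] = out_u
                        ni[:m] = out_i
                        nt[:m] = out_t
                        out_u, out_i, out_t = nu, ni, nt
                    out_u[m] = u
                    out_i[m] = trial
                    out_t[m] = t
                    m += 1
                    e0 = edge_src_ptr[u]
                    e1 = edge_src_ptr[u + 1]
                    for e in range(e0, e1):
                        v = edge_dst[e]
                        k0 = kern_ptr[e]
                        k1 = kern_ptr[e + 1]
                        for kk in range(k1 - k0):
                            pend[v, t + 1 + kk] += kern_flat[k0 + kk]
    return out_u[:m].copy(), out_i[:m].copy(), out_t[:m].copy()


def _edges_csr(net: GroundTruthNetwork):
    n = net.n
    srcs, dsts = np.nonzero(net.adjacency)
    order = np.argsort(srcs, kind="stable")
    srcs, dsts = srcs[order], dsts[order]
    ptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(ptr[1:], srcs, 1)
    ptr = np.cumsum(ptr)
    kerns = [net.kernels[(int(s), int(d))] for s, d in zip(srcs, dsts)]
    kern_ptr = np.zeros(len(kerns) + 1, dtype=np.int64)
    kern_ptr[1:] = np.cumsum([k.size for k in kerns])
    kern_flat = (np.concatenate(kerns) if kerns else np.zeros(0))
    return ptr, dsts.astype(np.int64), kern_ptr, kern_flat


def _spikes_to_dataset(u, i, t, n_units, n_trials) -> SpikeDataset:
    units = pd.DataFrame({
        "unit_id": [f"u{k:03d}" for k in range(n_units)],
        "area": "SIM",
        "array_id": 1,
        "electrode_id": np.arange(1, n_units + 1),
    })
    trials = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "condition": [CONDITIONS[k % len(CONDITIONS)] for k in range(n_trials)],
        "cue_onset_ms": CUE_ONSET_MS,
        "movement_onset_ms": MOVEMENT_ONSET_MS,
    })
    spikes = pd.DataFrame({
        "unit_id": pd.Series(u).map(lambda k: f"u{k:03d}"),
        "trial_id": i.astype(int),
        "time_ms": t.astype(float) + 0.5,
    })
    return SpikeDataset(units, trials, spikes)


def simulate_equal_rate(net: GroundTruthNetwork, rng: np.random.Generator,
                        n_trials: int = 600, trial_len_ms: int = TRIAL_LENGTH_MS,
                        kernel_integral: float = 0.02,
                        kernel_a: float = 5.0,
                        kernel_kind: str = "gamma",
                        rates: np.ndarray | None = None,
                        max_iter: int = 50, residual_tol: float = 0.005,
                        calibration_trials: int = 120) -> GroundTruthNetwork:
    """Simulate spiking on a ground-truth network.

    Draws gamma kernels (a = 5, b uniform in (0, 3], integral
    ``kernel_integral``) for every edge, log-normal target rates, then
    iteratively deflates base rates until the realized mean network rate
    matches the target mean to ``residual_tol`` relative error (checked on
    ``calibration_trials`` trials); the final pass simulates the full
    ``n_trials`` and attaches the resulting trial-structured dataset.
    """
    n = net.n
    if rates is None:
        rates = lognormal_rates(n, rng)
    net.target_rates = rates
    srcs, dsts = np.nonzero(net.adjacency)
    for s, d in zip(srcs, dsts):
        b = rng.uniform(0.0, 3.0)
        while b == 0.0:
            b = rng.uniform(0.0, 3.0)
        if kernel_kind == "gamma":
            net.kernels[(int(s), int(d))] = gamma_kernel(b, a=kernel_a,
                                                         integral=kernel_integral)
        else:
            net.kernels[(int(s), int(d))] = boxcar_kernel(integral=kernel_integral)
    ptr, dst, kern_ptr, kern_flat = _edges_csr(net)
    base = rates.copy()
    target_mean = rates.mean()
    realized = rates
    for it in range(max_iter):
        seed = int(rng.integers(2**31))
        u, i, t = _run_trials(base, ptr, dst, kern_ptr, kern_flat,
                              calibration_trials, trial_len_ms, seed)
        counts = np.bincount(u, minlength=n)
        realized = counts / (calibration_trials * trial_len_ms)
        resid = abs(realized.mean() - target_mean) / target_mean
        if resid < residual_tol:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(realized > 0, rates / realized, 1.0)
        base = np.clip(base * np.clip(factor, 0.25, 1.5), 1e-6, 1.0)
    else:
        raise RuntimeError(
            f"rate deflation did not converge in {max_iter} iterations "
            f"(last residual {resid:.4f})")
    seed = int(rng.integers(2**31))
    u, i, t = _run_trials(base, ptr, dst, kern_ptr, kern_flat,
                          n_trials, trial_len_ms, seed)
    counts = np.bincount(u, minlength=n)
    net.base_rates = base
    net.realized_rates = counts / (n_trials * trial_len_ms)
    if np.std(rates) > 0 and np.std(net.realized_rates) > 0:
        net.rate_correlation = float(np.corrcoef(rates, net.realized_rates)[0, 1])
    net.dataset = _spikes_to_dataset(u, i, t, n, n_trials)
    log.info("equal-rate %s: mean target %.3f Hz, realized %.3f Hz, r=%.3f",
             net.label, 1000 * rates.mean(), 1000 * net.realized_rates.mean(),
             net.rate_correlation)
    return net


# -- detection scoring ---------------------------------------------------

@dataclass
class DetectionReport:
    """Signal-detection scores of a detected network against its truth."""

    directed: dict
    undirected: dict
    direction_given_detection: dict
    bidirectional_peak_sd: float = np.nan
    common_drive_peak_sd: float = np.nan
    zero_lag_ratio: float = np.nan
    n_bidirectional: int = 0
    n_common_drive: int = 0
    common_drive_significant_fraction: float = np.nan

    def to_dict(self) -> dict:
        """JSON-ready detection report."""
        out = {
            "directed": self._rates(self.directed),
            "undirected": self._rates(self.undirected),
            "direction_given_detection": self._rates(self.direction_given_detection),
            "bidirectional_peak_sd": self.bidirectional_peak_sd,
            "common_drive_peak_sd": self.common_drive_peak_sd,
            "zero_lag_ratio": self.zero_lag_ratio,
            "n_bidirectional": self.n_bidirectional,
            "n_common_drive": self.n_common_drive,
            "common_drive_significant_fraction":
                self.common_drive_significant_fraction,
        }
        return {k: ({kk: (None if isinstance(vv, float) and np.isnan(vv) else vv)
                     for kk, vv in v.items()} if isinstance(v, dict)
                    else (None if isinstance(v, float) and np.isnan(v) else v))
                for k, v in out.items()}

    @staticmethod
    def _rates(d):
        pos = d["hit"] + d["miss"]
        neg = d["cr"] + d["fa"]
        return {
            **d,
            "hit_rate": d["hit"] / pos if pos else np.nan,
            "cr_rate": d["cr"] / neg if neg else np.nan,
        }

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, d in (("directed", self.directed),
                        ("undirected", self.undirected),
                        ("direction", self.direction_given_detection)):
            r = self._rates(d)
            rows.append((name, r["hit"], r["miss"], r["cr"], r["fa"],
                         100 * r["hit_rate"], 100 * r["cr_rate"]))
        return pd.DataFrame(rows, columns=["level", "hit", "miss", "cr", "fa",
                                           "hit_pct", "cr_pct"])


def _pair_type(adj, i, j):
    a, b = adj[i, j], adj[j, i]
    if a and b:
        return "bi"
    if a:
        return "ij"
    if b:
        return "ji"
    return "none"


def score_detection(net: GroundTruthNetwork, detected_adj: np.ndarray,
                    detection=None, config: RunConfig = DEFAULT_CONFIG
                    ) -> DetectionReport:
    """Hit/Miss/CR/FA at three levels plus common-drive CCH statistics.

    ``detection`` (a NetworkDetection) is needed for the CCH peak measures
    in surrogate-SD units and the significant-cluster counts; without it
    only the confusion counts are produced.
    """
    truth = net.adjacency
    n = net.n
    if detected_adj.shape != truth.shape:
        raise ValueError("truth and detected networks differ in node count")
    directed = {"hit": 0, "miss": 0, "cr": 0, "fa": 0}
    off = ~np.eye(n, dtype=bool)
    directed["hit"] = int((truth & detected_adj).sum())
    directed["miss"] = int((truth & ~detected_adj).sum())
    directed["fa"] = int((~truth & detected_adj & off).sum())
    directed["cr"] = int((~truth & ~detected_adj & off).sum())

    t_conn = truth | truth.T
    d_conn = detected_adj | detected_adj.T
    iu = np.triu_indices(n, 1)
    undirected = {
        "hit": int((t_conn & d_conn)[iu].sum()),
        "miss": int((t_conn & ~d_conn)[iu].sum()),
        "fa": int((~t_conn & d_conn)[iu].sum()),
        "cr": int((~t_conn & ~d_conn)[iu].sum()),
    }

    # direction given detection: ordered pairings of pairs whose connection
    # was detected -- a pure evaluation of directionality.  The true
    # direction counts as a hit when the detection includes it (also as part
    # of a bidirectional call); the absent reverse direction of a truly
    # unidirectional pair counts as CR when it was not claimed.
    dgd = {"hit": 0, "miss": 0, "cr": 0, "fa": 0}
    for i, j in zip(*np.nonzero(np.triu(t_conn & d_conn, 1))):
        for s, t in ((i, j), (j, i)):
            if truth[s, t]:
                dgd["hit" if detected_adj[s, t] else "miss"] += 1
            else:
                dgd["fa" if detected_adj[s, t] else "cr"] += 1

    report = DetectionReport(directed, undirected, dgd)

    if detection is not None:
        zprofiles = {}
        sig = {}
        unit_ids = detection.unit_ids
        for (ua, ub), pr in detection.pairs.items():
            i, j = unit_ids.index(ua), unit_ids.index(ub)
            zprofiles[(i, j)] = pr.zscores()
            sig[(i, j)] = bool(pr.significant_clusters())
        lags = detection.lags
        window = np.abs(lags) <= config.test_window_ms

        def group_stats(pairs):
            if not pairs:
                return np.nan, 0
            avg = np.mean([zprofiles[p] for p in pairs], axis=0)
            zero = sum(1 for p in pairs
                       if lags[window][np.argmax(zprofiles[p][window])] == 0)
            return float(avg[window].max()), zero

        bi_pairs = net.bidirectional_pairs()
        cd_pairs = net.common_drive_pairs()
        report.n_bidirectional = len(bi_pairs)
        report.n_common_drive = len(cd_pairs)
        report.bidirectional_peak_sd, zero_bi = group_stats(bi_pairs)
        report.common_drive_peak_sd, zero_cd = group_stats(cd_pairs)
        if bi_pairs and cd_pairs:
            # group-size-normalized fold excess; Haldane-Anscombe 0.5 keeps
            # the estimate finite when no common-drive maximum hits 0 ms
            report.zero_lag_ratio = (((zero_bi + 0.5) / len(bi_pairs))
                                     / ((zero_cd + 0.5) / len(cd_pairs)))
        if cd_pairs:
            report.common_drive_significant_fraction = float(
                np.mean([sig[p] for p in cd_pairs]))
    return report


def pool_detection_stats(nets_and_detections: list, config=DEFAULT_CONFIG) -> dict:
    """Pool bidirectional / common-drive CCH statistics across simulations
    (both network kinds), as used for the zero-lag and peak comparisons."""
    bi_profiles, cd_profiles = [], []
    cd_sig = []
    zero_bi = zero_cd = 0
    lags = None
    for net, det in nets_and_detections:
        lags = det.lags
        window = np.abs(lags) <= config.test_window_ms
        unit_ids = det.unit_ids
        zp = {}
        for (ua, ub), pr in det.pairs.items():
            zp[(unit_ids.index(ua), unit_ids.index(ub))] = pr.zscores()
        for p in net.bidirectional_pairs():
            bi_profiles.append(zp[p])
            if lags[window][np.argmax(zp[p][window])] == 0:
                zero_bi += 1
        for p in net.common_drive_pairs():
            cd_profiles.append(zp[p])
            if lags[window][np.argmax(zp[p][window])] == 0:
                zero_cd += 1
            cd_sig.append(bool(det.pairs[(unit_ids[p[0]], unit_ids[p[1]])]
                               .significant_clusters()))
    window = np.abs(lags) <= config.test_window_ms
    out = {
        "n_bidirectional": len(bi_profiles),
        "n_common_drive": len(cd_profiles),
        "bidirectional_peak_sd": float(np.mean(bi_profiles, axis=0)[window].max())
        if bi_profiles else np.nan,
        "common_drive_peak_sd": float(np.mean(cd_profiles, axis=0)[window].max())
        if cd_profiles else np.nan,
        "common_drive_significant_fraction": float(np.mean(cd_sig))
        if cd_sig else np.nan,
    }
    if bi_profiles and cd_profiles:
        out["zero_lag_ratio"] = (((zero_bi + 0.5) / len(bi_profiles))
                                 / ((zero_cd + 0.5) / len(cd_profiles)))
    else:
        out["zero_lag_ratio"] = np.nan
    out["zero_lag_bidirectional"] = zero_bi
    out["zero_lag_common_drive"] = zero_cd
    return out


# -- subsampling plane ---------------------------------------------------

@dataclass
class NeuronalPlane:
    """Two-area neuronal sheet with distance-group Poisson connectivity.

    Neurons live on (area, sub-region, electrode) coordinates; connection
    probability between two neurons depends only on their distance group
    (same electrode / same sub-region / same area / inter-area) scaled by
    ``density_scale``.  The adjacency is realized lazily per requested
    node subset, so the full 32,000-neuron plane never needs to be stored.
    """

    n_areas: int = 2
    n_subregions: int = 5
    n_electrodes: int = 160
    per_electrode: int = 20
    density_scale: float = 1.0
    densities: dict = field(default_factory=lambda: {
        "same_electrode": GROUP_DENSITIES["same_electrode"],
        "same_array": GROUP_DENSITIES["same_array"],
        "same_area": GROUP_DENSITIES["same_area"],
        "inter_area": INTER_AREA_DENSITY,
    })

    @property
    def n_neurons(self):
        return (self.n_areas * self.n_subregions * self.n_electrodes
                * self.per_electrode)

    def coords(self, idx: np.ndarray):
        per_sub = self.n_electrodes * self.per_electrode
        per_area = self.n_subregions * per_sub
        area = idx // per_area
        sub = (idx % per_area) // per_sub
        elec = (idx % per_sub) // self.per_electrode
        return area, sub, elec

    def group_matrix(self, idx: np.ndarray) -> np.ndarray:
        """Distance-group code (0..3) for every pair of the given neurons."""
        area, sub, elec = self.coords(np.asarray(idx))
        same_area = area[:, None] == area[None, :]
        same_sub = same_area & (sub[:, None] == sub[None, :])
        same_elec = same_sub & (elec[:, None] == elec[None, :])
        g = np.full((idx.size, idx.size), 3, dtype=np.int8)  # inter_area
        g[same_area] = 2
        g[same_sub] = 1
        g[same_elec] = 0
        return g

    def _probs(self):
        p = np.array([self.densities["same_electrode"],
                      self.densities["same_array"],
                      self.densities["same_area"],
                      self.densities["inter_area"]])
        return np.clip(p * self.density_scale, 0.0, 1.0)

    def realize_adjacency(self, idx: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
        """Symmetric boolean adjacency among the chosen neurons."""
        g = self.group_matrix(np.asarray(idx))
        p = self._probs()[g]
        upper = np.triu(rng.random(p.shape) < p, 1)
        return upper | upper.T

    def subsample_indices(self, n_units: int, rng: np.random.Generator,
                          subregions_per_area: int = 2,
                          electrodes_per_subregion: int = 32) -> np.ndarray:
        """Electrode-configuration-matched subsample of ``n_units`` neurons:
        both areas, 2 sub-regions per area, 32 electrode positions each."""
        per_sub = self.n_electrodes * self.per_electrode
        per_area = self.n_subregions * per_sub
        slots = []
        for area in range(self.n_areas):
            subs = rng.choice(self.n_subregions, subregions_per_area, replace=False)
            for s in subs:
                elecs = rng.choice(self.n_electrodes, electrodes_per_subregion,
                                   replace=False)
                for e in elecs:
                    base = area * per_area + s * per_sub + e * self.per_electrode
                    slots.extend(range(base, base + self.per_electrode))
        slots = np.array(slots)
        if n_units > slots.size:
            raise ValueError(f"cannot draw {n_units} units from {slots.size} slots")
        return np.sort(rng.choice(slots, size=n_units, replace=False))


def compartmentalization(n_nodes: int, n_components: int) -> float:
    """(P - 1) / (N - 1): 0 for a single component, 1 for all isolated."""
    if n_nodes <= 1:
        return 0.0
    return (n_components - 1) / (n_nodes - 1)


def plane_component_stats(plane: NeuronalPlane, rng: np.random.Generator,
                          n_check: int | None = None) -> dict:
    """Largest-component fraction and compartmentalization of the plane
    (realized on ``n_check`` neurons; the full plane when small enough)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = plane.n_neurons if n_check is None else min(n_check, plane.n_neurons)
    idx = (np.arange(plane.n_neurons) if n == plane.n_neurons
           else np.sort(rng.choice(plane.n_neurons, n, replace=False)))
    # build in row blocks to bound memory
    rows, cols = [], []
    block = max(1, 20_000_000 // n)
    probs = plane._probs()
    g_full = plane.group_matrix(idx)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        p = probs[g_full[lo:hi]]
        hit = rng.random(p.shape) < p
        r, c = np.nonzero(hit)
        keep = (r + lo) < c  # upper triangle only
        rows.append(r[keep] + lo)
        cols.append(c[keep])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.ones(rows.size, dtype=np.int8)
    a = csr_matrix((data, (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(a, directed=False)
    sizes = np.bincount(labels)
    return {
        "n_neurons": n,
        "n_components": int(n_comp),
        "largest_component_fraction": float(sizes.max() / n),
        "compartmentalization": compartmentalization(n, int(n_comp)),
        "mean_degree": float(2.0 * rows.size / n),
    }


def density_sweep(factors=(1/5, 1/4, 1/3, 1/2, 1, 2, 3, 4, 5),
                  dataset_sizes=(148, 137, 79, 57, 64, 64, 64, 78, 47, 33, 30, 41),
                  plane_kwargs: dict | None = None,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sweep the connection-density scale and report, per factor, the mean
    adjusted R^2 of a power-law fit to the subsampled degree distributions,
    the plane's relative largest-component size, and its
    compartmentalization."""
    from .topology import degree_distribution, fit_heavytail_models

    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for f in factors:
        plane = NeuronalPlane(density_scale=f, **(plane_kwargs or {}))
        comp = plane_component_stats(plane, rng)
        deg_sets = []
        for size in dataset_sizes:
            idx = plane.subsample_indices(size, rng)
            adj = plane.realize_adjacency(idx, rng)
            deg_sets.append(adj.sum(axis=1))
        pl_r2 = np.nan
        try:
            x, y = degree_distribution(deg_sets, normalize_pct=True, n_bins=15)
            fits = fit_heavytail_models(x, y)
            pl_r2 = fits["PL"].adj_r2
        except (ValueError, RuntimeError):
            pass
        rows.append((f, pl_r2, comp["largest_component_fraction"],
                     comp["compartmentalization"], comp["mean_degree"],
                     comp["largest_component_fraction"] < 1.0))
    df = pd.DataFrame(rows, columns=["factor", "pl_adj_r2", "largest_component",
                                     "compartmentalization", "mean_degree",
                                     "fragmented"])
    valid = df.dropna()
    if len(valid) >= 3:
        df.attrs["corr_pl_component"] = float(
            np.corrcoef(valid["pl_adj_r2"], valid["largest_component"])[0, 1])
        df.attrs["corr_pl_compart"] = float(
            np.corrcoef(valid["pl_adj_r2"], valid["compartmentalization"])[0, 1])
    return df


# -- oscillatory / non-oscillatory pair model ----------------------------

def _shared_probability(kind: str, n_trials: int, t_len: int,
                        freq_hz: float, peak_prob: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-trial shared spiking-probability traces (n_trials, t_len).

    Oscillatory: a 20 Hz sinusoid probability with random phase per trial
    and peak ``peak_prob``.  Non-oscillatory: the same trace randomized in
    time, low-passed at 50 Hz (4th-order Butterworth, non-causal) and
    variance- and mean-matched to the oscillatory trace.
    """
    t = np.arange(t_len) / 1000.0
    phases = rng.uniform(0, 2 * np.pi, size=n_trials)
    osc = peak_prob * (1 + np.sin(2 * np.pi * freq_hz * t[None, :]
                                  + phases[:, None])) / 2.0
    if kind == "oscillatory":
        return osc
    if kind != "non_oscillatory":
        raise ValueError(f"unknown pair kind {kind!r}")
    out = np.empty_like(osc)
    b, a = butter(4, 50.0, btype="low", fs=1000.0)
    for i in range(n_trials):
        scrambled = rng.permutation(osc[i])
        filt = filtfilt(b, a, scrambled)
        # variance- and mean-match to the sinusoid; clipping at zero removes
        # variance, so match iteratively on the clipped trace
        trace = filt
        for _ in range(4):
            s = trace.std()
            if s == 0:
                break
            trace = (trace - trace.mean()) / s * osc[i].std() + osc[i].mean()
            trace = np.clip(trace, 0.0, 1.0)
        out[i] = trace
    return out


def simulate_pair(kind: str, jitter_ms: float,
                  rng: np.random.Generator | None = None,
                  n_trials: int = 600, trial_len_ms: int = TRIAL_LENGTH_MS,
                  freq_hz: float = 20.0, peak_prob: float = 0.009,
                  background_hz: float = 0.5) -> SpikeDataset:
    """Two-unit dataset with shared-probability coupling.

    Both units draw spikes from the same per-trial probability trace (plus
    independent Poisson background yielding an average rate around 5 Hz);
    unit 2's trace is shifted by a per-trial offset uniform in
    [-jitter, +jitter] ms, so the jitter sets the coupling strength without
    touching single-unit statistics."""
    if rng is None:
        rng = np.random.default_rng(0)
    if not 0 <= jitter_ms <= 50:
        raise ValueError("jitter must be within [0, 50] ms")
    p = _shared_probability(kind, n_trials, trial_len_ms, freq_hz,
                            peak_prob, rng)
    bg = background_hz / 1000.0
    spikes_u = []
    spikes_i = []
    spikes_t = []
    for i in range(n_trials):
        offset = int(np.round(rng.uniform(-jitter_ms, jitter_ms)))
        p2 = np.roll(p[i], offset)
        for u, trace in enumerate((p[i], p2)):
            fire = rng.random(trial_len_ms) < np.clip(trace + bg, 0, 1)
            t = np.flatnonzero(fire)
            spikes_u.append(np.full(t.size, u))
            spikes_i.append(np.full(t.size, i))
            spikes_t.append(t)
    return _spikes_to_dataset(np.concatenate(spikes_u),
                              np.concatenate(spikes_i),
                              np.concatenate(spikes_t), 2, n_trials)


# -- packaged mini-fixtures ----------------------------------------------

def make_fixtures(seed: int = 0) -> dict:
    """Deterministic small fixture suite for tests: SN/CN networks (n = 30,
    reduced trials), an oscillatory pair, and a common-drive triplet."""
    rng = np.random.default_rng(seed)
    out = {}
    for kind in ("SN", "CN"):
        net = build_topology(kind, n=30, rng=rng)
        out[kind.lower()] = simulate_equal_rate(
            net, rng, n_trials=120, calibration_trials=60)
    out["osc_pair"] = simulate_pair("oscillatory", 0.0, rng, n_trials=150)
    # common-drive triplet: u0 -> u1 and u0 -> u2, no u1-u2 connection
    tri = GroundTruthNetwork("SN", np.array([[0, 1, 1], [0, 0, 0], [0, 0, 0]],
                                            dtype=bool), {}, np.zeros(3))
    out["common_drive"] = simulate_equal_rate(
        tri, rng, n_trials=200, calibration_trials=60,
        rates=np.full(3, 8.0 / 1000.0))
    return out
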
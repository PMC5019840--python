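"""Significance testing of correlograms and binary directed network construction.

Per pair: z-score the corrected correlogram by the per-lag surrogate SD,
cluster suprathreshold lags inside the +/-200 ms test window, score clusters
against the largest-chance-cluster null from the corrected surrogate
members, then control the false discovery rate across all clusters of all
pairs.  Significant pairs become edges whose direction follows the lag of
the significant structure: positive-lag clusters mean reference -> target;
structure on both sides (or straddling zero) falls back to the unsigned
maximum peak, bidirectional when that peak sits within 2 ms of zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cch import CCHEngine, SurrogateEnsemble
from .cluster import Cluster, attach_pvalues, fdr_correct, find_clusters, member_null
from .config import RunConfig, DEFAULT_CONFIG
from .data import BinnedSegments

log = logging.getLogger(__name__)

DISTANCE_GROUPS = (
    "same_electrode", "same_array", "same_area",
    "AIP-F5", "F5-M1", "AIP-M1", "inter_area",
)


@dataclass
class Edge:
    source: str
    target: str
    bidirectional: bool
    max_peak_lag_ms: float
    p_value: float


@dataclass
class PairResult:
    """Cluster statistics of one unordered pair (reference = unit_a)."""

    unit_a: str
    unit_b: str
    corrected: np.ndarray          # smoothed corrected CCH (orientation a->b)
    sd: np.ndarray                 # per-lag surrogate SD
    clusters: list[Cluster]
    skipped: bool = False

    def zscores(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.corrected / self.sd
        z[~np.isfinite(z)] = 0.0
        return z

    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]

    def max_peak(self, lags: np.ndarray, window: int):
        """(lag, z) of the unsigned maximum of the corrected CCH in window."""
        m = np.abs(lags) <= window
        idx = np.flatnonzero(m)
        vals = np.abs(self.corrected[idx])
        k = idx[int(np.argmax(vals))]
        sd = self.sd[k]
        z = self.corrected[k] / sd if sd > 0 else 0.0
        return int(lags[k]), float(z)


def zscore_and_cluster(corrected: np.ndarray, ensemble: SurrogateEnsemble,
                       lags: np.ndarray, config: RunConfig = DEFAULT_CONFIG
                       ) -> tuple[np.ndarray, list[Cluster]]:
    """z(tau) = corrected(tau)/SD(tau); same-sign contiguous runs with
    |z| >= threshold inside the test window form candidate clusters scored
    by accumulated z.  Zero-SD lags are masked."""
    sd = ensemble.sd
    valid = sd > 0
    if not valid.any():
        warnings.warn("all-zero surrogate SD; pair skipped")
        return np.zeros_like(corrected), []
    z = np.zeros_like(corrected, dtype=float)
    z[valid] = corrected[valid] / sd[valid]
    window = np.abs(lags) <= config.test_window_ms
    clusters = find_clusters(z, config.z_threshold, mask=window & valid)
    return z, clusters


def cluster_null(ensemble: SurrogateEnsemble, lags: np.ndarray,
                 config: RunConfig = DEFAULT_CONFIG) -> np.ndarray:
    """2R-value null of largest |accumulated z| chance clusters (both pair
    orderings merged; see cluster.member_null)."""
    sd = ensemble.sd
    valid = sd > 0
    window = (np.abs(lags) <= config.test_window_ms) & valid
    zm = np.zeros_like(ensemble.members)
    zm[:, valid] = ensemble.members[:, valid] / sd[valid]
    return member_null(zm, config.z_threshold, mask=window, merge_orderings=True)


def classify_direction(pair: PairResult, lags: np.ndarray,
                       config: RunConfig = DEFAULT_CONFIG) -> Edge | None:
    """Edge(s) implied by the significant clusters of a pair.

    Positive lags carry unit_a -> unit_b influence.  The unsigned maximum
    peak decides ambiguous cases; |lag| <= 2 ms means bidirectional.
    """
    sig = pair.significant_clusters()
    if not sig:
        return None
    p_best = min(c.p_value for c in sig)
    pos = all(lags[c.start] > 0 for c in sig)
    neg = all(lags[c.stop] < 0 for c in sig)
    peak_lag, _ = pair.max_peak(lags, config.test_window_ms)
    if pos:
        return Edge(pair.unit_a, pair.unit_b, False, float(peak_lag), p_best)
    if neg:
        return Edge(pair.unit_b, pair.unit_a, False, float(peak_lag), p_best)
    if abs(peak_lag) <= config.bidirectional_max_peak_ms:
        return Edge(pair.unit_a, pair.unit_b, True, float(peak_lag), p_best)
    if peak_lag > 0:
        return Edge(pair.unit_a, pair.unit_b, False, float(peak_lag), p_best)
    return Edge(pair.unit_b, pair.unit_a, False, float(peak_lag), p_best)


def pair_distance_group(meta_a, meta_b) -> str:
    if meta_a.area == meta_b.area:
        if meta_a.array_id == meta_b.array_id:
            if meta_a.electrode_id == meta_b.electrode_id:
                return "same_electrode"
            return "same_array"
        return "same_area"
    pair = "-".join(sorted((meta_a.area, meta_b.area)))
    return pair if pair in DISTANCE_GROUPS else "inter_area"


class NetworkDetection:
    """Result of the pairwise connectivity analysis of one dataset."""

    def __init__(self, unit_ids, lags, pairs: dict, edges: list[Edge],
                 config: RunConfig, engine: CCHEngine | None = None):
        self.unit_ids = list(unit_ids)
        self.lags = lags
        self.pairs = pairs            # {(a_id, b_id): PairResult}, a_id < b_id order of unit list
        self.edges = edges
        self.config = config
        self.engine = engine

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.source, e.target, e.bidirectional, e.max_peak_lag_ms, e.p_value)
             for e in self.edges],
            columns=["source", "target", "bidirectional", "max_peak_lag_ms", "p_value"],
        )

    def adjacency(self) -> np.ndarray:
        """Binary directed adjacency over all units (unpruned)."""
        idx = {u: i for i, u in enumerate(self.unit_ids)}
        a = np.zeros((len(self.unit_ids),) * 2, dtype=bool)
        for e in self.edges:
            a[idx[e.source], idx[e.target]] = True
            if e.bidirectional:
                a[idx[e.target], idx[e.source]] = True
        return a


def analyze_pairs(binned: BinnedSegments, config: RunConfig = DEFAULT_CONFIG,
                  rng: np.random.Generator | None = None,
                  n_surrogates: int | None = None,
                  keep_engine: bool = False,
                  progress: bool = False) -> NetworkDetection:
    """Full pairwise CCH + cluster-significance + FDR + direction pipeline."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    R = int(n_surrogates or config.n_surrogates)
    engine = CCHEngine(binned, config)
    engine.make_surrogates(R, rng)
    lags = engine.lags
    unit_ids = engine.unit_ids
    n = len(unit_ids)
    pairs: dict[tuple[str, str], PairResult] = {}
    all_clusters: list[Cluster] = []
    for a in range(n):
        if progress and a % 10 == 0:
            log.info("pair analysis: reference unit %d/%d", a, n)
        for b in range(a + 1, n):
            res = engine.corrected_pair(a, b)
            key = (unit_ids[a], unit_ids[b])
            if res is None:
                pairs[key] = PairResult(unit_ids[a], unit_ids[b],
                                        np.zeros_like(lags, dtype=float),
                                        np.zeros_like(lags, dtype=float),
                                        [], skipped=True)
                continue
            corrected, ens = res
            z, clusters = zscore_and_cluster(corrected, ens, lags, config)
            if clusters:
                null = cluster_null(ens, lags, config)
                attach_pvalues(clusters, null)
            pairs[key] = PairResult(unit_ids[a], unit_ids[b], corrected,
                                    ens.sd, clusters)
            all_clusters.extend(clusters)
    # network-wide FDR across all clusters of all pairs
    if all_clusters:
        keep = fdr_correct(np.array([c.p_value for c in all_clusters]), config.fdr_q)
        for c, k in zip(all_clusters, keep):
            c.significant = bool(k)
    edges = []
    for pr in pairs.values():
        e = classify_direction(pr, lags, config)
        if e is not None:
            edges.append(e)
    return NetworkDetection(unit_ids, lags, pairs, edges, config,
                            engine=engine if keep_engine else None)


def build_graph(detection: NetworkDetection, unit_meta: list) -> "ConnectivityGraph":
    """Binary directed graph over the largest weakly connected component."""
    meta = {m.unit_id: m for m in unit_meta}
    g = nx.DiGraph()
    connected_units = set()
    for e in detection.edges:
        connected_units.update((e.source, e.target))
    for u in detection.unit_ids:
        if u in connected_units:
            g.add_node(u, **vars(meta[u]))
    for e in detection.edges:
        g.add_edge(e.source, e.target, bidirectional=e.bidirectional)
        if e.bidirectional:
            g.add_edge(e.target, e.source, bidirectional=True)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph: no significant connections")
    comps = sorted(nx.weakly_connected_components(g), key=len, reverse=True)
    largest = comps[0]
    dropped = [u for u in detection.unit_ids if u not in largest]
    h = g.subgraph(largest).copy()
    return ConnectivityGraph(h, meta, dropped, n_total=len(detection.unit_ids))


class ConnectivityGraph:
    """Directed binary network restricted to the largest weakly connected
    component, with distance-group labels per node pair."""

    def __init__(self, digraph: nx.DiGraph, meta: dict, dropped: list[str],
                 n_total: int):
        self.digraph = digraph
        self.meta = meta
        self.dropped = dropped
        self.n_total = n_total
        if digraph.number_of_nodes() and not nx.is_weakly_connected(digraph):
            raise ValueError("graph is not weakly connected")

    @property
    def nodes(self) -> list[str]:
        return list(self.digraph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.digraph.number_of_nodes()

    @property
    def dropped_fraction(self) -> float:
        return len(self.dropped) / self.n_total if self.n_total else 0.0

    def skeleton(self) -> nx.Graph:
        """Undirected connection graph (a bidirectional pair is one edge)."""
        return nx.Graph(self.digraph)

    def distance_group(self, u: str, v: str) -> str:
        return pair_distance_group(self.meta[u], self.meta[v])

    def edge_groups(self) -> dict[str, list[tuple[str, str]]]:
        out: dict[str, list] = {}
        for u, v in self.skeleton().edges:
            out.setdefault(self.distance_group(u, v), []).append((u, v))
        return out

    def write_graphml(self, path, node_attrs: dict | None = None) -> None:
        """Export the directed graph in GraphML, with unit metadata and any
        extra per-node attributes (module, hub, oscillator class, ...)."""
        g = self.digraph.copy()
        for u in g.nodes:
            m = self.meta[u]
            g.nodes[u].update(area=m.area, array_id=int(m.array_id),
                              electrode_id=int(m.electrode_id))
            for key, mapping in (node_attrs or {}).items():
                if u in mapping:
                    val = mapping[u]
                    g.nodes[u][key] = (val if isinstance(val, (int, float, str, bool))
                                       else str(val))
        nx.write_graphml(g, path)

    def group_densities(self) -> pd.DataFrame:
        """Realized connection probability per distance group."""
        nodes = self.nodes
        possible: dict[str, int] = {}
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                gname = self.distance_group(u, v)
                possible[gname] = possible.get(gname, 0) + 1
        sk = self.skeleton()
        realized = {gname: 0 for gname in possible}
        for u, v in sk.edges:
            realized[self.distance_group(u, v)] += 1
        rows = [(gname, realized.get(gname, 0), n_pairs,
                 realized.get(gname, 0) / n_pairs if n_pairs else np.nan)
                for gname, n_pairs in possible.items()]
        return pd.DataFrame(rows, columns=["group", "edges", "pairs", "density"])
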
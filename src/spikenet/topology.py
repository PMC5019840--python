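"""Graph-topology characterization of the detected binary directed network.

Conventions: the *degree* of a node counts distinct connected partners (a
bidirectional pair contributes one), matching the undirected form of the
rich-club count; path-based measures (characteristic path length L and
betweenness g) run on the directed adjacency as constructed; the clustering
coefficient C uses the undirected skeleton.  Small-worldness is
SW = (C/C_rand)/(L/L_rand) against the mean of a distance-preserving
surrogate-network ensemble; modularity Q is evaluated exactly as

    Q = sum_u [ e_uu - (sum_v e_uv)^2 ]

with e_uv the fraction of connections joining modules u and v.  The
rich-club coefficient R(k) = 2 E_{>k} / (N_{>k}(N_{>k}-1)) is normalized by
degree-preserving surrogates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.sparse.csgraph import shortest_path as _sp

from .cluster import Cluster, cluster_permutation_test
from .config import RunConfig, DEFAULT_CONFIG
from .connectivity import ConnectivityGraph

log = logging.getLogger(__name__)


# -- core measures on boolean adjacency ----------------------------------

def _skeleton_adj(adj: np.ndarray) -> np.ndarray:
    return adj | adj.T


def degrees(adj: np.ndarray) -> np.ndarray:
    """Partner counts on the undirected skeleton."""
    return _skeleton_adj(adj).sum(axis=1)


def clustering_coefficients(adj: np.ndarray) -> np.ndarray:
    """Per-node fraction of realized links among connected neighbors."""
    a = _skeleton_adj(adj).astype(np.int64)
    k = a.sum(axis=1)
    tri = np.diag(a @ a @ a) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = 2.0 * tri / (k * (k - 1.0))
    c[k < 2] = 0.0
    return c


def path_lengths(adj: np.ndarray) -> np.ndarray:
    """Directed shortest-path length matrix (inf where unreachable)."""
    d = _sp(adj.astype(np.int8), method="D", directed=True, unweighted=True)
    return d


def characteristic_path_length(adj: np.ndarray) -> float:
    """Mean shortest path over reachable ordered pairs i != j."""
    d = path_lengths(adj)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    return float(d[finite].mean()) if finite.any() else np.nan


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Directed betweenness centrality, normalized by (n-1)(n-2)."""
    g = nx.from_numpy_array(adj, create_using=nx.DiGraph)
    bc = nx.betweenness_centrality(g, normalized=True)
    return np.array([bc[i] for i in range(adj.shape[0])])


@dataclass
class TopologyReport:
    node_ids: list[str]
    degree: np.ndarray
    degree_pct: np.ndarray          # % of n-1 possible partners
    betweenness: np.ndarray
    clustering: np.ndarray
    C: float
    L: float
    density: float
    SW: float = np.nan
    SW_p: float = np.nan
    C_p: float = np.nan
    L_p: float = np.nan
    Q: float = np.nan
    Q_p: float = np.nan
    partition: list[set] | None = None
    rich_club: pd.DataFrame | None = None
    hubs: list[str] | None = None
    degree_betweenness_spearman: tuple[float, float] | None = None

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "unit_id": self.node_ids,
            "degree": self.degree,
            "degree_pct": self.degree_pct,
            "betweenness": self.betweenness,
            "clustering": self.clustering,
            "hub": [u in set(self.hubs or ()) for u in self.node_ids],
        })


def centralities(graph: ConnectivityGraph) -> TopologyReport:
    """Per-node degree/betweenness/clustering and global C, L, density."""
    if graph.n_nodes < 3:
        raise ValueError("need a connected graph with >= 3 nodes")
    nodes = graph.nodes
    adj = nx.to_numpy_array(graph.digraph, nodelist=nodes, dtype=bool)
    k = degrees(adj)
    n = len(nodes)
    c = clustering_coefficients(adj)
    report = TopologyReport(
        node_ids=nodes,
        degree=k,
        degree_pct=100.0 * k / (n - 1),
        betweenness=betweenness(adj),
        clustering=c,
        C=float(c.mean()),
        L=characteristic_path_length(adj),
        density=float(k.sum() / (n * (n - 1))),
    )
    return report


# -- surrogate network ensembles -----------------------------------------

@dataclass
class SurrogateNetworkSet:
    kind: str                      # distance_preserving | degree_preserving
    members: list[np.ndarray]      # boolean directed adjacencies
    node_ids: list[str]

    @property
    def n_members(self):
        return len(self.members)


def _edge_flags(graph: ConnectivityGraph, grouper=None):
    """Unordered edges with bidirectional flags, grouped by distance group."""
    grouper = grouper or graph.distance_group
    groups: dict[str, list[tuple[int, int, bool]]] = {}
    nodes = graph.nodes
    idx = {u: i for i, u in enumerate(nodes)}
    dig = graph.digraph
    for u, v in graph.skeleton().edges:
        bi = dig.has_edge(u, v) and dig.has_edge(v, u)
        groups.setdefault(grouper(u, v), []).append((idx[u], idx[v], bi))
    return groups


def _group_pairs(graph: ConnectivityGraph, grouper=None):
    grouper = grouper or graph.distance_group
    nodes = graph.nodes
    idx = {u: i for i, u in enumerate(nodes)}
    pairs: dict[str, list[tuple[int, int]]] = {}
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            pairs.setdefault(grouper(u, v), []).append((idx[u], idx[v]))
    return pairs


def physical_distance_grouper(coords: dict, step_mm: float = 3.6,
                              max_group_pairs: set | None = None):
    """Distance grouping by physical electrode distance in ``step_mm`` bins
    (0 mm is its own group).  Node pairs listed in ``max_group_pairs`` (e.g.
    area pairs separated by a sulcus, where Euclidean distance is
    misleading) are assigned to a separate maximum-distance group."""

    def grouper(u, v):
        (xa, ya, aa), (xb, yb, ab) = coords[u], coords[v]
        if max_group_pairs and frozenset((aa, ab)) in max_group_pairs:
            return "max_distance"
        d = float(np.hypot(xa - xb, ya - yb))
        if d == 0:
            return "d0"
        return f"d{int(np.ceil(d / step_mm))}"

    return grouper


def _orient(n, chosen, flags, rng):
    adj = np.zeros((n, n), dtype=bool)
    for (i, j), bi in zip(chosen, flags):
        if bi:
            adj[i, j] = adj[j, i] = True
        elif rng.random() < 0.5:
            adj[i, j] = True
        else:
            adj[j, i] = True
    return adj


def _connected(adj: np.ndarray) -> bool:
    sk = _skeleton_adj(adj)
    n = sk.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(sk[i]):
            if not seen[j]:
                seen[j] = True
                stack.append(j)
    return bool(seen.all())


def shuffle_networks(graph: ConnectivityGraph, kind: str, count: int = 1000,
                     rng: np.random.Generator | None = None,
                     grouper=None) -> SurrogateNetworkSet:
    """Ensemble of shuffled networks.

    distance_preserving: per distance group the number of connections and
    the bi-/unidirectional ratio are held constant while the connected pairs
    are redrawn within the group.  degree_preserving: degree-preserving
    double-edge swaps on the undirected skeleton, flags redistributed.
    Segregated (disconnected) members are discarded and redrawn until
    ``count`` connected members exist.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = graph.n_nodes
    members: list[np.ndarray] = []
    attempts = 0
    if kind == "distance_preserving":
        groups = _edge_flags(graph, grouper)
        candidates = _group_pairs(graph, grouper)
        while len(members) < count:
            attempts += 1
            adj = np.zeros((n, n), dtype=bool)
            for gname, edges in groups.items():
                cand = candidates[gname]
                pick = rng.choice(len(cand), size=len(edges), replace=False)
                flags = rng.permutation([bi for _, _, bi in edges])
                adj |= _orient(n, [cand[p] for p in pick], flags, rng)
            if _connected(adj):
                members.append(adj)
            _check_acceptance(attempts, len(members), count)
    elif kind == "degree_preserving":
        sk = nx.Graph(nx.from_numpy_array(
            _skeleton_adj(nx.to_numpy_array(graph.digraph, nodelist=graph.nodes,
                                            dtype=bool))))
        n_bi = sum(1 for _, _, bi in
                   (e for edges in _edge_flags(graph).values() for e in edges) if bi)
        n_edges = sk.number_of_edges()
        while len(members) < count:
            attempts += 1
            g = sk.copy()
            try:
                nx.connected_double_edge_swap(g, nswap=max(1, 2 * n_edges),
                                              seed=int(rng.integers(2**31)))
            except nx.NetworkXError:
                continue
            edges = list(g.edges)
            bi_idx = set(rng.choice(len(edges), size=n_bi, replace=False))
            flags = [e in bi_idx for e in range(len(edges))]
            adj = _orient(n, edges, flags, rng)
            if _connected(adj):
                members.append(adj)
            _check_acceptance(attempts, len(members), count)
    else:
        raise ValueError(f"unknown surrogate kind {kind!r}")
    return SurrogateNetworkSet(kind, members, graph.nodes)


def _check_acceptance(attempts, n_ok, count):
    if attempts >= 2000 and n_ok / attempts < 0.001:
        raise RuntimeError(
            f"surrogate acceptance rate {n_ok}/{attempts} below 0.1%; "
            "the network is too fragile to shuffle under these constraints")


# -- small world, modularity ---------------------------------------------

def small_world(graph: ConnectivityGraph, surrogates: SurrogateNetworkSet,
                report: TopologyReport | None = None) -> TopologyReport:
    """SW = (C/C_rand)/(L/L_rand) with surrogate-ensemble means, plus
    empirical p-values of C, L and SW against the member distributions."""
    if report is None:
        report = centralities(graph)
    cs = np.array([clustering_coefficients(a).mean() for a in surrogates.members])
    ls = np.array([characteristic_path_length(a) for a in surrogates.members])
    c_rand = cs.mean()
    l_rand = ls.mean()
    report.SW = (report.C / c_rand) / (report.L / l_rand)
    sw_null = (cs / c_rand) / (ls / l_rand)
    report.C_p = _two_sided_p(report.C, cs)
    report.L_p = _two_sided_p(report.L, ls)
    report.SW_p = _two_sided_p(report.SW, sw_null)
    return report


def _two_sided_p(value, null):
    null = np.asarray(null)
    hi = (1 + np.count_nonzero(null >= value)) / (1 + null.size)
    lo = (1 + np.count_nonzero(null <= value)) / (1 + null.size)
    return float(min(1.0, 2 * min(hi, lo)))


def modularity_q(skeleton: nx.Graph, partition: list[set]) -> float:
    """Exact evaluation of Q on a partition (undirected connections)."""
    m = skeleton.number_of_edges()
    if m == 0:
        return 0.0
    node_mod = {}
    for mi, mod in enumerate(partition):
        for u in mod:
            node_mod[u] = mi
    n_mod = len(partition)
    # e_uu = fraction of links inside module u; the row sum e_u. is the
    # fraction of edge endpoints in u, so Q = sum_u (e_uu - e_u.^2)
    within = np.zeros(n_mod)
    endpoints = np.zeros(n_mod)
    for u, v in skeleton.edges:
        a, b = node_mod[u], node_mod[v]
        if a == b:
            within[a] += 1
        endpoints[a] += 0.5
        endpoints[b] += 0.5
    return float(np.sum(within / m - (endpoints / m) ** 2))


def modularity(graph: ConnectivityGraph, config: RunConfig = DEFAULT_CONFIG,
               rng: np.random.Generator | None = None):
    """Greedy multi-level partition, best of ``modularity_restarts`` seeded
    restarts, Q re-evaluated exactly.  Returns (Q, partition)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sk = graph.skeleton()
    best_q, best_part = -1.0, [set(sk.nodes)]
    for _ in range(config.modularity_restarts):
        part = nx.community.louvain_communities(
            sk, seed=int(rng.integers(2**31)))
        q = modularity_q(sk, part)
        if q > best_q:
            best_q, best_part = q, [set(p) for p in part]
    single = modularity_q(sk, [set(sk.nodes)])
    if single > best_q:  # optimization sanity floor
        best_q, best_part = single, [set(sk.nodes)]
    return best_q, best_part


def modularity_significance(graph: ConnectivityGraph, q: float,
                            surrogates: SurrogateNetworkSet,
                            config: RunConfig = DEFAULT_CONFIG,
                            rng: np.random.Generator | None = None) -> float:
    """Permutation p-value of Q against the surrogate-network ensemble."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    null = []
    for adj in surrogates.members:
        g = nx.from_numpy_array(_skeleton_adj(adj))
        part = nx.community.louvain_communities(g, seed=int(rng.integers(2**31)))
        null.append(modularity_q(g, part))
    null = np.asarray(null)
    return float((1 + np.count_nonzero(null >= q)) / (1 + null.size))


def module_composition(partition: list[set], areas: dict[str, str],
                       n_permutations: int = 1000,
                       rng: np.random.Generator | None = None):
    """Largest-area proportion per module and its permutation p-value
    (area labels shuffled across nodes)."""
    if rng is None:
        rng = np.random.default_rng(0)
    nodes = [u for mod in partition for u in mod]
    labels = np.array([areas[u] for u in nodes])
    sizes = [len(mod) for mod in partition]

    def largest_props(lab):
        props = []
        i = 0
        for s in sizes:
            seg = lab[i:i + s]
            _, counts = np.unique(seg, return_counts=True)
            props.append(counts.max() / s)
            i += s
        return np.mean(props)

    real = largest_props(labels)
    null = np.array([largest_props(rng.permutation(labels))
                     for _ in range(n_permutations)])
    p = (1 + np.count_nonzero(null >= real)) / (1 + null.size)
    per_module = []
    i = 0
    for s in sizes:
        seg = labels[i:i + s]
        vals, counts = np.unique(seg, return_counts=True)
        per_module.append((vals[np.argmax(counts)], counts.max() / s))
        i += s
    return {"mean_largest_proportion": float(real), "p_value": float(p),
            "per_module": per_module}


# -- rich club -----------------------------------------------------------

def rich_club_curve(adj: np.ndarray, min_nodes: int = 5) -> pd.DataFrame:
    """R(k) = 2 E_{>=k} / (N_{>=k}(N_{>=k}-1)) over the undirected skeleton,
    for k where at least ``min_nodes`` nodes qualify."""
    sk = _skeleton_adj(adj)
    k = sk.sum(axis=1)
    rows = []
    for level in range(1, int(k.max()) + 1):
        sel = k >= level
        m = int(sel.sum())
        if m < max(min_nodes, 2):
            break
        e = int(sk[np.ix_(sel, sel)].sum()) // 2
        rows.append((level, m, e, 2.0 * e / (m * (m - 1))))
    return pd.DataFrame(rows, columns=["k", "n_nodes", "n_edges", "R"])


def rich_club(graph: ConnectivityGraph, surrogates: SurrogateNetworkSet,
              config: RunConfig = DEFAULT_CONFIG,
              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Rich-club curve with degree-preserving surrogate normalization and
    cluster-based permutation significance across k."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    real = rich_club_curve(nx.to_numpy_array(graph.digraph, nodelist=graph.nodes,
                                             dtype=bool),
                           config.rich_club_min_nodes)
    ks = real["k"].to_numpy()
    surr = np.full((surrogates.n_members, ks.size), np.nan)
    for i, adj in enumerate(surrogates.members):
        c = rich_club_curve(adj, min_nodes=1).set_index("k")["R"]
        surr[i] = [c.get(k, np.nan) for k in ks]
    surr_mean = np.nanmean(surr, axis=0)
    real = real.assign(R_surr=surr_mean, R_norm=real["R"].to_numpy() / surr_mean)
    # significance: real curve vs surrogate curves, cluster test across k
    valid = np.isfinite(surr).all(axis=1)
    if valid.sum() >= 2 and ks.size >= 1:
        clusters = cluster_permutation_test(
            np.tile(real["R"].to_numpy(), (2, 1)), surr[valid],
            n_permutations=min(config.n_permutations, 500), rng=rng)
        sig = np.zeros(ks.size, dtype=bool)
        for c in clusters:
            if c.p_value < 0.05:
                sig[c.start:c.stop + 1] = True
        real = real.assign(significant=sig)
    else:
        real = real.assign(significant=False)
    return real


# -- heavy-tail model fitting --------------------------------------------

@dataclass
class ModelFit:
    model: str
    params: dict
    adj_r2: float
    fitted: np.ndarray | None = None


def _adj_r2(y, yhat, n_params):
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    n = y.size
    if n - n_params - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


_MODELS = {
    "PL": (lambda k, A, g: A * k ** (-g), 2),
    "EXP": (lambda k, A, kc: A * np.exp(-k / kc), 2),
    # truncated power law with a decaying exponential cutoff
    "EXPTPL": (lambda k, A, g, kc: A * k ** (g - 1.0) * np.exp(-k / kc), 3),
    "GAUS": (lambda k, A, mu, s: A * np.exp(-((k - mu) ** 2) / (2 * s ** 2)), 3),
}


def exptpl_pdf(k: np.ndarray, gamma: float, kc: float) -> np.ndarray:
    """Unnormalized EXPTPL density k^(gamma-1) exp(-k/kc)."""
    k = np.asarray(k, dtype=float)
    return k ** (gamma - 1.0) * np.exp(-k / kc)


def degree_distribution(deg_sets: list[np.ndarray], normalize_pct: bool = False,
                        n_bins: int | None = None):
    """Average AUC-normalized degree distribution across datasets.

    Each dataset's degrees are binned (integer degrees, or percent of the
    possible maximum when ``normalize_pct``), the area under each histogram
    is normalized to 100%, then histograms are averaged.
    """
    if normalize_pct:
        vals = [100.0 * np.asarray(d) / (len(d) - 1) for d in deg_sets]
        hi = max(v.max() for v in vals)
        edges = np.linspace(0, hi + 1e-9, (n_bins or 20) + 1)
    else:
        vals = [np.asarray(d, dtype=float) for d in deg_sets]
        hi = int(max(v.max() for v in vals))
        edges = np.arange(0.5, hi + 1.5)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hists = []
    for v in vals:
        h, _ = np.histogram(v, bins=edges)
        area = np.trapezoid(h, centers)
        hists.append(100.0 * h / area if area > 0 else h.astype(float))
    return centers, np.mean(hists, axis=0)


def fit_heavytail_models(x: np.ndarray, y: np.ndarray) -> dict[str, ModelFit]:
    """Least-squares fits of the four candidate degree-distribution models
    (power law, exponential, exponentially truncated power law, Gaussian)
    ranked by adjusted R^2.  ``x`` must be positive."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = x > 0
    x, y = x[keep], y[keep]
    if x.size < 6 or np.ptp(x) == 0:
        raise ValueError("degenerate support: need >= 6 distinct positive points")
    amp = max(y.max(), 1e-12)
    xm = x[np.argmax(y)]
    p0 = {
        "PL": [amp * max(x.min(), 1.0), 1.0],
        "EXP": [amp, max(x.mean(), 1.0)],
        "EXPTPL": [amp, 0.7, max(x.mean(), 1.0)],
        "GAUS": [amp, xm, max(x.std(), 1.0)],
    }
    bounds = {
        "PL": ([0, -10], [np.inf, 20]),
        "EXP": ([0, 1e-6], [np.inf, np.inf]),
        "EXPTPL": ([0, -10, 1e-6], [np.inf, 20, np.inf]),
        "GAUS": ([0, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
    }
    out = {}
    names = {"PL": ("A", "gamma"), "EXP": ("A", "kc"),
             "EXPTPL": ("A", "gamma", "kc"), "GAUS": ("A", "mu", "sigma")}
    for name, (fn, n_params) in _MODELS.items():
        try:
            popt, _ = optimize.curve_fit(fn, x, y, p0=p0[name],
                                         bounds=bounds[name], maxfev=20000)
            yhat = fn(x, *popt)
            out[name] = ModelFit(name, dict(zip(names[name], popt)),
                                 _adj_r2(y, yhat, n_params), yhat)
        except RuntimeError:
            out[name] = ModelFit(name, {}, -np.inf, None)
    return out


def best_model(fits: dict[str, ModelFit]) -> str:
    return max(fits.values(), key=lambda f: f.adj_r2).model


# -- hubs ----------------------------------------------------------------

def classify_hubs(report: TopologyReport, config: RunConfig = DEFAULT_CONFIG
                  ) -> TopologyReport:
    """Hubs by normalized degree and/or betweenness threshold; also records
    the Spearman association between degree and betweenness."""
    k_crit = report.degree_pct >= config.hub_degree_pct
    g_crit = report.betweenness >= config.hub_betweenness
    sel = (k_crit | g_crit) if config.hub_rule == "or" else (k_crit & g_crit)
    report.hubs = [u for u, s in zip(report.node_ids, sel) if s]
    if report.degree.size >= 3:
        r, p = stats.spearmanr(report.degree, report.betweenness)
        report.degree_betweenness_spearman = (float(r), float(p))
    return report


def overlap_permutation_p(set_a: set, set_b: set, universe: list,
                          n_permutations: int = 1000,
                          rng: np.random.Generator | None = None) -> float:
    """P(|A ∩ B_perm| >= |A ∩ B|) with B randomly re-drawn from the universe."""
    if rng is None:
        rng = np.random.default_rng(0)
    universe = list(universe)
    real = len(set_a & set_b)
    nb = len(set_b)
    null = np.array([
        len(set_a & set(rng.choice(universe, size=nb, replace=False)))
        for _ in range(n_permutations)
    ])
    return float((1 + np.count_nonzero(null >= real)) / (1 + null.size))


def distribution_test(real: np.ndarray, surrogate: np.ndarray,
                      n_permutations: int = 1000, alpha: float = 0.05,
                      rng: np.random.Generator | None = None) -> list[Cluster]:
    """Cluster-based permutation comparison of per-dataset normalized
    distributions against surrogate distributions (rows = datasets)."""
    return cluster_permutation_test(real, surrogate, n_permutations, alpha, rng)
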
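"""Graph measures against brute-force oracles, surrogate ensembles,
rich club, model fitting and hub classification."""

import itertools

import networkx as nx
import numpy as np
import pytest

from spikenet import topology as topo
from spikenet.config import RunConfig
from spikenet.connectivity import ConnectivityGraph
from spikenet.data import UnitMeta


def graph_from_adj(adj, areas=None, arrays=None):
    n = adj.shape[0]
    ids = [f"n{i}" for i in range(n)]
    meta = {ids[i]: UnitMeta(ids[i],
                             (areas[i] if areas else "SIM"),
                             (arrays[i] if arrays else 1), i + 1)
            for i in range(n)}
    g = nx.DiGraph()
    g.add_nodes_from(ids)
    for i, j in zip(*np.nonzero(adj)):
        g.add_edge(ids[i], ids[j])
    return ConnectivityGraph(g, meta, [], n)


def bidirectional(und_edges, n):
    adj = np.zeros((n, n), dtype=bool)
    for i, j in und_edges:
        adj[i, j] = adj[j, i] = True
    return adj


# -- brute-force oracles --------------------------------------------------

def brute_shortest_paths(adj):
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    d[adj] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    return d


def brute_betweenness(adj):
    """Directed betweenness by explicit enumeration of all shortest paths."""
    n = adj.shape[0]
    g = nx.from_numpy_array(adj, create_using=nx.DiGraph)
    counts = np.zeros(n)
    for h, j in itertools.permutations(range(n), 2):
        try:
            paths = list(nx.all_shortest_paths(g, h, j))
        except nx.NetworkXNoPath:
            continue
        for i in range(n):
            if i in (h, j):
                continue
            through = sum(1 for p in paths if i in p)
            counts[i] += through / len(paths)
    return counts / ((n - 1) * (n - 2))


def brute_clustering(adj):
    sk = adj | adj.T
    n = sk.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(sk[i])
        k = nb.size
        if k < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(nb, 2) if sk[a, b])
        c[i] = 2 * links / (k * (k - 1))
    return c


class TestCentralities:
    def test_triangle(self):
        g = graph_from_adj(bidirectional([(0, 1), (1, 2), (0, 2)], 3))
        rep = topo.centralities(g)
        assert np.all(rep.degree == 2)
        assert np.all(rep.clustering == 1.0)
        assert rep.C == 1.0 and rep.L == 1.0

    def test_path_graph(self):
        g = graph_from_adj(bidirectional([(0, 1), (1, 2)], 3))
        rep = topo.centralities(g)
        assert rep.betweenness[1] == pytest.approx(1.0)
        assert rep.betweenness[0] == rep.betweenness[2] == 0.0
        assert rep.L == pytest.approx(4 / 3)  # (1+1+2)*2 / 6 ordered pairs

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        adj = rng.random((n, n)) < 0.45
        np.fill_diagonal(adj, False)
        # ensure weak connectivity by adding a ring
        for i in range(n):
            adj[i, (i + 1) % n] = True
        g = graph_from_adj(adj)
        rep = topo.centralities(g)
        d = brute_shortest_paths(adj)
        finite = np.isfinite(d) & ~np.eye(n, dtype=bool)
        assert rep.L == pytest.approx(d[finite].mean())
        np.testing.assert_allclose(rep.betweenness, brute_betweenness(adj),
                                   atol=1e-12)
        np.testing.assert_allclose(rep.clustering, brute_clustering(adj),
                                   atol=1e-12)
        np.testing.assert_allclose(rep.degree, (adj | adj.T).sum(1))

    def test_degree_sum_is_twice_connections(self):
        rng = np.random.default_rng(3)
        adj = rng.random((12, 12)) < 0.3
        np.fill_diagonal(adj, False)
        adj |= np.eye(12, k=1, dtype=bool) | np.eye(12, k=-11, dtype=bool)
        g = graph_from_adj(adj)
        rep = topo.centralities(g)
        assert rep.degree.sum() == 2 * g.skeleton().number_of_edges()

    def test_disconnected_graph_rejected(self):
        adj = bidirectional([(0, 1), (2, 3)], 4)
        with pytest.raises(ValueError):
            graph_from_adj(adj)


class TestModularity:
    def test_single_module_q_zero(self):
        g = graph_from_adj(bidirectional([(0, 1), (1, 2), (0, 2)], 3))
        assert topo.modularity_q(g.skeleton(), [set(g.nodes)]) == pytest.approx(0.0)

    def test_two_cliques_recovered(self):
        edges = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        edges += [(i, j) for i in range(10, 20) for j in range(i + 1, 20)]
        edges.append((0, 10))
        g = graph_from_adj(bidirectional(edges, 20))
        cfg = RunConfig().replace(modularity_restarts=20)
        q, part = topo.modularity(g, cfg, np.random.default_rng(0))
        assert len(part) == 2
        assert {frozenset(p) for p in part} == {
            frozenset(f"n{i}" for i in range(10)),
            frozenset(f"n{i}" for i in range(10, 20))}
        # direct evaluation on the known partition
        expected = topo.modularity_q(g.skeleton(), part)
        assert q == pytest.approx(expected)
        assert 0.4 < q < 0.5

    @pytest.mark.parametrize("seed", range(4))
    def test_q_matches_networkx_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(15, 0.3, seed=seed)
        while not nx.is_connected(g):
            g = nx.gnp_random_graph(15, 0.3, seed=seed + 100)
        part = nx.community.louvain_communities(g, seed=1)
        mine = topo.modularity_q(g, [set(p) for p in part])
        ref = nx.community.modularity(g, part)
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_returned_q_at_least_single_module(self):
        g = graph_from_adj(bidirectional([(0, 1), (1, 2), (2, 3), (3, 0)], 4))
        q, _ = topo.modularity(g, RunConfig().replace(modularity_restarts=5))
        assert q >= 0.0


class TestModuleComposition:
    def test_modules_identical_to_areas(self):
        part = [set(f"a{i}" for i in range(6)), set(f"b{i}" for i in range(6))]
        areas = {f"a{i}": "F5" for i in range(6)}
        areas |= {f"b{i}": "AIP" for i in range(6)}
        out = topo.module_composition(part, areas, 300,
                                      np.random.default_rng(0))
        assert out["mean_largest_proportion"] == 1.0
        assert out["p_value"] < 0.02

    def test_random_labels_not_significant(self):
        rng = np.random.default_rng(1)
        nodes = [f"u{i}" for i in range(40)]
        part = [set(nodes[:20]), set(nodes[20:])]
        areas = {u: ("F5" if rng.random() < 0.5 else "AIP") for u in nodes}
        out = topo.module_composition(part, areas, 300, rng)
        assert out["p_value"] > 0.05

    def test_designed_mixing_recovered(self):
        rng = np.random.default_rng(2)
        nodes = [f"u{i}" for i in range(100)]
        part = [set(nodes[:50]), set(nodes[50:])]
        areas = {}
        for i, u in enumerate(nodes):
            main = "F5" if i < 50 else "AIP"
            other = "AIP" if i < 50 else "F5"
            areas[u] = main if rng.random() < 0.8 else other
        out = topo.module_composition(part, areas, 300, rng)
        assert out["mean_largest_proportion"] == pytest.approx(0.8, abs=0.05)


class TestRichClub:
    def test_clique_with_pendants(self):
        # 5-clique (degrees >= 4) plus pendant nodes hanging off it
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        edges += [(i, 5 + i) for i in range(5)]
        adj = bidirectional(edges, 10)
        rc = topo.rich_club_curve(adj, min_nodes=2)
        r_at = rc.set_index("k")["R"]
        assert r_at[5] == 1.0  # only the clique nodes have degree >= 5
        assert r_at[1] < 1.0

    def test_surrogate_self_normalization_near_one(self):
        rng = np.random.default_rng(3)
        adj = rng.random((30, 30)) < 0.25
        np.fill_diagonal(adj, False)
        adj |= np.roll(np.eye(30, dtype=bool), 1, axis=1)
        g = graph_from_adj(adj)
        surr = topo.shuffle_networks(g, "degree_preserving", 60, rng)
        # a surrogate member normalized by the ensemble is ~1 across k
        member = graph_from_adj(surr.members[0])
        rc = topo.rich_club(member, surr, RunConfig(),
                            np.random.default_rng(4))
        assert np.nanmedian(np.abs(rc["R_norm"] - 1.0)) < 0.2


class TestSurrogateNetworks:
    @pytest.fixture(scope="class")
    def mixed_graph(self):
        rng = np.random.default_rng(5)
        n = 24
        areas = ["F5"] * 12 + ["AIP"] * 12
        arrays = [1] * 6 + [2] * 6 + [3] * 6 + [4] * 6
        adj = np.zeros((n, n), bool)
        for i in range(n):
            for j in range(i + 1, n):
                p = 0.5 if arrays[i] == arrays[j] else (
                    0.25 if areas[i] == areas[j] else 0.12)
                if rng.random() < p:
                    if rng.random() < 0.3:
                        adj[i, j] = adj[j, i] = True
                    elif rng.random() < 0.5:
                        adj[i, j] = True
                    else:
                        adj[j, i] = True
        g = graph_from_adj(adj, areas=areas, arrays=arrays)
        assert nx.is_weakly_connected(g.digraph)
        return g

    def test_distance_preserving_constraints_hold(self, mixed_graph):
        surr = topo.shuffle_networks(mixed_graph, "distance_preserving", 25,
                                     np.random.default_rng(6))
        want = {}
        for gname, edges in topo._edge_flags(mixed_graph).items():
            want[gname] = (len(edges), sum(b for *_, b in edges))
        ids = mixed_graph.nodes
        for adj in surr.members:
            got = {}
            member = graph_from_adj(adj, areas=[mixed_graph.meta[u].area for u in ids],
                                    arrays=[mixed_graph.meta[u].array_id for u in ids])
            for gname, edges in topo._edge_flags(member).items():
                got[gname] = (len(edges), sum(b for *_, b in edges))
            assert got == want  # per-group edge counts and bi/uni ratio

    def test_degree_preserving_keeps_degree_sequence(self, mixed_graph):
        surr = topo.shuffle_networks(mixed_graph, "degree_preserving", 15,
                                     np.random.default_rng(7))
        ref = np.sort(topo.degrees(nx.to_numpy_array(
            mixed_graph.digraph, nodelist=mixed_graph.nodes, dtype=bool)))
        for adj in surr.members:
            np.testing.assert_array_equal(np.sort(topo.degrees(adj)), ref)

    def test_all_members_connected(self, mixed_graph):
        for kind in ("distance_preserving", "degree_preserving"):
            surr = topo.shuffle_networks(mixed_graph, kind, 10,
                                         np.random.default_rng(8))
            for adj in surr.members:
                assert topo._connected(adj)

    def test_member_clustering_spans_original(self):
        rng = np.random.default_rng(9)
        adj = rng.random((25, 25)) < 0.25
        np.fill_diagonal(adj, False)
        adj |= np.roll(np.eye(25, dtype=bool), 1, axis=1)
        g = graph_from_adj(adj)
        surr = topo.shuffle_networks(g, "distance_preserving", 80, rng)
        cs = np.array([topo.clustering_coefficients(a).mean()
                       for a in surr.members])
        c0 = topo.clustering_coefficients(adj).mean()
        p_hi = np.mean(cs >= c0)
        p_lo = np.mean(cs <= c0)
        assert min(p_hi, p_lo) > 0.01  # a random graph sits inside its null

    def test_physical_distance_grouping_agrees_with_categorical(self):
        # electrode-coordinate-based distance shuffling yields a rich-club
        # normalization highly correlated with the categorical grouping
        rng = np.random.default_rng(10)
        n = 30
        areas = ["F5"] * 15 + ["AIP"] * 15
        arrays = [1] * 8 + [2] * 7 + [3] * 8 + [4] * 7
        coords = {}
        for i in range(n):
            base_x = {1: 0.0, 2: 2.0, 3: 20.0, 4: 22.0}[arrays[i]]
            coords[f"n{i}"] = (base_x + 0.4 * (i % 8), 0.4 * (i % 3), areas[i])
        adj = np.zeros((n, n), bool)
        for i in range(n):
            for j in range(i + 1, n):
                p = 0.5 if arrays[i] == arrays[j] else (
                    0.3 if areas[i] == areas[j] else 0.15)
                if rng.random() < p:
                    adj[i, j] = adj[j, i] = True
        g = graph_from_adj(adj, areas=areas, arrays=arrays)
        grouper = topo.physical_distance_grouper(
            coords, step_mm=3.6, max_group_pairs={frozenset(("F5", "AIP"))})
        rc_cat, rc_phys = [], []
        for grp in (None, grouper):
            surr = topo.shuffle_networks(g, "distance_preserving", 60,
                                         np.random.default_rng(11), grouper=grp)
            curve = topo.rich_club_curve(adj, 5).set_index("k")["R"]
            ks = curve.index.to_numpy()
            mean_surr = np.nanmean([
                [topo.rich_club_curve(a, 1).set_index("k")["R"].get(k, np.nan)
                 for k in ks] for a in surr.members], axis=0)
            (rc_cat if grp is None else rc_phys).append(
                curve.to_numpy() / mean_surr)
        r = np.corrcoef(rc_cat[0], rc_phys[0])[0, 1]
        assert r > 0.8


class TestModelFits:
    def test_power_law_recovery(self):
        k = np.arange(1.0, 40.0)
        y = 3.0 * k ** -2.0
        fits = topo.fit_heavytail_models(k, y)
        assert topo.best_model(fits) == "PL"
        assert fits["PL"].params["gamma"] == pytest.approx(2.0, rel=0.05)

    def test_exptpl_limits_to_pl(self):
        k = np.arange(1.0, 30.0)
        y = 2.0 * k ** -0.8
        fits = topo.fit_heavytail_models(k, y)
        # with no truncation in the data, EXPTPL fits as well as PL
        assert fits["EXPTPL"].adj_r2 >= fits["PL"].adj_r2 - 0.02

    def test_gaussian_data_prefers_gaus(self):
        k = np.arange(1.0, 30.0)
        y = 5.0 * np.exp(-0.5 * ((k - 12.0) / 3.0) ** 2)
        fits = topo.fit_heavytail_models(k, y)
        assert topo.best_model(fits) == "GAUS"

    def test_exptpl_shape_recovery(self):
        k = np.arange(1.0, 30.0)
        y = 4.0 * topo.exptpl_pdf(k, 0.6839, 8.657)
        fits = topo.fit_heavytail_models(k, y)
        assert topo.best_model(fits) == "EXPTPL"
        assert fits["EXPTPL"].params["kc"] == pytest.approx(8.657, rel=0.1)

    def test_degenerate_support_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            topo.fit_heavytail_models(np.ones(10), np.ones(10))

    def test_distribution_test_wrapper(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(10, 30))
        b = rng.normal(size=(10, 30))
        b[:, 5:12] += 2.5
        out = topo.distribution_test(a, b, 300, rng=rng)
        assert any(c.p_value < 0.05 for c in out)


class TestHubs:
    def test_star_center_is_hub(self):
        edges = [(0, i) for i in range(1, 9)]
        g = graph_from_adj(bidirectional(edges, 9))
        rep = topo.classify_hubs(topo.centralities(g))
        assert rep.hubs == ["n0"]

    def test_ring_has_no_hubs(self):
        n = 40  # degree is ~5% of possible partners, below the hub cutoff
        edges = [(i, (i + 1) % n) for i in range(n)]
        g = graph_from_adj(bidirectional(edges, n))
        rep = topo.classify_hubs(topo.centralities(g))
        assert rep.hubs == []

    def test_and_rule_stricter_than_or(self):
        rng = np.random.default_rng(13)
        adj = rng.random((25, 25)) < 0.2
        np.fill_diagonal(adj, False)
        adj |= np.roll(np.eye(25, dtype=bool), 1, axis=1)
        g = graph_from_adj(adj)
        rep_or = topo.classify_hubs(topo.centralities(g),
                                    RunConfig().replace(hub_rule="or"))
        rep_and = topo.classify_hubs(topo.centralities(g), RunConfig())
        assert set(rep_and.hubs) <= set(rep_or.hubs)
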
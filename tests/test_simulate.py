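"""Ground-truth simulators: kernels, topologies, dynamics, plane, pair model."""

import numpy as np
import pytest

from spikenet import simulate as sim
from spikenet import topology as topo
from spikenet.data import bin_and_align


class TestKernels:
    def test_gamma_mode_at_a_minus_one_b(self):
        k = sim.gamma_kernel(b=1.0, a=5.0)
        assert int(np.argmax(k)) + 1 == 4  # lags start at t = 1 ms

    @pytest.mark.parametrize("b", [0.2, 1.0, 2.7])
    def test_integral_normalized(self, b):
        k = sim.gamma_kernel(b=b)
        assert k.sum() == pytest.approx(0.02, abs=1e-12)

    def test_invalid_b_rejected(self):
        with pytest.raises(ValueError):
            sim.gamma_kernel(b=0.0)

    def test_boxcar_alternative(self):
        k = sim.boxcar_kernel()
        assert k.size == 20 and k.sum() == pytest.approx(0.02)
        assert np.ptp(k) == 0.0


class TestTopologies:
    def test_sn_degree_distribution_gaussian_best(self):
        rng = np.random.default_rng(50)
        degs = []
        for _ in range(4):
            adj = sim.build_topology("SN", 100, rng).adjacency
            degs.append((adj | adj.T).sum(1))
        x, y = topo.degree_distribution(degs)
        fits = topo.fit_heavytail_models(x, y)
        assert topo.best_model(fits) == "GAUS"

    def test_cn_degree_distribution_exptpl_best(self):
        rng = np.random.default_rng(51)
        degs = []
        for _ in range(4):
            adj = sim.build_topology("CN", 100, rng).adjacency
            degs.append((adj | adj.T).sum(1))
        x, y = topo.degree_distribution(degs)
        fits = topo.fit_heavytail_models(x, y)
        assert topo.best_model(fits) == "EXPTPL"

    def test_zero_connection_request_gives_empty_adjacency(self):
        net = sim.build_topology("SN", 30, np.random.default_rng(52),
                                 out_mean=0.0, out_sd=0.0)
        assert net.adjacency.sum() == 0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            sim.build_topology("SN", 5)

    def test_truth_pair_sets(self):
        adj = np.zeros((4, 4), bool)
        adj[0, 1] = adj[1, 0] = True     # bidirectional 0-1
        adj[0, 2] = adj[0, 3] = True     # common source 0 for (2, 3)
        net = sim.GroundTruthNetwork("SN", adj, {}, np.zeros(4))
        assert net.bidirectional_pairs() == [(0, 1)]
        # units 1, 2, 3 all receive from unit 0 and are mutually
        # unconnected, so every pairing among them is common drive
        assert net.common_drive_pairs() == [(1, 2), (1, 3), (2, 3)]


class TestEqualRate:
    def test_empty_adjacency_realizes_target_rates(self):
        rng = np.random.default_rng(53)
        net = sim.GroundTruthNetwork("SN", np.zeros((20, 20), bool), {},
                                     np.zeros(20))
        rates = np.full(20, 8.0 / 1000.0)
        net = sim.simulate_equal_rate(net, rng, n_trials=150,
                                      calibration_trials=40, rates=rates)
        assert net.realized_rates.mean() == pytest.approx(8.0 / 1000.0,
                                                          rel=0.02)

    def test_deflation_converges_within_two_percent(self, sn_fixture):
        target = sn_fixture.target_rates.mean()
        realized = sn_fixture.realized_rates.mean()
        assert abs(realized - target) / target < 0.02
        assert sn_fixture.rate_correlation > 0.95

    def test_injected_kernel_recovered_in_cch(self):
        # single edge A -> B: the corrected CCH's positive-lag part
        # reproduces the transfer kernel shape
        from spikenet.cch import CCHEngine
        from spikenet.config import RunConfig
        rng = np.random.default_rng(54)
        adj = np.zeros((2, 2), bool)
        adj[0, 1] = True
        net = sim.GroundTruthNetwork("SN", adj, {}, np.zeros(2))
        net = sim.simulate_equal_rate(net, rng, n_trials=400,
                                      calibration_trials=60,
                                      rates=np.full(2, 8.0 / 1000.0))
        kern = net.kernels[(0, 1)]
        binned = bin_and_align(net.dataset)
        eng = CCHEngine(binned, RunConfig())
        eng.make_surrogates(40, rng)
        corrected, _ = eng.corrected_pair(0, 1)
        lags = eng.lags
        # equally processed template: the kernel smoothed like the CCH
        from spikenet.data import smooth_hist
        template = np.zeros_like(corrected)
        template[np.isin(lags, np.arange(1, kern.size + 1))] = kern
        template = smooth_hist(template, 3.66)
        sel = (lags >= -10) & (lags <= kern.size + 10)
        r = np.corrcoef(corrected[sel], template[sel])[0, 1]
        assert r > 0.8

    def test_deterministic_under_seed(self):
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(55)
            net = sim.build_topology("SN", 20, rng)
            net = sim.simulate_equal_rate(net, rng, n_trials=30,
                                          calibration_trials=20)
            outs.append(net.dataset.spikes)
        import pandas as pd
        pd.testing.assert_frame_equal(outs[0], outs[1])


class TestPlane:
    @pytest.mark.parametrize("n,p,expect", [(5, 1, 0.0), (5, 5, 1.0),
                                            (5, 3, 0.5)])
    def test_compartmentalization_formula(self, n, p, expect):
        assert sim.compartmentalization(n, p) == pytest.approx(expect)

    def test_subsample_size_exact(self):
        plane = sim.NeuronalPlane(per_electrode=2)
        rng = np.random.default_rng(56)
        idx = plane.subsample_indices(70, rng)
        assert idx.size == 70
        area, sub, _ = plane.coords(idx)
        assert set(area) == {0, 1}
        for a in (0, 1):
            assert len(set(sub[area == a])) == 2

    def test_group_densities_within_binomial_tolerance(self):
        plane = sim.NeuronalPlane(per_electrode=4)
        rng = np.random.default_rng(57)
        idx = plane.subsample_indices(120, rng)
        g = plane.group_matrix(idx)
        adj = plane.realize_adjacency(idx, rng)
        iu = np.triu_indices(idx.size, 1)
        for code, name in [(1, "same_array"), (2, "same_area"),
                           (3, "inter_area")]:
            mask = g[iu] == code
            n_pairs = int(mask.sum())
            if n_pairs < 50:
                continue
            p = plane.densities[{1: "same_array", 2: "same_area",
                                 3: "inter_area"}[code]]
            got = adj[iu][mask].mean()
            assert abs(got - p) < 4 * np.sqrt(p * (1 - p) / n_pairs)

    def test_full_scale_subsample_degree_is_gaussian_not_powerlaw(self):
        # electrode-configuration subsampling of the random plane does not
        # fake a heavy tail: Gaussian fits best, the power law clearly worse
        plane = sim.NeuronalPlane(per_electrode=2)
        rng = np.random.default_rng(58)
        degs = []
        for size in (70, 64, 78, 57, 64, 47):
            idx = plane.subsample_indices(size, rng)
            degs.append(plane.realize_adjacency(idx, rng).sum(1))
        x, y = topo.degree_distribution(degs, normalize_pct=True, n_bins=15)
        fits = topo.fit_heavytail_models(x, y)
        assert topo.best_model(fits) == "GAUS"
        assert fits["GAUS"].adj_r2 - fits["PL"].adj_r2 > 0.1

    def test_component_stats_reduced_plane(self):
        plane = sim.NeuronalPlane(per_electrode=1, density_scale=1.0)
        out = sim.plane_component_stats(plane, np.random.default_rng(59))
        assert out["largest_component_fraction"] > 0.99
        assert out["compartmentalization"] < 0.01

    def test_low_density_fragments_plane(self):
        plane = sim.NeuronalPlane(per_electrode=1, density_scale=0.02)
        out = sim.plane_component_stats(plane, np.random.default_rng(60))
        assert out["largest_component_fraction"] < 1.0


class TestPairModel:
    def test_rate_near_five_hz(self):
        rng = np.random.default_rng(61)
        ds = sim.simulate_pair("oscillatory", 0.0, rng, n_trials=120)
        b = bin_and_align(ds)
        rate = 1000.0 * np.concatenate(
            [b.cue.reshape(2, -1), b.movement.reshape(2, -1)], axis=1).mean()
        assert rate == pytest.approx(5.0, abs=0.5)

    def test_zero_jitter_side_lobes_at_period(self):
        from spikenet.cch import CCHEngine
        from spikenet.config import RunConfig
        rng = np.random.default_rng(62)
        ds = sim.simulate_pair("oscillatory", 0.0, rng, n_trials=250)
        eng = CCHEngine(bin_and_align(ds), RunConfig())
        eng.make_surrogates(30, rng)
        corrected, _ = eng.corrected_pair(0, 1)
        lags = eng.lags
        center = corrected[np.abs(lags) <= 10].max()
        lobe = corrected[(np.abs(lags) >= 40) & (np.abs(lags) <= 60)].max()
        trough = corrected[(np.abs(lags) >= 20) & (np.abs(lags) <= 30)].min()
        assert center > 0 and lobe > 0 > trough
        assert lobe > 0.4 * center

    def test_jitter_bounds_enforced(self):
        with pytest.raises(ValueError):
            sim.simulate_pair("oscillatory", 60.0)

    def test_peak_decay_and_kind_matching(self):
        # coupling strength is set by the jitter alone: peaks decay with
        # jitter for BOTH kinds and match between kinds at equal jitter
        from spikenet.cch import CCHEngine
        from spikenet.config import RunConfig

        def peak(kind, jitter, seed):
            rng = np.random.default_rng(seed)
            ds = sim.simulate_pair(kind, jitter, rng, n_trials=300)
            eng = CCHEngine(bin_and_align(ds), RunConfig())
            eng.make_surrogates(20, rng)
            raw = eng.pair_raw(0, 1)
            mem = eng.pair_members(0, 1)
            corr = raw - mem.mean(0)
            w = np.abs(eng.lags) <= 25
            return corr[w].max()

        peaks = {}
        for kind in ("oscillatory", "non_oscillatory"):
            peaks[kind] = [np.mean([peak(kind, j, 63 + r) for r in range(3)])
                           for j in (0.0, 25.0, 50.0)]
            assert peaks[kind][0] > peaks[kind][1] > 0
            assert peaks[kind][0] > peaks[kind][2]
        for i in range(3):
            ratio = peaks["oscillatory"][i] / peaks["non_oscillatory"][i]
            assert 0.7 < ratio < 1.4


class TestScoring:
    def test_perfect_detection(self):
        rng = np.random.default_rng(64)
        net = sim.build_topology("SN", 20, rng)
        rep = sim.score_detection(net, net.adjacency.copy())
        assert rep.directed["miss"] == rep.directed["fa"] == 0
        assert rep.undirected["hit"] > 0 and rep.undirected["miss"] == 0
        assert rep.direction_given_detection["miss"] == 0
        assert rep.direction_given_detection["fa"] == 0

    def test_empty_detection(self):
        rng = np.random.default_rng(65)
        net = sim.build_topology("SN", 20, rng)
        rep = sim.score_detection(net, np.zeros_like(net.adjacency))
        assert rep.directed["hit"] == rep.directed["fa"] == 0
        assert rep.directed["cr"] > 0
        s = rep.summary()
        assert s.loc[s.level == "directed", "hit_pct"].iloc[0] == 0.0

    def test_confusion_counts_partition_pairs(self):
        rng = np.random.default_rng(66)
        net = sim.build_topology("SN", 25, rng)
        detected = net.adjacency.copy()
        detected[rng.random(detected.shape) < 0.1] ^= True
        np.fill_diagonal(detected, False)
        rep = sim.score_detection(net, detected)
        n = net.n
        d = rep.directed
        assert d["hit"] + d["miss"] + d["cr"] + d["fa"] == n * (n - 1)
        u = rep.undirected
        assert u["hit"] + u["miss"] + u["cr"] + u["fa"] == n * (n - 1) // 2

    def test_node_mismatch_rejected(self):
        rng = np.random.default_rng(67)
        net = sim.build_topology("SN", 20, rng)
        with pytest.raises(ValueError):
            sim.score_detection(net, np.zeros((21, 21), bool))
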
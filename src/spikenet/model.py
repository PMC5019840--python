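"""statsmodels-style entry point: fit the functional network of a dataset.

``FunctionalConnectivityModel`` wraps the full pipeline -- correlograms,
surrogate correction, cluster statistics, FDR, direction classification,
graph construction, topology, optionally spectra and rate prediction --
behind a ``fit()`` that returns a :class:`FunctionalNetworkResult` carrying
the estimates, their permutation-based uncertainties and a ``summary()``
table.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import connectivity, prediction, spectra, topology
from .cch import CCHEngine
from .config import RunConfig, DEFAULT_CONFIG
from .data import SpikeDataset, bin_and_align, load_dataset

log = logging.getLogger(__name__)


class FunctionalConnectivityModel:
    """Functional single-neuron network model of one spike dataset.

    Parameters
    ----------
    dataset : SpikeDataset
        Trial-structured spike trains with unit metadata and task events.
    config : RunConfig
        Analysis parameters; defaults reproduce the reference conditions.
    """

    def __init__(self, dataset: SpikeDataset, config: RunConfig = DEFAULT_CONFIG):
        self.dataset = dataset
        self.config = config

    @classmethod
    def from_tables(cls, spikes_path, trials_path, units_path,
                    config: RunConfig = DEFAULT_CONFIG):
        return cls(load_dataset(spikes_path, trials_path, units_path), config)

    def fit(self, seed: int | None = None, n_surrogates: int | None = None,
            n_network_surrogates: int | None = None,
            stages: tuple = ("connectivity", "topology"),
            n_permutations: int | None = None,
            keep_engine: bool = False) -> "FunctionalNetworkResult":
        """Run the pipeline stages in order and collect the results.

        ``stages`` may include "connectivity", "topology", "spectra" and
        "prediction"; later stages require the earlier ones.  A failed
        stage marks the result partial and skips downstream stages.
        """
        cfg = self.config
        if seed is None:
            seed = cfg.seed
        rng = np.random.default_rng(seed)
        res = FunctionalNetworkResult(model=self, config=cfg, seed=seed)
        t0 = time.time()
        res.binned = bin_and_align(self.dataset, cfg)
        want = list(stages)
        try:
            res.detection = connectivity.analyze_pairs(
                res.binned, cfg, rng, n_surrogates=n_surrogates,
                keep_engine=keep_engine or ("spectra" in want))
            res.graph = connectivity.build_graph(res.detection,
                                                 self.dataset.unit_meta())
            res.stages_done.append("connectivity")
        except Exception:
            log.exception("connectivity stage failed; result is partial")
            res.partial = True
            return res
        n_net = n_network_surrogates or cfg.n_network_surrogates
        n_perm = n_permutations or cfg.n_permutations
        if "topology" in want and not res.partial:
            try:
                rep = topology.centralities(res.graph)
                dist_surr = topology.shuffle_networks(
                    res.graph, "distance_preserving", n_net, rng)
                rep = topology.small_world(res.graph, dist_surr, rep)
                rep.Q, rep.partition = topology.modularity(res.graph, cfg, rng)
                rep.Q_p = topology.modularity_significance(
                    res.graph, rep.Q,
                    topology.shuffle_networks(res.graph, "degree_preserving",
                                              min(n_net, 200), rng),
                    cfg, rng)
                deg_surr = topology.shuffle_networks(
                    res.graph, "degree_preserving", n_net, rng)
                rep.rich_club = topology.rich_club(res.graph, deg_surr, cfg, rng)
                rep = topology.classify_hubs(rep, cfg)
                res.topology = rep
                res.module_composition = topology.module_composition(
                    rep.partition,
                    {u: res.graph.meta[u].area for u in res.graph.nodes},
                    n_permutations=n_perm, rng=rng)
                res.stages_done.append("topology")
            except Exception:
                log.exception("topology stage failed; result is partial")
                res.partial = True
        if "spectra" in want and not res.partial:
            try:
                res.ach_spectra, res.cch_spectra = self._spectra(res, rng)
                res.oscillators = spectra.classify_oscillators(res.ach_spectra, cfg)
                res.stages_done.append("spectra")
            except Exception:
                log.exception("spectra stage failed; result is partial")
                res.partial = True
        if "prediction" in want and not res.partial:
            try:
                res.prediction = prediction.predict_all(
                    res.detection, res.binned,
                    n_permutations=min(n_perm, 200), rng=rng, config=cfg)
                res.stages_done.append("prediction")
            except Exception:
                log.exception("prediction stage failed; result is partial")
                res.partial = True
        res.wall_clock_s = time.time() - t0
        return res

    def _spectra(self, res, rng):
        cfg = self.config
        engine: CCHEngine = res.detection.engine
        if engine is None:
            raise RuntimeError("spectra need the retained CCH engine")
        unit_ids = res.detection.unit_ids
        lags = res.detection.lags
        ach = {}
        for i, u in enumerate(unit_ids):
            out = engine.corrected_pair(i, i)
            if out is None:
                continue
            corrected, ens = out
            ach[u] = spectra.spectrum_significance(
                corrected, ens.members, lags, "ACH", source=u, config=cfg)
        cch = {}
        sig_pairs = {tuple(sorted((e.source, e.target))) for e in res.detection.edges}
        for (ua, ub) in sig_pairs:
            pr = res.detection.pairs.get((ua, ub)) or res.detection.pairs[(ub, ua)]
            a = unit_ids.index(pr.unit_a)
            b = unit_ids.index(pr.unit_b)
            out = engine.corrected_pair(a, b)
            if out is None:
                continue
            corrected, ens = out
            cch[(pr.unit_a, pr.unit_b)] = spectra.spectrum_significance(
                corrected, ens.members, lags, "CCH",
                source=f"{pr.unit_a}~{pr.unit_b}", config=cfg)
        return ach, cch


@dataclass
class FunctionalNetworkResult:
    """Fitted functional network with topology and diagnostics."""

    model: FunctionalConnectivityModel
    config: RunConfig
    seed: int
    binned: object | None = None
    detection: object | None = None
    graph: object | None = None
    topology: object | None = None
    module_composition: dict | None = None
    ach_spectra: dict | None = None
    cch_spectra: dict | None = None
    oscillators: pd.DataFrame | None = None
    prediction: pd.DataFrame | None = None
    stages_done: list = field(default_factory=list)
    partial: bool = False
    wall_clock_s: float = np.nan

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        lines = ["Functional network fit", "=" * 54]
        ds = self.model.dataset
        lines.append(f"units: {ds.n_units}   trials: {ds.n_trials}   "
                     f"spikes: {len(ds.spikes)}")
        if self.detection is not None:
            n_edges = len(self.detection.edges)
            n_bi = sum(e.bidirectional for e in self.detection.edges)
            lines.append(f"significant connections: {n_edges} "
                         f"({n_bi} bidirectional)")
        if self.graph is not None:
            g = self.graph
            lines.append(f"largest component: {g.n_nodes}/{g.n_total} units "
                         f"({100 * g.dropped_fraction:.1f}% dropped)")
        t = self.topology
        if t is not None:
            lines.append(f"density: {100 * t.density:.2f}%   "
                         f"C = {t.C:.3f} (p={t.C_p:.3g})   "
                         f"L = {t.L:.3f} (p={t.L_p:.3g})")
            lines.append(f"small-world SW = {t.SW:.2f} (p={t.SW_p:.3g})   "
                         f"modularity Q = {t.Q:.3f} (p={t.Q_p:.3g}, "
                         f"{len(t.partition or [])} modules)")
            if t.hubs is not None:
                r, p = t.degree_betweenness_spearman or (np.nan, np.nan)
                lines.append(f"hubs: {len(t.hubs)}/{t.degree.size} "
                             f"(degree-betweenness Spearman r={r:.2f}, p={p:.3g})")
            if t.rich_club is not None and len(t.rich_club):
                rc = t.rich_club
                sig = rc["significant"].any() if "significant" in rc else False
                lines.append(f"rich club: max normalized R = "
                             f"{np.nanmax(rc['R_norm']):.2f}"
                             f"{' (significant)' if sig else ''}")
        if self.module_composition is not None:
            mc = self.module_composition
            lines.append(f"module area dominance: "
                         f"{100 * mc['mean_largest_proportion']:.1f}% "
                         f"(p={mc['p_value']:.3g})")
        if self.oscillators is not None:
            counts = self.oscillators["label"].value_counts().to_dict()
            lines.append(f"oscillators: {counts}")
        if self.prediction is not None and len(self.prediction):
            frac_pos = float((self.prediction["correlation"] > 0).mean())
            frac_sig = float(self.prediction["significant"].mean())
            lines.append(f"rate prediction: {100 * frac_pos:.0f}% positively "
                         f"correlated, {100 * frac_sig:.0f}% significant")
        if self.partial:
            lines.append(f"PARTIAL RESULT (completed: {self.stages_done})")
        return "\n".join(lines)

    def to_json(self) -> str:
        out = {"seed": self.seed, "stages": self.stages_done,
               "partial": self.partial, "wall_clock_s": self.wall_clock_s,
               "config": json.loads(self.config.to_json())}
        if self.detection is not None:
            out["n_edges"] = len(self.detection.edges)
        t = self.topology
        if t is not None:
            out["topology"] = {
                "n_nodes": len(t.node_ids), "density": t.density,
                "C": t.C, "L": t.L, "SW": t.SW, "Q": t.Q,
                "n_hubs": len(t.hubs or []),
            }
        return json.dumps(out, sort_keys=True)

    # -- simulation / plotting hooks -------------------------------------
    def simulate_surrogate_networks(self, kind="distance_preserving",
                                    count=100, rng=None):
        return topology.shuffle_networks(self.graph, kind, count, rng)

    def plot_degree_distribution(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = topology.degree_distribution([self.topology.degree])
        ax.plot(x, y, "o-")
        ax.set_xlabel("degree k")
        ax.set_ylabel("% of units (AUC-normalized)")
        return ax

    def plot_rich_club(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rc = self.topology.rich_club
        ax.plot(rc["k"], rc["R_norm"], "o-")
        ax.axhline(1.0, color="k", ls=":")
        ax.set_xlabel("degree level k")
        ax.set_ylabel("normalized rich club R/R_surr")
        return ax
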
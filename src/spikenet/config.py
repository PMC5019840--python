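"""Run configuration: every tunable of the pipeline with its default.

Defaults reproduce the analysis conditions the pipeline was designed for
(1 ms bins, +/-500 ms correlograms, +/-200 ms test window, z threshold 2,
1000 surrogates, Gaussian smoothing SD 3.66 ms, FDR q = 0.05, ...).  A
config instance is serialized verbatim into every output manifest so that
two runs with equal config and inputs are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    # binning / alignment
    bin_ms: float = 1.0
    cue_window_ms: tuple[float, float] = (-700.0, 1500.0)
    movement_window_ms: tuple[float, float] = (-300.0, 500.0)

    # correlograms
    max_lag_ms: int = 500
    smooth_sd_ms: float = 3.66
    n_surrogates: int = 1000

    # cluster statistics
    test_window_ms: int = 200
    z_threshold: float = 2.0
    fdr_q: float = 0.05

    # direction classification
    bidirectional_max_peak_ms: float = 2.0
    direction_rule: str = "max_peak"  # fixed rule; threshold above is swept in tests

    # topology
    n_network_surrogates: int = 1000
    rich_club_min_nodes: int = 5
    hub_degree_pct: float = 9.0
    hub_betweenness: float = 0.03
    hub_rule: str = "and"  # "and" | "or"
    modularity_restarts: int = 100
    small_world_null: str = "distance_preserving"  # or "configuration"

    # spectra
    n_frequencies: int = 100
    freq_lo_hz: float = 3.0
    freq_hi_hz: float = 100.0
    beta_band_hz: tuple[float, float] = (18.0, 35.0)
    low_band_hz: tuple[float, float] = (3.0, 7.0)
    gamma_band_hz: tuple[float, float] = (45.0, 80.0)
    cch_window_max_ms: float = 1000.0
    cch_window_min_ms: float = 150.0
    ach_window_max_ms: float = 500.0
    ach_window_min_ms: float = 75.0
    excise_ms: float = 5.0

    # permutation counts
    n_permutations: int = 1000

    # prediction
    prediction_kernel_lag_ms: int = 200
    prediction_report_smooth_ms: float = 40.0
    trial_shuffle_joint: bool = True

    # reproducibility
    seed: int = 0

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_overrides(cls, overrides: dict[str, str] | None = None) -> "RunConfig":
        """Build a config from ``key=value`` string overrides (CLI `--set`)."""
        cfg = cls()
        if not overrides:
            return cfg
        kw = {}
        for key, raw in overrides.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key: {key}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                kw[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kw[key] = int(raw)
            elif isinstance(current, float):
                kw[key] = float(raw)
            elif isinstance(current, tuple):
                kw[key] = tuple(float(x) for x in raw.split(","))
            else:
                kw[key] = raw
        return cfg.replace(**kw)


DEFAULT_CONFIG = RunConfig()
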
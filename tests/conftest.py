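"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest

from spikenet import simulate as sim
from spikenet.config import RunConfig
from spikenet.data import SpikeDataset, bin_and_align
from spikenet import connectivity


@pytest.fixture(scope="session")
def config():
    return RunConfig()


def poisson_dataset(n_units, n_trials, rate_hz, seed, trial_len=3100,
                    cue=700.0, mov=2600.0, conditions=("power_instructed",)):
    """Homogeneous Poisson population with the standard trial layout."""
    rng = np.random.default_rng(seed)
    units = pd.DataFrame({
        "unit_id": [f"u{i:03d}" for i in range(n_units)],
        "area": "SIM", "array_id": 1,
        "electrode_id": np.arange(1, n_units + 1)})
    trials = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "condition": [conditions[i % len(conditions)] for i in range(n_trials)],
        "cue_onset_ms": cue, "movement_onset_ms": mov})
    rows_u, rows_i, rows_t = [], [], []
    rates = np.broadcast_to(np.asarray(rate_hz, dtype=float), (n_units,))
    for u in range(n_units):
        counts = rng.poisson(rates[u] * trial_len / 1000.0, size=n_trials)
        for i, c in enumerate(counts):
            t = np.sort(rng.uniform(0, trial_len, size=c))
            rows_u.append(np.full(c, u)); rows_i.append(np.full(c, i))
            rows_t.append(t)
    spikes = pd.DataFrame({
        "unit_id": [f"u{k:03d}" for k in np.concatenate(rows_u)],
        "trial_id": np.concatenate(rows_i).astype(int),
        "time_ms": np.concatenate(rows_t)})
    return SpikeDataset(units, trials, spikes)


@pytest.fixture(scope="session")
def tiny_dataset():
    return poisson_dataset(3, 8, 20.0, seed=0)


@pytest.fixture(scope="session")
def sn_fixture():
    rng = np.random.default_rng(101)
    net = sim.build_topology("SN", n=30, rng=rng)
    return sim.simulate_equal_rate(net, rng, n_trials=150,
                                   calibration_trials=60)


@pytest.fixture(scope="session")
def cn_fixture():
    rng = np.random.default_rng(202)
    net = sim.build_topology("CN", n=30, rng=rng)
    return sim.simulate_equal_rate(net, rng, n_trials=150,
                                   calibration_trials=60)


@pytest.fixture(scope="session")
def sn_detection(sn_fixture, config):
    rng = np.random.default_rng(7)
    binned = bin_and_align(sn_fixture.dataset, config)
    return connectivity.analyze_pairs(binned, config, rng, n_surrogates=60)


@pytest.fixture(scope="session")
def cn_detection(cn_fixture, config):
    rng = np.random.default_rng(8)
    binned = bin_and_align(cn_fixture.dataset, config)
    return connectivity.analyze_pairs(binned, config, rng, n_surrogates=60)
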
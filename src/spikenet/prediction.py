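"""Firing-rate prediction from detected functional inputs.

Every corrected CCH doubles as a spike-rate transfer function: its positive
lags describe how target spiking follows input spiking.  A unit's rate is
predicted by convolving each significant input unit's spike train with the
input->target output part of their corrected CCH (lags (0, +200] ms,
nothing fitted), summing over inputs, and correlating the summed signal
with the target's Gaussian-smoothed train (SD 3.66 ms, identical to the
CCH smoothing) over the concatenated analysis segments.

Three permutation schemes guard against trivial explanations: shuffling of
trials (breaks within-trial timing while keeping event-locked structure),
shuffling of the transfer kernels among inputs, and replacement of the
input units by random non-input units.  A prediction counts as significant
only if its correlation exceeds all applicable null distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .config import RunConfig, DEFAULT_CONFIG
from .connectivity import NetworkDetection
from .data import BinnedSegments, smooth_hist

log = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    target: str
    inputs: list[str]
    correlation: float
    p_trials: float = np.nan
    p_kernels: float = np.nan
    p_inputs: float = np.nan
    condition_correlation: float = np.nan
    p_cond_kernels: float = np.nan
    p_cond_inputs: float = np.nan

    @property
    def significant(self) -> bool:
        ps = [self.p_trials, self.p_kernels, self.p_inputs]
        return all(np.isfinite(p) and p < 0.05 for p in ps)

    @property
    def condition_significant(self) -> bool:
        ps = [self.p_cond_kernels, self.p_cond_inputs]
        return all(np.isfinite(p) and p < 0.05 for p in ps)


def input_kernels(detection: NetworkDetection, target: str,
                  config: RunConfig = DEFAULT_CONFIG) -> dict[str, np.ndarray]:
    """Output-part kernels (lag 1..L ms) of every significant input."""
    L = int(config.prediction_kernel_lag_ms)
    lags = detection.lags
    kernels: dict[str, np.ndarray] = {}
    for e in detection.edges:
        if e.target == target:
            src = e.source
        elif e.bidirectional and e.source == target:
            src = e.target
        else:
            continue
        key = (src, target) if (src, target) in detection.pairs else (target, src)
        pr = detection.pairs[key]
        if key[0] == src:   # positive lags carry src -> target
            sel = (lags >= 1) & (lags <= L)
            kern = pr.corrected[sel]
        else:               # src -> target influence sits at negative lags
            sel = (lags <= -1) & (lags >= -L)
            kern = pr.corrected[sel][::-1]
        kernels[src] = kern
    return kernels


def _convolve_inputs(binned: BinnedSegments, unit_kernels: dict[str, np.ndarray],
                     trial_order: np.ndarray | None = None) -> np.ndarray:
    """Summed input convolution, per segment, concatenated (n_trials, total)."""
    uidx = {u: i for i, u in enumerate(binned.unit_ids)}
    parts = []
    for seg_name in ("cue", "movement"):
        seg = binned.segment(seg_name)
        n_bins = seg.shape[2]
        acc = np.zeros((binned.n_trials, n_bins))
        for u, kern in unit_kernels.items():
            x = seg[uidx[u]].astype(float)
            if trial_order is not None:
                x = x[trial_order]
            conv = fftconvolve(x, kern[None, :], axes=1)[:, :n_bins]
            acc[:, 1:] += conv[:, :-1]  # kern[0] acts at lag +1
        parts.append(acc)
    return np.concatenate(parts, axis=1)


def _target_signal(binned: BinnedSegments, target: str,
                   config: RunConfig) -> np.ndarray:
    ti = binned.unit_ids.index(target)
    parts = [smooth_hist(binned.segment(s)[ti].astype(float),
                         config.smooth_sd_ms, axis=1)
             for s in ("cue", "movement")]
    return np.concatenate(parts, axis=1)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def predict_target(detection: NetworkDetection, binned: BinnedSegments,
                   target: str, config: RunConfig = DEFAULT_CONFIG):
    """Predicted signal, actual smoothed signal and kernels for one target.

    Returns ``None`` when the target has no significant inputs."""
    kernels = input_kernels(detection, target, config)
    if not kernels:
        return None
    predicted = _convolve_inputs(binned, kernels)
    actual = _target_signal(binned, target, config)
    return predicted, actual, kernels


def permutation_tests(detection: NetworkDetection, binned: BinnedSegments,
                      target: str, predicted: np.ndarray, actual: np.ndarray,
                      kernels: dict[str, np.ndarray],
                      n_permutations: int = 1000,
                      rng: np.random.Generator | None = None,
                      config: RunConfig = DEFAULT_CONFIG) -> PredictionResult:
    """The three permutation schemes for one target's prediction."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    real = _corr(predicted, actual)
    res = PredictionResult(target, list(kernels), real)
    n_m = binned.n_trials

    # 1. trial shuffle: permute the inputs' trial order jointly
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        order = rng.permutation(n_m)
        null[i] = _corr(_convolve_inputs(binned, kernels, order), actual)
    res.p_trials = float((1 + np.count_nonzero(null >= real)) / (1 + null.size))

    # 2. kernel shuffle: permute output parts among the inputs
    units = list(kernels)
    if len(units) >= 2:
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            perm = rng.permutation(len(units))
            shuffled = {units[j]: kernels[units[perm[j]]] for j in range(len(units))}
            null[i] = _corr(_convolve_inputs(binned, shuffled), actual)
        res.p_kernels = float((1 + np.count_nonzero(null >= real)) / (1 + null.size))
    else:
        # a single input has no within-target kernel permutation; draw the
        # kernel from other pairs' output parts instead
        donors = [pr.corrected for pr in detection.pairs.values()
                  if not pr.skipped and target not in (pr.unit_a, pr.unit_b)]
        if donors:
            L = kernels[units[0]].size
            lags = detection.lags
            sel = (lags >= 1) & (lags <= L)
            null = np.empty(n_permutations)
            for i in range(n_permutations):
                kern = donors[int(rng.integers(len(donors)))][sel]
                null[i] = _corr(_convolve_inputs(binned, {units[0]: kern}), actual)
            res.p_kernels = float((1 + np.count_nonzero(null >= real)) / (1 + null.size))

    # 3. input-unit shuffle: replace inputs by random non-input units
    candidates = [u for u in binned.unit_ids
                  if u != target and u not in kernels]
    if len(candidates) >= len(units):
        kern_list = [kernels[u] for u in units]
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            repl = rng.choice(candidates, size=len(units), replace=False)
            null[i] = _corr(
                _convolve_inputs(binned, dict(zip(repl, kern_list))), actual)
        res.p_inputs = float((1 + np.count_nonzero(null >= real)) / (1 + null.size))
    else:
        log.warning("target %s: not enough non-input units for the input "
                    "shuffle; scheme skipped", target)
    return res


def condition_average_prediction(res: PredictionResult, predicted, actual,
                                 detection: NetworkDetection,
                                 binned: BinnedSegments,
                                 kernels: dict[str, np.ndarray],
                                 n_permutations: int = 1000,
                                 rng: np.random.Generator | None = None,
                                 config: RunConfig = DEFAULT_CONFIG) -> PredictionResult:
    """Correlation of condition-averaged rate curves (additionally smoothed
    for reporting), tested against kernel- and input-shuffle nulls only."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    conds = pd.unique(binned.conditions)
    if len(conds) < 2:
        return res

    def cond_means(sig):
        curves = []
        for c in conds:
            m = binned.conditions == c
            curves.append(smooth_hist(sig[m].mean(axis=0),
                                      config.prediction_report_smooth_ms))
        return np.concatenate(curves)

    real = _corr(cond_means(predicted), cond_means(actual))
    res.condition_correlation = real
    units = list(kernels)
    actual_cm = cond_means(actual)
    if len(units) >= 2:
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            perm = rng.permutation(len(units))
            shuffled = {units[j]: kernels[units[perm[j]]] for j in range(len(units))}
            null[i] = _corr(cond_means(_convolve_inputs(binned, shuffled)),
                            actual_cm)
        res.p_cond_kernels = float((1 + np.count_nonzero(null >= real)) / (1 + null.size))
    candidates = [u for u in binned.unit_ids if u != res.target and u not in kernels]
    if len(candidates) >= len(units):
        kern_list = [kernels[u] for u in units]
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            repl = rng.choice(candidates, size=len(units), replace=False)
            null[i] = _corr(
                cond_means(_convolve_inputs(binned, dict(zip(repl, kern_list)))),
                actual_cm)
        res.p_cond_inputs = float((1 + np.count_nonzero(null >= real)) / (1 + null.size))
    return res


def predict_all(detection: NetworkDetection, binned: BinnedSegments,
                n_permutations: int = 1000,
                rng: np.random.Generator | None = None,
                with_conditions: bool = True,
                config: RunConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Prediction + permutation testing for every target with inputs."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for target in binned.unit_ids:
        out = predict_target(detection, binned, target, config)
        if out is None:
            continue
        predicted, actual, kernels = out
        res = permutation_tests(detection, binned, target, predicted, actual,
                                kernels, n_permutations, rng, config)
        if with_conditions:
            res = condition_average_prediction(res, predicted, actual, detection,
                                               binned, kernels, n_permutations,
                                               rng, config)
        rows.append((res.target, len(res.inputs), res.correlation,
                     res.p_trials, res.p_kernels, res.p_inputs, res.significant,
                     res.condition_correlation, res.condition_significant))
    return pd.DataFrame(rows, columns=[
        "target", "n_inputs", "correlation", "p_trials", "p_kernels",
        "p_inputs", "significant", "condition_correlation",
        "condition_significant"])
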
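"""Frequency-domain analysis of correlograms: oscillatory synchrony.

Power spectra of corrected CCHs/ACHs are computed at 100 logarithmically
spaced frequencies (3-100 Hz) with frequency-matched Hanning windows
aligned on the zero lag: each frequency uses a window of four oscillation
periods for CCHs (clipped to [150, 1000] ms, centered) and two periods for
ACHs (clipped to [75, 500] ms, covering one half of the symmetric ACH),
each bin scaled by its window length.  Sharp near-zero CCH peaks are
excised (+/-5 ms, linear interpolation) before the transform so their
broadband impulse energy does not mask genuine rhythmicity.

Significance uses the same cluster-based surrogate logic as the lag-domain
test: surrogate-member spectra provide the per-frequency SD and the
largest-chance-cluster null.  Units are classified as beta (18-35 Hz) /
low-frequency (3-7 Hz) oscillators from their ACH spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import Cluster, attach_pvalues, find_clusters, largest_cluster_stat
from .config import RunConfig, DEFAULT_CONFIG

log = logging.getLogger(__name__)


def frequency_grid(config: RunConfig = DEFAULT_CONFIG) -> np.ndarray:
    return np.logspace(np.log10(config.freq_lo_hz), np.log10(config.freq_hi_hz),
                       config.n_frequencies)


def prep_cch_for_spectrum(values: np.ndarray, lags: np.ndarray,
                          excise_ms: float = 5.0) -> np.ndarray:
    """Replace the +/-excise_ms bins by linear interpolation between the
    first bins outside the excised range (spectral analysis only)."""
    v = np.asarray(values, dtype=float).copy()
    inside = np.abs(lags) <= excise_ms
    if not inside.any():
        return v
    i0 = int(np.flatnonzero(inside)[0])
    i1 = int(np.flatnonzero(inside)[-1])
    lo = i0 - 1
    hi = i1 + 1
    if lo < 0 or hi >= v.size:
        return v
    v[i0:i1 + 1] = np.interp(np.arange(i0, i1 + 1), [lo, hi], [v[lo], v[hi]])
    return v


@dataclass
class _Window:
    idx: np.ndarray        # histogram bin indices entering the transform
    weight: np.ndarray     # Hanning taper
    phase: np.ndarray      # complex exponential at the target frequency
    length: int            # window length in ms (scaling denominator)
    double: bool           # half-window route (ACH): double the power


def window_bank(kind: str, lags: np.ndarray,
                config: RunConfig = DEFAULT_CONFIG) -> list[_Window]:
    """Per-frequency tapered DFT windows aligned on the zero lag."""
    freqs = frequency_grid(config)
    zero = int(np.flatnonzero(lags == 0)[0])
    maxlag = int(lags.max())
    bank = []
    for f in freqs:
        if kind == "CCH":
            length = float(np.clip(4000.0 / f, config.cch_window_min_ms,
                                   config.cch_window_max_ms))
            h = min(int(round(length / 2)), maxlag)
            rel = np.arange(-h, h + 1)
            weight = np.hanning(rel.size)
            double = False
            norm_len = rel.size
        elif kind == "ACH":
            length = float(np.clip(2000.0 / f, config.ach_window_min_ms,
                                   config.ach_window_max_ms))
            w = min(int(round(length)), maxlag)
            rel = np.arange(0, w)
            weight = np.hanning(2 * w)[w:]
            double = True
            norm_len = w
        else:
            raise ValueError(kind)
        phase = np.exp(-2j * np.pi * f * rel / 1000.0)
        bank.append(_Window(zero + rel, weight, phase, norm_len, double))
    return bank


def power_spectrum(values: np.ndarray, bank: list[_Window]) -> np.ndarray:
    """Window-length-normalized power at each bank frequency."""
    out = np.empty(len(bank))
    for i, w in enumerate(bank):
        coeff = np.sum(values[..., w.idx] * w.weight * w.phase, axis=-1)
        p = np.abs(coeff) ** 2 / w.length
        out[i] = 2.0 * p if w.double else p
    return out


def power_spectra(matrix: np.ndarray, bank: list[_Window]) -> np.ndarray:
    """(n_hist, n_freq) power for a stack of histograms."""
    out = np.empty((matrix.shape[0], len(bank)))
    for i, w in enumerate(bank):
        coeff = matrix[:, w.idx] @ (w.weight * w.phase)
        p = np.abs(coeff) ** 2 / w.length
        out[:, i] = 2.0 * p if w.double else p
    return out


@dataclass
class SpectrumSet:
    """Spectrum of one histogram with surrogate-based significance."""

    source: str
    kind: str
    freqs: np.ndarray
    power: np.ndarray               # corrected power (surrogate mean removed)
    raw_power: np.ndarray
    zscores: np.ndarray
    clusters: list[Cluster]
    significant: np.ndarray         # per-frequency mask

    def band_significant(self, band: tuple[float, float]) -> bool:
        lo, hi = band
        in_band = (self.freqs >= lo) & (self.freqs <= hi)
        return bool((self.significant & in_band).any())


def spectrum_significance(values: np.ndarray, members: np.ndarray,
                          lags: np.ndarray, kind: str, source: str = "",
                          config: RunConfig = DEFAULT_CONFIG,
                          alpha: float = 0.05) -> SpectrumSet:
    """Cluster-based surrogate test over frequency bins.

    The mean surrogate spectrum is subtracted from the real spectrum; both
    real and member spectra are z-scored by the member SD, clustered over
    contiguous frequencies (|z| >= threshold), and real clusters are tested
    against the largest-chance-cluster null from the members."""
    bank = window_bank(kind, lags, config)
    if kind == "CCH":
        values = prep_cch_for_spectrum(values, lags, config.excise_ms)
        members = np.stack([prep_cch_for_spectrum(m, lags, config.excise_ms)
                            for m in members])
    raw = power_spectrum(values, bank)
    mem = power_spectra(members, bank)
    mean = mem.mean(axis=0)
    sd = mem.std(axis=0)
    corrected = raw - mean
    valid = sd > 0
    z = np.zeros_like(corrected)
    z[valid] = corrected[valid] / sd[valid]
    zm = np.zeros_like(mem)
    zm[:, valid] = (mem[:, valid] - mean[valid]) / sd[valid]
    clusters = find_clusters(z, config.z_threshold, mask=valid)
    null = np.array([largest_cluster_stat(m, config.z_threshold, mask=valid)
                     for m in zm])
    attach_pvalues(clusters, null)
    sig = np.zeros(z.size, dtype=bool)
    for c in clusters:
        if c.p_value < alpha:
            c.significant = True
            sig[c.start:c.stop + 1] = True
    return SpectrumSet(source, kind, frequency_grid(config), corrected, raw,
                       z, clusters, sig)


# -- oscillator classification -------------------------------------------

@dataclass
class OscillatorLabel:
    unit_id: str
    beta: bool
    low: bool
    gamma: bool

    @property
    def label(self) -> str:
        if self.beta and self.low:
            return "both"
        if self.beta:
            return "beta"
        if self.low:
            return "low"
        return "none"


def classify_oscillators(ach_spectra: dict[str, SpectrumSet],
                         config: RunConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Per-unit oscillator class from significant ACH spectrum bands."""
    rows = []
    for unit, spec in ach_spectra.items():
        lab = OscillatorLabel(
            unit,
            spec.band_significant(config.beta_band_hz),
            spec.band_significant(config.low_band_hz),
            spec.band_significant(config.gamma_band_hz),
        )
        rows.append((unit, lab.label, lab.beta, lab.low, lab.gamma))
    return pd.DataFrame(rows, columns=["unit_id", "label", "beta", "low", "gamma"])


def threshold_classification(ach_spectra: dict[str, SpectrumSet],
                             labels: pd.DataFrame,
                             config: RunConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Alternative oscillator detection by fixed band-power thresholds,
    calibrated so each band yields the same oscillator count as the
    statistical classification."""
    units = list(ach_spectra)
    freqs = frequency_grid(config)
    out = {"unit_id": units}
    for band_name, band in (("beta", config.beta_band_hz),
                            ("low", config.low_band_hz)):
        in_band = (freqs >= band[0]) & (freqs <= band[1])
        power = np.array([ach_spectra[u].power[in_band].mean() for u in units])
        n_target = int(labels[band_name].sum())
        if n_target == 0:
            thresh = np.inf
        else:
            thresh = np.sort(power)[::-1][n_target - 1]
        out[band_name] = power >= thresh
        out[f"{band_name}_power"] = power
    return pd.DataFrame(out)


def rank_group_comparison(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Tukey-Kramer-style multiple comparison on average ranks."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    ranks = stats.rankdata(values)
    res = pairwise_tukeyhsd(ranks, groups)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return frame


def both_band_coincidence_p(labels: pd.DataFrame, n_permutations: int = 1000,
                            rng: np.random.Generator | None = None) -> float:
    """Is the number of units oscillating in both bands larger than the
    coincidental overlap of the two (marginally fixed) bands?"""
    if rng is None:
        rng = np.random.default_rng(0)
    beta = labels["beta"].to_numpy()
    low = labels["low"].to_numpy()
    real = int((beta & low).sum())
    null = np.array([(rng.permutation(beta) & low).sum()
                     for _ in range(n_permutations)])
    return float((1 + np.count_nonzero(null >= real)) / (1 + null.size))


# -- oscillatory state split ---------------------------------------------

def population_ach_power(binned, config: RunConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Per-trial oscillatory-synchrony level from population ACH spectra.

    The activity of all units is pooled into one spike-count train per
    trial; each trial's ACH (both segments, averaged) is transformed with
    the ACH window bank and summarized as the mean power in the beta and
    low-frequency bands.  No surrogate correction is possible for a single
    trial; power is normalized per trial by the Eq-style denominator."""
    from scipy.signal import fftconvolve

    maxlag = int(config.max_lag_ms)
    lags = np.arange(-maxlag, maxlag + 1)
    bank = window_bank("ACH", lags, config)
    n_trials = binned.n_trials
    power = np.zeros((n_trials, len(bank)))
    n_seg = 0
    for seg_name in ("cue", "movement"):
        seg = binned.segment(seg_name)          # (U, M, N)
        pooled = seg.sum(axis=0).astype(float)  # (M, N)
        n_bins = pooled.shape[1]
        lam = pooled.mean(axis=1)               # spikes/bin per trial
        cc = fftconvolve(pooled, pooled[:, ::-1], mode="full", axes=1)
        center = n_bins - 1
        hist = cc[:, center - maxlag: center + maxlag + 1]
        overlap = (n_bins - np.abs(lags)).astype(float)
        ok = lam > 0
        vals = np.zeros_like(hist)
        vals[ok] = hist[ok] / (overlap[None, :] * lam[ok, None] ** 2)
        # remove the trivial zero-lag self-count before the transform
        zero = maxlag
        vals[:, zero] = 0.5 * (vals[:, zero - 1] + vals[:, zero + 1])
        power += power_spectra(vals, bank)
        n_seg += 1
    power /= n_seg
    freqs = frequency_grid(config)
    beta = (freqs >= config.beta_band_hz[0]) & (freqs <= config.beta_band_hz[1])
    low = (freqs >= config.low_band_hz[0]) & (freqs <= config.low_band_hz[1])
    return pd.DataFrame({
        "trial_id": binned.trial_ids,
        "condition": binned.conditions,
        "band_power": power[:, beta].mean(axis=1) + power[:, low].mean(axis=1),
    })


def oscillatory_state_split(dataset, config: RunConfig = DEFAULT_CONFIG,
                            rng: np.random.Generator | None = None,
                            min_trials: int = 900):
    """Split trials into high- and low-oscillatory-synchrony halves.

    Trials are ranked by their population-ACH band power and median-split
    within each condition (equal trial counts per condition per block; an
    odd trial is dropped at random).  Returns (high_ids, low_ids, table).
    """
    from .data import bin_and_align

    if rng is None:
        rng = np.random.default_rng(config.seed)
    if dataset.n_trials < min_trials:
        log.warning("state split on %d trials; >= %d recommended for stable "
                    "topology estimates", dataset.n_trials, min_trials)
    binned = bin_and_align(dataset, config)
    table = population_ach_power(binned, config)
    high, low = [], []
    for _, grp in table.groupby("condition", sort=False):
        grp = grp.sample(frac=1.0, random_state=int(rng.integers(2**31)))
        grp = grp.sort_values("band_power", kind="stable")
        n = len(grp)
        if n % 2 == 1:
            grp = grp.iloc[:-1] if rng.random() < 0.5 else grp.iloc[1:]
            n -= 1
        low.extend(grp["trial_id"].iloc[: n // 2])
        high.extend(grp["trial_id"].iloc[n // 2:])
    return sorted(high), sorted(low), table
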
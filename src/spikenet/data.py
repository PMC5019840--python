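"""Trial-structured spike data: I/O, alignment, binning, PSTHs, rate summaries.

The universal input of the pipeline is a :class:`SpikeDataset` -- parallel
spike trains from many single units recorded over many trials, with unit
metadata (cortical area / electrode array / electrode) and per-trial task
events (cue onset, movement onset).  Analysis operates on two fixed
event-aligned segments binned at 1 kHz:

* cue segment: [-700, 1500) ms around cue onset (2200 bins),
* movement segment: [-300, 500) ms around movement onset (800 bins).

Bins are half-open ``[t, t+1)``; multiple spikes falling into the same
millisecond are clipped to 1 (the correlogram arithmetic treats the binned
train as a spike indicator), and clip events are counted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .config import RunConfig, DEFAULT_CONFIG

log = logging.getLogger(__name__)

AREAS = ("F5", "M1", "AIP", "SIM")
CONDITIONS = (
    "power_instructed",
    "precision_instructed",
    "power_free",
    "precision_free",
)

SEGMENTS = ("cue", "movement")
EPOCHS = ("fixation", "cue", "memory", "movement")
# analysis windows of the four task epochs, defined on the two segments
EPOCH_WINDOWS = {
    "fixation": ("cue", -700.0, 0.0),
    "cue": ("cue", 0.0, 300.0),
    "memory": ("cue", 300.0, 1500.0),
    "movement": ("movement", -300.0, 500.0),
}


@dataclass(frozen=True)
class UnitMeta:
    unit_id: str
    area: str
    array_id: int
    electrode_id: int

    def __post_init__(self):
        if self.area not in AREAS:
            raise ValueError(f"unknown area {self.area!r} for unit {self.unit_id}")


@dataclass(frozen=True)
class TrialRecord:
    trial_id: int
    condition: str
    cue_onset_ms: float
    movement_onset_ms: float

    def __post_init__(self):
        if not self.movement_onset_ms > self.cue_onset_ms:
            raise ValueError(
                f"trial {self.trial_id}: movement onset must follow cue onset"
            )


class SpikeDataset:
    """Cross-referenced container of units, trials and spike events.

    Parameters
    ----------
    units, trials, spikes
        DataFrames with the documented columns (``units``: unit_id, area,
        array_id, electrode_id; ``trials``: trial_id, condition,
        cue_onset_ms, movement_onset_ms; ``spikes``: unit_id, trial_id,
        time_ms).  Referential integrity is validated on construction.
    """

    def __init__(self, units: pd.DataFrame, trials: pd.DataFrame, spikes: pd.DataFrame):
        units = units.reset_index(drop=True).copy()
        trials = trials.reset_index(drop=True).copy()
        spikes = spikes.reset_index(drop=True).copy()
        units["unit_id"] = units["unit_id"].astype(str)
        spikes["unit_id"] = spikes["unit_id"].astype(str)
        if units["unit_id"].duplicated().any():
            dup = units.loc[units["unit_id"].duplicated(), "unit_id"].iloc[0]
            raise ValueError(f"duplicate unit_id {dup!r}")
        if trials["trial_id"].duplicated().any():
            dup = trials.loc[trials["trial_id"].duplicated(), "trial_id"].iloc[0]
            raise ValueError(f"duplicate trial_id {dup!r}")
        # electrode -> array -> area hierarchy must be consistent
        elec = units.groupby(["area", "array_id", "electrode_id"]).size()
        by_elec = units.drop_duplicates(["array_id", "electrode_id"])[
            ["area", "array_id", "electrode_id"]
        ]
        if by_elec.duplicated(["array_id", "electrode_id"]).any():
            raise ValueError("an electrode is assigned to more than one area")
        del elec
        times = pd.to_numeric(spikes["time_ms"], errors="coerce")
        bad = ~np.isfinite(times)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-numeric or non-finite spike time at spikes row {row}")
        if (times < 0).any():
            row = int(np.flatnonzero(times < 0)[0])
            raise ValueError(f"negative spike time at spikes row {row}")
        spikes["time_ms"] = times.astype(float)
        known_units = set(units["unit_id"])
        known_trials = set(trials["trial_id"])
        bad_u = ~spikes["unit_id"].isin(known_units)
        if bad_u.any():
            row = int(np.flatnonzero(bad_u.to_numpy())[0])
            raise ValueError(
                f"spikes row {row} references unknown unit_id "
                f"{spikes['unit_id'].iloc[row]!r}"
            )
        bad_t = ~spikes["trial_id"].isin(known_trials)
        if bad_t.any():
            row = int(np.flatnonzero(bad_t.to_numpy())[0])
            raise ValueError(
                f"spikes row {row} references unknown trial_id "
                f"{spikes['trial_id'].iloc[row]!r}"
            )
        for rec in trials.itertuples(index=False):
            # trials with a missing event survive loading; binning drops them
            if (np.isfinite(rec.cue_onset_ms) and np.isfinite(rec.movement_onset_ms)
                    and not rec.movement_onset_ms > rec.cue_onset_ms):
                raise ValueError(
                    f"trial {rec.trial_id}: movement onset must follow cue onset"
                )
        self.units = units
        self.trials = trials
        self.spikes = spikes

    # -- convenience accessors -------------------------------------------
    @property
    def unit_ids(self) -> list[str]:
        return list(self.units["unit_id"])

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def unit_meta(self) -> list[UnitMeta]:
        return [
            UnitMeta(r.unit_id, r.area, int(r.array_id), int(r.electrode_id))
            for r in self.units.itertuples(index=False)
        ]

    def subset_trials(self, trial_ids) -> "SpikeDataset":
        keep = self.trials["trial_id"].isin(set(trial_ids))
        trials = self.trials[keep]
        spikes = self.spikes[self.spikes["trial_id"].isin(set(trial_ids))]
        return SpikeDataset(self.units, trials, spikes)

    def __repr__(self):
        return (
            f"<SpikeDataset {self.n_units} units, {self.n_trials} trials, "
            f"{len(self.spikes)} spikes>"
        )


def load_dataset(spikes_path, trials_path, units_path) -> SpikeDataset:
    """Load a dataset from the three tab-separated tables."""
    units = pd.read_csv(units_path, sep="\t")
    trials = pd.read_csv(trials_path, sep="\t")
    spikes = pd.read_csv(spikes_path, sep="\t")
    for df, cols, name in (
        (units, ("unit_id", "area", "array_id", "electrode_id"), "units"),
        (trials, ("trial_id", "condition", "cue_onset_ms", "movement_onset_ms"), "trials"),
        (spikes, ("unit_id", "trial_id", "time_ms"), "spikes"),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table is missing columns {missing}")
    return SpikeDataset(units, trials, spikes)


def write_dataset(dataset: SpikeDataset, spikes_path, trials_path, units_path) -> None:
    dataset.units.to_csv(units_path, sep="\t", index=False)
    dataset.trials.to_csv(trials_path, sep="\t", index=False)
    dataset.spikes.to_csv(spikes_path, sep="\t", index=False)


class BinnedSegments:
    """Binary 1 kHz rasters per unit x trial for the two aligned segments.

    Attributes
    ----------
    cue, movement : ndarray of uint8, shape (n_units, n_trials, n_bins)
        2200 and 800 bins respectively.
    clip_count : int
        Number of (unit, trial, ms) bins that contained more than one spike
        and were clipped to 1.
    """

    def __init__(self, unit_ids, trial_ids, conditions, cue, movement, clip_count=0):
        self.unit_ids = list(unit_ids)
        self.trial_ids = list(trial_ids)
        self.conditions = np.asarray(conditions)
        self.cue = cue
        self.movement = movement
        self.clip_count = int(clip_count)

    @property
    def n_units(self):
        return len(self.unit_ids)

    @property
    def n_trials(self):
        return len(self.trial_ids)

    def segment(self, name: str) -> np.ndarray:
        if name == "cue":
            return self.cue
        if name == "movement":
            return self.movement
        raise KeyError(name)

    def sparse(self, name: str):
        """Flattened spike-bin indices for the CCH engine.

        Returns ``(times, offsets)`` where ``offsets[u, i]:offsets[u, i+1]``
        slices the sorted bin indices of unit ``u`` on trial ``i``.
        """
        seg = self.segment(name)
        n_u, n_m, _ = seg.shape
        counts = seg.sum(axis=2, dtype=np.int64)
        offsets = np.zeros((n_u, n_m + 1), dtype=np.int64)
        np.cumsum(counts, axis=1, out=offsets[:, 1:])
        base = np.concatenate([[0], offsets[:, -1].cumsum()])[:-1]
        times = np.empty(int(counts.sum()), dtype=np.int32)
        for u in range(n_u):
            uu, ii = np.nonzero(seg[u])
            # nonzero returns trial-major order -> already sorted per trial
            times[base[u] : base[u] + uu.size] = ii.astype(np.int32)
        offsets = offsets + base[:, None]
        return times, offsets


def bin_and_align(dataset: SpikeDataset, config: RunConfig = DEFAULT_CONFIG) -> BinnedSegments:
    """Bin spikes into the cue and movement segments.

    Trials missing either event are excluded with a warning.  Returns exact
    segment lengths (2200 and 800 bins at the default windows) and never
    invents spikes: the binned total is bounded by the raw in-window count.
    """
    trials = dataset.trials
    ok = np.isfinite(trials["cue_onset_ms"]) & np.isfinite(trials["movement_onset_ms"])
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} trial(s) with missing alignment events"
        )
        trials = trials[ok]
    trial_ids = trials["trial_id"].to_numpy()
    conditions = trials["condition"].to_numpy()
    n_u, n_m = dataset.n_units, len(trial_ids)
    cue_lo, cue_hi = config.cue_window_ms
    mov_lo, mov_hi = config.movement_window_ms
    n_cue = int(round(cue_hi - cue_lo))
    n_mov = int(round(mov_hi - mov_lo))
    cue = np.zeros((n_u, n_m, n_cue), dtype=np.uint8)
    mov = np.zeros((n_u, n_m, n_mov), dtype=np.uint8)

    uidx = {u: i for i, u in enumerate(dataset.unit_ids)}
    tidx = {t: i for i, t in enumerate(trial_ids)}
    cue_on = trials["cue_onset_ms"].to_numpy()
    mov_on = trials["movement_onset_ms"].to_numpy()

    sp = dataset.spikes
    su = sp["unit_id"].map(uidx).to_numpy()
    st = sp["trial_id"].map(tidx)
    keep = st.notna().to_numpy()
    su = su[keep]
    st = st[keep].to_numpy().astype(np.int64)
    stime = sp["time_ms"].to_numpy()[keep]

    clip = 0
    for arr, onset, lo, nbins in ((cue, cue_on, cue_lo, n_cue), (mov, mov_on, mov_lo, n_mov)):
        rel = stime - onset[st]
        b = np.floor(rel - lo).astype(np.int64)
        inw = (b >= 0) & (b < nbins)
        flat = (su[inw] * n_m + st[inw]) * nbins + b[inw]
        uniq, cnt = np.unique(flat, return_counts=True)
        clip += int((cnt > 1).sum())
        arr.reshape(-1)[uniq] = 1
    if clip:
        log.info("clipped %d multi-spike bins to 1", clip)
    binned = BinnedSegments(dataset.unit_ids, trial_ids, conditions, cue, mov, clip)
    if binned.cue.sum() + binned.movement.sum() == 0:
        warnings.warn("no spikes fall inside the analysis segments")
    return binned


def save_binned(binned: BinnedSegments, path) -> None:
    """Cache binned segments to HDF5 (shape metadata in attributes)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["n_units"] = binned.n_units
        f.attrs["n_trials"] = binned.n_trials
        f.attrs["clip_count"] = binned.clip_count
        f.attrs["unit_ids"] = [str(u) for u in binned.unit_ids]
        f.attrs["trial_ids"] = [int(t) for t in binned.trial_ids]
        f.attrs["conditions"] = [str(c) for c in binned.conditions]
        f.create_dataset("cue", data=binned.cue, compression="gzip")
        f.create_dataset("movement", data=binned.movement, compression="gzip")


def load_binned(path) -> BinnedSegments:
    import h5py

    with h5py.File(path, "r") as f:
        return BinnedSegments(
            [str(u) for u in f.attrs["unit_ids"]],
            [int(t) for t in f.attrs["trial_ids"]],
            np.array([str(c) for c in f.attrs["conditions"]]),
            f["cue"][()], f["movement"][()],
            clip_count=int(f.attrs["clip_count"]),
        )


@dataclass
class RateFunction:
    """Per-bin trial-averaged firing rate (spikes/bin) of one unit.

    ``raw`` is the unsmoothed PSTH; ``rate`` is smoothed with a Gaussian
    kernel (SD 3.66 ms by default), the rate function used for surrogate
    spike generation.
    """

    unit_id: str
    condition: str
    segment: str
    raw: np.ndarray
    rate: np.ndarray
    n_trials: int


def smooth_hist(x: np.ndarray, sd_ms: float, axis: int = -1) -> np.ndarray:
    """Gaussian smoothing used throughout (histograms, PSTHs, rasters).

    Reflecting boundaries keep the histogram mass conserved."""
    return gaussian_filter1d(np.asarray(x, dtype=float), sd_ms, axis=axis, mode="reflect")


def compute_psth(
    binned: BinnedSegments,
    condition: str | None,
    segment: str,
    config: RunConfig = DEFAULT_CONFIG,
) -> list[RateFunction]:
    """PSTHs for every unit in one condition (or pooled if None) and segment."""
    if condition is None:
        mask = np.ones(binned.n_trials, dtype=bool)
        cond_name = "all"
    else:
        mask = binned.conditions == condition
        cond_name = condition
    if not mask.any():
        raise ValueError(f"no trials in condition {condition!r}")
    seg = binned.segment(segment)[:, mask, :]
    raw = seg.mean(axis=1)
    sm = smooth_hist(raw, config.smooth_sd_ms, axis=1)
    n = int(mask.sum())
    return [
        RateFunction(u, cond_name, segment, raw[i], sm[i], n)
        for i, u in enumerate(binned.unit_ids)
    ]


def rate_summary(dataset: SpikeDataset, config: RunConfig = DEFAULT_CONFIG) -> dict:
    """Mean rates per unit x epoch x condition and the correlation structure
    of log rates across epoch/condition pairs.

    Returns a dict with a tidy ``rates`` DataFrame (spikes/s), the
    ``log_correlation`` matrix over (epoch, condition) columns, and the list
    of units excluded from the log correlation (zero spikes overall).
    """
    binned = bin_and_align(dataset, config)
    conds = [c for c in pd.unique(binned.conditions)]
    cols = []
    names = []
    rows = []
    for cond in conds:
        mask = binned.conditions == cond
        if not mask.any():
            continue
        for epoch in EPOCHS:
            seg_name, lo, hi = EPOCH_WINDOWS[epoch]
            seg_lo = config.cue_window_ms[0] if seg_name == "cue" else config.movement_window_ms[0]
            i0 = int(round(lo - seg_lo))
            i1 = int(round(hi - seg_lo))
            seg = binned.segment(seg_name)[:, mask, i0:i1]
            rate_hz = seg.mean(axis=(1, 2)) * 1000.0
            cols.append(rate_hz)
            names.append((epoch, cond))
            for i, u in enumerate(binned.unit_ids):
                rows.append((u, epoch, cond, rate_hz[i]))
    rates = pd.DataFrame(rows, columns=["unit_id", "epoch", "condition", "rate_hz"])
    mat = np.column_stack(cols)
    total = mat.sum(axis=1)
    excluded = [u for u, t in zip(binned.unit_ids, total) if t == 0]
    if excluded:
        warnings.warn(
            f"{len(excluded)} unit(s) with zero spikes excluded from log-rate correlation"
        )
    keep = total > 0
    logm = np.log10(np.maximum(mat[keep], 1e-3))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(logm, rowvar=False)
    corr = pd.DataFrame(
        corr,
        index=pd.MultiIndex.from_tuples(names, names=["epoch", "condition"]),
        columns=pd.MultiIndex.from_tuples(names, names=["epoch", "condition"]),
    )
    return {"rates": rates, "log_correlation": corr, "excluded_units": excluded}
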
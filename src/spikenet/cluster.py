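"""Cluster-based surrogate/permutation statistics.

Shared machinery: contiguous runs of threshold-exceeding values (same sign)
form clusters scored by their accumulated statistic; real cluster scores are
compared against the null distribution of the largest |cluster| found in
each surrogate/permutation member.  Benjamini-Hochberg FDR is applied across
all clusters of a whole network where stated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


@dataclass
class Cluster:
    """One contiguous same-sign suprathreshold run."""

    start: int           # first bin index (inclusive)
    stop: int            # last bin index (inclusive)
    sign: int            # +1 / -1
    stat: float          # accumulated statistic (signed)
    p_value: float = np.nan
    significant: bool = False

    @property
    def abs_stat(self) -> float:
        return abs(self.stat)


def find_clusters(values: np.ndarray, threshold: float,
                  mask: np.ndarray | None = None) -> list[Cluster]:
    """Maximal runs of contiguous bins with |value| >= threshold, split at
    sign changes.  ``mask`` marks bins eligible for clustering (e.g. the
    +/-200 ms test window, or bins with nonzero surrogate SD)."""
    v = np.asarray(values, dtype=float)
    marked = np.abs(v) >= threshold
    if mask is not None:
        marked &= mask
    clusters: list[Cluster] = []
    i = 0
    n = v.size
    while i < n:
        if not marked[i]:
            i += 1
            continue
        sign = 1 if v[i] > 0 else -1
        j = i
        acc = 0.0
        while j < n and marked[j] and (v[j] > 0) == (sign > 0):
            acc += v[j]
            j += 1
        clusters.append(Cluster(start=i, stop=j - 1, sign=sign, stat=acc))
        i = j
    return clusters


def largest_cluster_stat(values: np.ndarray, threshold: float,
                         mask: np.ndarray | None = None) -> float:
    """|accumulated statistic| of the largest cluster (0 if none)."""
    cl = find_clusters(values, threshold, mask)
    return max((c.abs_stat for c in cl), default=0.0)


@njit(cache=True)
def _member_largest(z, mask, thresh):  # pragma: no cover - numba
    n_rows, n = z.shape
    out = np.zeros(n_rows)
    for r in range(n_rows):
        best = 0.0
        acc = 0.0
        sign = 0
        for i in range(n):
            v = z[r, i]
            if mask[i] and (v >= thresh or v <= -thresh):
                s = 1 if v > 0 else -1
                if sign != 0 and s != sign:
                    if abs(acc) > best:
                        best = abs(acc)
                    acc = 0.0
                sign = s
                acc += v
            else:
                if abs(acc) > best:
                    best = abs(acc)
                acc = 0.0
                sign = 0
        if abs(acc) > best:
            best = abs(acc)
        out[r] = best
    return out


def member_null(members: np.ndarray, threshold: float,
                mask: np.ndarray | None = None,
                merge_orderings: bool = True) -> np.ndarray:
    """Null distribution of largest |cluster| per surrogate member.

    With ``merge_orderings`` the two pair orderings are pooled.  Because the
    reversed-ordering member histograms are exact time reversals of the same
    surrogate draws, their largest-cluster values coincide; the merged null
    therefore has 2R entries duplicating the R per-ordering values, which
    leaves empirical p-values unchanged.  Members with no cluster contribute 0.
    """
    members = np.ascontiguousarray(members, dtype=np.float64)
    if mask is None:
        mask = np.ones(members.shape[1], dtype=bool)
    null = _member_largest(members, np.ascontiguousarray(mask), threshold)
    if merge_orderings:
        null = np.concatenate([null, null])
    return null


def empirical_p(stat: float, null: np.ndarray) -> float:
    """Fraction of the null at or above |stat| (0 when the cluster beats
    every chance cluster; the network-wide FDR step needs this exact
    empirical CDF convention to stay operable at moderate member counts)."""
    if null.size == 0:
        return 1.0
    return np.count_nonzero(null >= abs(stat)) / null.size


def attach_pvalues(clusters: list[Cluster], null: np.ndarray) -> list[Cluster]:
    for c in clusters:
        c.p_value = empirical_p(c.abs_stat, null)
    return clusters


def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rule: retain all p(k) with k up to the
    largest k satisfying p(k) <= k q / m.  Returns a boolean mask."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    thresh = (np.arange(1, m + 1) * q) / m
    passed = p[order] <= thresh
    keep = np.zeros(m, dtype=bool)
    if passed.any():
        k_max = int(np.max(np.flatnonzero(passed)))
        keep[order[: k_max + 1]] = True
    return keep


def cluster_permutation_test(group_a: np.ndarray, group_b: np.ndarray,
                             n_permutations: int = 1000, alpha: float = 0.05,
                             rng: np.random.Generator | None = None) -> list[Cluster]:
    """Nonparametric cluster-based permutation test between two groups of
    curves (rows = observations, columns = support bins).

    Pointwise independent-sample t statistics thresholded at the two-sided
    critical t for ``alpha``; contiguous suprathreshold same-sign bins form
    clusters scored by summed t; the null is the maximum |cluster| over
    random reassignments of rows to groups (group sizes preserved).
    """
    from scipy import stats

    if rng is None:
        rng = np.random.default_rng(0)
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("need 2-D group arrays (observations x bins)")
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least 2 observations per group")
    n_a = len(a)
    pooled = np.vstack([a, b])
    df = len(a) + len(b) - 2
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)

    def tvals(x, y):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = stats.ttest_ind(x, y, axis=0).statistic
        return np.nan_to_num(t)

    real = find_clusters(tvals(a, b), t_crit)
    null = np.zeros(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(pooled))
        null[i] = largest_cluster_stat(
            tvals(pooled[perm[:n_a]], pooled[perm[n_a:]]), t_crit)
    return attach_pvalues(real, null)
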
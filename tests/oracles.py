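"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: direct formulas,
exhaustive enumeration and re-pooling agglomeration written from first
principles.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd


def exact_ranksum_p(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating all rank assignments."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n, na = len(pooled), len(a)
    mean_w = na * (n + 1) / 2
    count = 0
    total = 0
    for comb in combinations(range(1, n + 1), na):
        total += 1
        if abs(sum(comb) - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def bh_by_hand(p) -> np.ndarray:
    """Step-up BH: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def knee_by_scan(reads) -> int:
    """Max signed above-chord distance in (log10 rank, cum fraction)."""
    reads = np.sort(np.asarray(reads, dtype=float))[::-1]
    frac = np.cumsum(reads) / reads.sum()
    x = np.log10(np.arange(1, len(reads) + 1, dtype=float))
    dx, dy = x[-1] - x[0], frac[-1] - frac[0]
    best, best_i = -np.inf, -1
    for i in range(len(reads)):
        d = (dx * (frac[i] - frac[0]) - dy * (x[i] - x[0])) / np.hypot(dx, dy)
        if d > best:
            best, best_i = d, i
    return int(reads[best_i])


def _logcpm_rows(raw: pd.DataFrame) -> np.ndarray:
    arr = raw.to_numpy(dtype=float)
    return np.log1p(arr / arr.sum(axis=1, keepdims=True) * 1e6)


def agglomerate_oracle(counts: pd.DataFrame, labels: pd.Series, genes,
                       r_merge: float = 0.95):
    """Re-pooling agglomeration: repeatedly pool the most-correlated pair
    (r >= r_merge) of groups, recomputing pooled counts each step.
    Returns (final partition as frozensets of fine labels, merge order)."""
    groups = {g: frozenset([g]) for g in sorted(labels.astype(str).unique())}
    raw = counts.groupby(labels.astype(str)).sum()
    merges = []
    gene_pos = [counts.columns.get_loc(g) for g in genes]
    while len(raw) > 1:
        names = sorted(raw.index)
        lc = _logcpm_rows(raw.loc[names])[:, gene_pos]
        r = np.corrcoef(lc)
        best_pair, best_r = None, -np.inf
        for i, j in combinations(range(len(names)), 2):
            if r[i, j] > best_r:
                best_r = r[i, j]
        cand = sorted(
            (names[i], names[j])
            for i, j in combinations(range(len(names)), 2)
            if r[i, j] == best_r
        )
        if best_r < r_merge:
            break
        a, b = cand[0]
        merges.append((a, b))
        merged = "+".join(sorted(groups[a] | groups[b]))
        groups[merged] = groups.pop(a) | groups.pop(b)
        pooled = raw.loc[a] + raw.loc[b]
        raw = raw.drop(index=[a, b])
        raw.loc[merged] = pooled
    return set(groups.values()), merges


def exclusion_oracle(counts: pd.DataFrame, labels: pd.Series, genes,
                     sizes: pd.Series, r_min: float = 0.90):
    """Iteratively drop the group with the smallest mean off-diagonal r
    until the min off-diagonal reaches r_min or 2 groups remain."""
    raw = counts.groupby(labels.astype(str)).sum()
    current = sorted(raw.index)
    excluded = []
    gene_pos = [counts.columns.get_loc(g) for g in genes]
    while len(current) > 2:
        lc = _logcpm_rows(raw.loc[current])[:, gene_pos]
        r = np.corrcoef(lc)
        off = r[~np.eye(len(current), dtype=bool)]
        if off.min() >= r_min:
            break
        mean_off = (r.sum(axis=0) - 1) / (len(current) - 1)
        order = sorted(
            range(len(current)),
            key=lambda i: (mean_off[i], sizes.get(current[i], 0), current[i]),
        )
        excluded.append(current.pop(order[0]))
    return current, excluded
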
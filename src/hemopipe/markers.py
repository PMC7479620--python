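"""Rank-sum marker statistics, BH adjustment, DEG counting and cohort
proportion tables.

The Wilcoxon rank-sum (Mann-Whitney) test uses exact null enumeration for
small tie-free samples and the tie-corrected normal approximation with
continuity correction otherwise; marker significance is controlled by
Benjamini-Hochberg FDR within each one-vs-rest comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .subcluster import NormalizedMatrix

EXACT_MAX_N = 20  #: exact null enumeration up to this combined sample size


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


def rank_sum_test(values_a, values_b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact p-value (full enumeration of rank assignments) when
    n_a + n_b <= 20 and there are no ties; otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    Identical constant samples are degenerate: p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        u = a.size * b.size / 2.0
        return RankSumResult(statistic=u, pvalue=1.0, degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankSumResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped to [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_stats(values: np.ndarray, in_group: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-gene expm1-mean, pct detected, for group and rest."""
    x_in, x_out = values[in_group], values[~in_group]
    m_in = np.expm1(x_in).mean(axis=0)
    m_out = np.expm1(x_out).mean(axis=0)
    pct_in = (x_in > 0).mean(axis=0)
    pct_out = (x_out > 0).mean(axis=0)
    return m_in, m_out, pct_in, pct_out


def deg_count(
    norm: NormalizedMatrix,
    labels,
    q_max: float = 0.05,
    lfc_min: float = 0.25,
    min_cells_detected: int = 3,
    min_group_size: int = 3,
) -> tuple[int, pd.DataFrame]:
    """One-vs-rest DEG count among groups.

    Per group, every gene detected in >= ``min_cells_detected`` cells is
    tested by rank-sum (group vs all other cells); BH adjustment is applied
    within each comparison. The count is the number of unique genes with
    q < q_max and \\|log2 fold change\\| >= lfc_min in at least one
    comparison; log2FC is computed on expm1-back-transformed group means
    with pseudocount 1.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=norm.cell_names)
    groups = [g for g in pd.unique(labels)]
    sizes = labels.value_counts()
    tested_groups = [g for g in groups if sizes[g] >= min_group_size]
    skipped = set(groups) - set(tested_groups)
    if skipped:
        warnings.warn(f"groups below {min_group_size} cells excluded from DEG test: {sorted(map(str, skipped))}")
    if len(tested_groups) < 2:
        raise ValueError("need at least 2 groups of sufficient size")

    x = norm.values
    dense = x.toarray() if sp.issparse(x) else np.asarray(x)
    detected = (dense > 0).sum(axis=0) >= min_cells_detected
    gene_idx = np.where(detected)[0]
    if gene_idx.size == 0:
        return 0, pd.DataFrame(
            columns=["gene", "group", "statistic", "p_value", "q_value",
                     "log2_fold_change", "pct_in_group", "pct_in_rest"]
        )
    d = dense[:, gene_idx]
    rows = []
    for g in tested_groups:
        in_group = (labels == g).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant genes yield p=nan
            res = stats.mannwhitneyu(
                d[in_group], d[~in_group], alternative="two-sided",
                method="asymptotic", axis=0,
            )
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        q = bh_adjust(p)
        m_in, m_out, pct_in, pct_out = _group_stats(d, in_group)
        lfc = np.log2((m_in + 1.0) / (m_out + 1.0))
        rows.append(
            pd.DataFrame(
                {
                    "gene": np.asarray(norm.gene_names)[gene_idx],
                    "group": g,
                    "statistic": np.asarray(res.statistic, dtype=float),
                    "p_value": p,
                    "q_value": q,
                    "log2_fold_change": lfc,
                    "pct_in_group": pct_in,
                    "pct_in_rest": pct_out,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    sig = table[(table["q_value"] < q_max) & (table["log2_fold_change"].abs() >= lfc_min)]
    return int(sig["gene"].nunique()), table


@dataclass
class ProportionTable:
    """Per-group, per-condition counts with condition shares and counts
    normalized to the first condition's total."""

    counts: pd.DataFrame  # groups x conditions, raw counts
    shares: pd.DataFrame  # columns sum to 1
    normalized: pd.DataFrame  # counts scaled to the reference condition total

    def ratio(self, cond_a: str, cond_b: str) -> pd.Series:
        """Proportional ratio: group share in A over share in B; NaN where
        the denominator share is zero (undefined, not infinite)."""
        a, b = self.shares[cond_a], self.shares[cond_b]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(b > 0, a / b, np.nan)
        return pd.Series(r, index=self.shares.index, name=f"{cond_a}/{cond_b}")


def proportion_table(labels, condition) -> ProportionTable:
    """Cross-tabulate group membership by condition."""
    labels = pd.Series(np.asarray(labels, dtype=object), name="group")
    condition = pd.Series(np.asarray(condition, dtype=object), name="condition")
    if len(labels) != len(condition):
        raise ValueError("labels and condition must align")
    counts = pd.crosstab(labels, condition)
    if (counts.sum(axis=0) == 0).any() or counts.shape[1] == 0:
        raise ValueError("empty condition")
    shares = counts / counts.sum(axis=0)
    ref_total = counts.iloc[:, 0].sum()
    normalized = counts / counts.sum(axis=0) * ref_total
    return ProportionTable(counts=counts, shares=shares, normalized=normalized)
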
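"""Balanced-resampling consensus for transcription-factor (regulon)
activity.

Activity calls on a full dataset are biased toward large cell populations:
the expressing-cell gene filter scales with dataset size, so targets of a
regulon active only in a small subcluster are discarded before they can be
scored. The consensus procedure corrects this by repeatedly drawing an
equal number of cells from every subcluster (two thirds of the smallest
subcluster), running the activity caller on each balanced subsample, and
keeping TFs called active in at least ``min_hits`` of ``trials`` trials.

The per-trial caller is pluggable (any callable with the
:class:`ActivityCaller` signature); the built-in reference caller scores a
regulon per cell as the mean log-normalized expression of its surviving
targets and calls the TF active when some subcluster's score distribution
exceeds all other cells (one-sided rank-sum, BH q < 0.05, positive mean
difference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .markers import bh_adjust
from .subcluster import normalize_counts


@dataclass(frozen=True)
class Regulon:
    """A TF and its target-gene set."""

    tf: str
    targets: frozenset[str]

    def __post_init__(self):
        if self.tf in self.targets:
            raise ValueError(f"regulon {self.tf}: TF cannot be its own target")
        if len(self.targets) == 0:
            raise ValueError(f"regulon {self.tf}: empty target set")


@dataclass
class ConsensusConfig:
    trials: int = 100
    sample_fraction: float = 2.0 / 3.0
    min_hits: int = 25
    gene_filter_fraction: float = 0.03
    gene_filter_multiplier: float = 3.0
    minor_group_fraction: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.sample_fraction <= 1.0):
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.min_hits > self.trials:
            raise ValueError("min_hits must be <= trials")


@dataclass
class ConsensusResult:
    hits: pd.Series  # per TF, number of trials called active
    consensus: set[str]
    trials: int
    failed_trials: int
    samples: list[list[str]] = field(default_factory=list)  # per-trial cells


class ActivityCaller(Protocol):
    def __call__(
        self, adata: ad.AnnData, cells: Sequence[str], labels: pd.Series,
        regulons: Sequence[Regulon],
    ) -> set[str]:
        ...


def activity_gene_filter(
    adata: ad.AnnData, fraction: float = 0.03, multiplier: float = 3.0
) -> tuple[list[str], float, float]:
    """SCENIC-style gene filter.

    With N cells, keep genes whose total UMI count exceeds
    ``multiplier * (fraction * N)`` and which are detected (count > 0) in
    at least ``fraction * N`` cells. Both thresholds are returned as
    unrounded real numbers.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    if adata.n_obs == 0:
        raise ValueError("empty matrix")
    n = adata.n_obs
    min_cells = fraction * n
    umi_threshold = multiplier * min_cells
    x = sp.csr_matrix(adata.X)
    totals = np.asarray(x.sum(axis=0)).ravel()
    detected = np.asarray((x > 0).sum(axis=0)).ravel()
    keep = (totals > umi_threshold) & (detected >= min_cells)
    return [str(g) for g in adata.var_names[keep]], umi_threshold, min_cells


def balanced_sample(
    labels: pd.Series, sample_fraction: float, seed: int
) -> list[str]:
    """Draw k = floor(sample_fraction * smallest-subcluster size) cells
    without replacement from every subcluster."""
    labels = pd.Series(labels)
    sizes = labels.value_counts()
    if (sizes == 0).any():
        raise ValueError("every subcluster must be non-empty")
    k = int(np.floor(sample_fraction * sizes.min()))
    if k == 0:
        raise ValueError("smallest subcluster too small for fraction")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for g in sorted(map(str, sizes.index)):
        members = labels.index[labels.astype(str) == g].to_numpy()
        out.extend(rng.choice(members, size=k, replace=False).tolist())
    return out


def reference_caller(
    adata: ad.AnnData,
    cells: Sequence[str],
    labels: pd.Series,
    regulons: Sequence[Regulon],
    q_max: float = 0.05,
    gene_filter_fraction: float = 0.03,
    gene_filter_multiplier: float = 3.0,
) -> set[str]:
    """Rank-sum reference activity caller on a cell subset.

    The subset is gene-filtered and log-normalized; each regulon is scored
    per cell as the mean normalized expression of its surviving targets. A
    TF is active when some subcluster's cells exceed all other cells
    (one-sided Mann-Whitney, BH across all TF x subcluster tests,
    q < q_max, positive mean difference).
    """
    from scipy import stats

    sub = adata[list(cells)]
    if sub.X.sum() == 0:
        return set()
    kept, _, _ = activity_gene_filter(
        sub, fraction=gene_filter_fraction, multiplier=gene_filter_multiplier
    )
    kept_set = set(kept)
    lab = pd.Series(labels).loc[list(cells)].astype(str)
    norm = normalize_counts(sub[:, [g for g in sub.var_names if g in kept_set]])
    gene_pos = {g: i for i, g in enumerate(norm.gene_names)}
    dense = norm.dense()

    tests: list[tuple[str, float, float]] = []  # (tf, p, mean difference)
    for reg in regulons:
        targets = [g for g in sorted(reg.targets) if g in gene_pos]
        if not targets:
            warnings.warn(f"regulon {reg.tf}: no targets survive gene filter; skipped")
            continue
        score = dense[:, [gene_pos[g] for g in targets]].mean(axis=1)
        for g in sorted(lab.unique()):
            in_group = (lab == g).to_numpy()
            if in_group.all() or not in_group.any():
                continue
            a, b = score[in_group], score[~in_group]
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            p = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic").pvalue
            tests.append((reg.tf, float(p), float(a.mean() - b.mean())))
    if not tests:
        return set()
    q = bh_adjust([t[1] for t in tests])
    return {tf for (tf, _, diff), qv in zip(tests, q) if qv < q_max and diff > 0}


def run_consensus(
    adata: ad.AnnData,
    labels: pd.Series,
    regulons: Sequence[Regulon],
    caller: ActivityCaller,
    config: ConsensusConfig,
) -> ConsensusResult:
    """Balanced-resampling consensus over ``config.trials`` trials.

    Trial t draws a balanced sample with a seed derived deterministically
    from (config.seed, t) and tallies the caller's active TFs; the
    consensus set is every TF with at least ``min_hits`` hits. More than
    10% failed trials aborts.
    """
    labels = pd.Series(labels)
    hits = pd.Series(0, index=[r.tf for r in regulons], dtype=int)
    samples: list[list[str]] = []
    failed = 0
    for t in range(config.trials):
        trial_seed = int(
            np.random.SeedSequence([config.seed, t]).generate_state(1)[0] % (2**31)
        )
        cells = balanced_sample(labels, config.sample_fraction, seed=trial_seed)
        samples.append(cells)
        try:
            active = caller(adata, cells, labels, regulons)
        except Exception as exc:  # caller contract: a failed trial is recorded
            warnings.warn(f"trial {t} failed: {exc}")
            failed += 1
            continue
        for tf in active:
            if tf in hits.index:
                hits[tf] += 1
    if failed > 0.10 * config.trials:
        raise RuntimeError(f"{failed}/{config.trials} trials failed")
    consensus = set(hits.index[hits >= config.min_hits])
    return ConsensusResult(
        hits=hits, consensus=consensus, trials=config.trials,
        failed_trials=failed, samples=samples,
    )


def group_profiles(
    adata: ad.AnnData,
    labels: pd.Series,
    timepoints: pd.Series,
    minor_group_fraction: float = 0.001,
) -> pd.DataFrame:
    """Scaled pseudo-bulk per (group, timepoint): per-gene mean of z-scored
    log-normalized expression. Combinations smaller than
    ``minor_group_fraction`` of all cells are dropped."""
    labels = pd.Series(labels).astype(str)
    timepoints = pd.Series(timepoints).astype(str)
    if len(labels) != adata.n_obs or len(timepoints) != adata.n_obs:
        raise ValueError("labels and timepoints must cover all cells")
    total = adata.n_obs
    cutoff = minor_group_fraction * total
    norm = normalize_counts(adata)
    dense = norm.dense()
    mu = dense.mean(axis=0)
    sd = dense.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (dense - mu) / sd
    key = pd.MultiIndex.from_arrays(
        [labels.to_numpy(), timepoints.to_numpy()], names=["group", "timepoint"]
    )
    rows = {}
    for (g, tp), idx in pd.Series(range(total), index=key).groupby(level=[0, 1]):
        if len(idx) < cutoff:
            continue
        rows[(g, tp)] = z[idx.to_numpy()].mean(axis=0)
    if not rows:
        raise ValueError("all (group, timepoint) combinations dropped")
    return pd.DataFrame(
        np.vstack(list(rows.values())),
        index=pd.MultiIndex.from_tuples(rows.keys(), names=["group", "timepoint"]),
        columns=norm.gene_names,
    )
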
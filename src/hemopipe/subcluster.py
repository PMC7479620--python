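"""Resolution-optimized, correlation-merged subclustering.

The optimal-subclustering procedure sweeps the clustering resolution over a
grid; at each resolution the fine clusters are aggregated to pseudo-bulk
profiles, the least-correlated clusters (Pearson r < r_exclude over the
variable genes) are iteratively pruned, the most-correlated pairs
(r >= r_merge) are iteratively pooled into super-groups, and the number of
DEGs among super-groups is counted. The optimum is the resolution
maximizing the DEG count: fine enough to split genuine cell states, coarse
enough that near-duplicate clusters are merged rather than diluting the
marker contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: value = log(1 + count / cell_total *
    target_total). Cell totals are kept so counts can be recovered."""

    values: sp.spmatrix | np.ndarray
    cell_names: np.ndarray
    gene_names: np.ndarray
    cell_totals: np.ndarray
    target_total: float = 1e4
    pseudocount: float = 1.0

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def dense(self) -> np.ndarray:
        return self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values)


@dataclass
class PseudobulkProfile:
    """Per-group summed counts plus log1p-CPM profiles for correlation."""

    raw: pd.DataFrame  # groups x genes, summed counts
    logcpm: pd.DataFrame  # groups x genes
    sizes: pd.Series  # cells per group


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over group profiles."""

    groups: list[str]
    r: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.r, self.r.T, atol=1e-9):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-9):
            raise ValueError("correlation diagonal must be 1")

    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(len(self.groups), dtype=bool)
        return self.r[mask]


@dataclass
class SupergroupSolution:
    resolution: float
    fine_labels: pd.Series  # cell -> fine cluster
    excluded_clusters: set[str]
    supergroup_map: dict[str, str]  # fine cluster -> super-group
    deg_count: int
    trace: pd.DataFrame = field(default_factory=pd.DataFrame)

    def supergroup_labels(self) -> pd.Series:
        """Cell-level super-group labels; cells of excluded clusters NaN."""
        return self.fine_labels.map(self.supergroup_map)

    def recovered_partition(self) -> pd.Series:
        """Cell-level partition counting each excluded cluster as its own
        group (used for recovery scoring against planted coarse labels)."""
        lab = self.supergroup_labels()
        excl = self.fine_labels.isin(self.excluded_clusters)
        out = lab.astype(object)
        out[excl] = "excluded:" + self.fine_labels[excl].astype(str)
        return out


class ClusterBackend(Protocol):
    """Callable clustering backend: (NormalizedMatrix, resolution, seed) ->
    per-cell labels. Must be deterministic given the seed."""

    def __call__(self, norm: NormalizedMatrix, resolution: float, seed: int) -> np.ndarray:
        ...


def normalize_counts(
    adata: ad.AnnData, target_total: float = 1e4, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Depth-normalize and log-transform UMI counts."""
    x = sp.csr_matrix(adata.X, dtype=float)
    totals = np.asarray(x.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = adata.obs_names[np.where(totals == 0)[0][0]]
        raise ValueError(f"zero-total cell: {bad}")
    scaled = sp.diags(target_total / totals) @ x
    scaled.data = np.log1p(scaled.data)
    return NormalizedMatrix(
        values=scaled.tocsr(),
        cell_names=adata.obs_names.to_numpy(),
        gene_names=adata.var_names.to_numpy(),
        cell_totals=totals,
        target_total=target_total,
        pseudocount=pseudocount,
    )


def select_variable_genes(norm: NormalizedMatrix, n: int = 2000) -> list[str]:
    """Top-n genes by dispersion (variance / mean of normalized values);
    zero-mean genes are ineligible, ties break by gene-identifier order."""
    x = norm.values
    if sp.issparse(x):
        mean = np.asarray(x.mean(axis=0)).ravel()
        sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    else:
        mean = x.mean(axis=0)
        sq = (x ** 2).mean(axis=0)
    var = sq - mean ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / mean, -np.inf)
    eligible = (mean > 0) & (var > 0)
    if eligible.sum() < n:
        warnings.warn(
            f"only {int(eligible.sum())} eligible variable genes (< {n}); returning all"
        )
        n = int(eligible.sum())
    names = np.asarray(norm.gene_names, dtype=object)
    order = np.lexsort((names, -dispersion))
    order = order[eligible[order]]
    return [str(g) for g in names[order[:n]]]


def _logcpm(raw: pd.DataFrame) -> pd.DataFrame:
    totals = raw.sum(axis=1)
    return np.log1p(raw.div(totals, axis=0) * 1e6)


def pseudobulk(adata: ad.AnnData, labels) -> PseudobulkProfile:
    """Sum counts per group; groups sorted by label for determinism."""
    labels = pd.Series(np.asarray(labels, dtype=object), index=adata.obs_names)
    if labels.isna().any():
        raise ValueError("every cell must be labeled")
    groups = sorted(map(str, pd.unique(labels)))
    x = sp.csr_matrix(adata.X, dtype=float)
    rows = []
    sizes = {}
    for g in groups:
        mask = (labels.astype(str) == g).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"empty group: {g}")
        rows.append(np.asarray(x[mask].sum(axis=0)).ravel())
        sizes[g] = int(mask.sum())
    raw = pd.DataFrame(np.vstack(rows), index=groups, columns=adata.var_names)
    return PseudobulkProfile(raw=raw, logcpm=_logcpm(raw), sizes=pd.Series(sizes))


def correlation_matrix(profile: PseudobulkProfile, genes: Sequence[str]) -> CorrelationMatrix:
    """Pearson r between group log-CPM profiles over the gene list."""
    if len(profile.raw) < 2:
        raise ValueError("need at least 2 groups")
    sub = profile.logcpm.loc[:, list(genes)]
    sd = sub.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ValueError(f"zero variance over gene list in group: {bad}")
    r = np.corrcoef(sub.to_numpy())
    return CorrelationMatrix(groups=list(sub.index), r=r)


def exclude_uncorrelated(
    corr: CorrelationMatrix,
    sizes: pd.Series,
    r_min: float = 0.90,
) -> tuple[list[str], list[str], CorrelationMatrix]:
    """Iteratively drop the least-correlated group until the minimum
    off-diagonal r reaches r_min or only two groups remain.

    "Least correlated" is the group with the smallest mean off-diagonal r;
    ties break by smaller size, then label order.
    """
    if len(corr.groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = list(corr.groups)
    r = corr.r.copy()
    excluded: list[str] = []
    while len(groups) > 2:
        off = r[~np.eye(len(groups), dtype=bool)]
        if off.min() >= r_min:
            break
        mean_off = (r.sum(axis=0) - 1.0) / (len(groups) - 1)
        order = sorted(
            range(len(groups)),
            key=lambda i: (mean_off[i], sizes.get(groups[i], 0), groups[i]),
        )
        drop = order[0]
        excluded.append(groups.pop(drop))
        r = np.delete(np.delete(r, drop, axis=0), drop, axis=1)
    if len(groups) == 2 and r[0, 1] < r_min:
        warnings.warn(
            f"two groups remain with r={r[0, 1]:.3f} < {r_min}; both retained"
        )
    return groups, excluded, CorrelationMatrix(groups=groups, r=r)


def merge_supergroups(
    adata: ad.AnnData,
    labels,
    genes: Sequence[str],
    r_merge: float = 0.95,
    merge_log: list | None = None,
) -> tuple[dict[str, str], CorrelationMatrix | None]:
    """Iteratively pool the most-correlated pair of groups (r >= r_merge)
    into a super-group until the maximum off-diagonal r falls below
    r_merge. Pooled profiles are recomputed from summed member-cell counts,
    not by averaging profiles. Returns fine-label -> super-group mapping
    (super-group named by its sorted member labels joined with '+')."""
    labels = pd.Series(np.asarray(labels, dtype=object), index=adata.obs_names).astype(str)
    fine = sorted(labels.unique())
    members: dict[str, tuple[str, ...]] = {g: (g,) for g in fine}
    profile = pseudobulk(adata, labels)
    raw = profile.raw.copy()

    def corr_of(raw_df: pd.DataFrame) -> CorrelationMatrix:
        prof = PseudobulkProfile(raw=raw_df, logcpm=_logcpm(raw_df), sizes=pd.Series(dtype=int))
        return corr_from_profile(prof)

    def corr_from_profile(prof: PseudobulkProfile) -> CorrelationMatrix:
        return correlation_matrix(prof, genes)

    if len(fine) == 1:
        return {fine[0]: fine[0]}, None
    corr = corr_of(raw)
    while len(raw) > 1:
        names = list(raw.index)
        r = corr.r
        mask = np.triu(np.ones_like(r, dtype=bool), k=1)
        if r[mask].max() < r_merge:
            break
        best = r[mask].max()
        # first pair in label order among the argmax pairs
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if r[i, j] == best
        ]
        a, b = sorted(pairs)[0]
        if merge_log is not None:
            merge_log.append((a, b))
        merged_members = tuple(sorted(members.pop(a) + members.pop(b)))
        new_name = "+".join(merged_members)
        members[new_name] = merged_members
        pooled = raw.loc[a] + raw.loc[b]
        raw = raw.drop(index=[a, b])
        raw.loc[new_name] = pooled
        raw = raw.sort_index()
        if len(raw) == 1:
            corr = None
            break
        corr = corr_of(raw)
    mapping = {m: sg for sg, mem in members.items() for m in mem}
    return mapping, corr


def flag_library_biased(labels, library_ids, frac: float = 0.5) -> set[str]:
    """Groups dominated (> frac of cells, strict) by a single library."""
    labels = pd.Series(np.asarray(labels, dtype=object))
    libs = pd.Series(np.asarray(library_ids, dtype=object))
    if libs.isna().any():
        raise ValueError("every cell must have a library")
    flagged = set()
    for g, grp in libs.groupby(labels):
        if len(grp) == 0:
            raise ValueError(f"empty group: {g}")
        if grp.value_counts(normalize=True).max() > frac:
            flagged.add(str(g))
    return flagged


def optimize_resolution(
    adata: ad.AnnData,
    backend: ClusterBackend,
    res_grid: Sequence[float] | None = None,
    seed: int = 0,
    n_hvg: int = 2000,
    r_exclude: float = 0.90,
    r_merge: float = 0.95,
    q_max: float = 0.05,
    lfc_min: float = 0.25,
) -> SupergroupSolution:
    """Sweep the resolution grid and keep the prune-merge solution with the
    maximal DEG count among super-groups (ties: lowest resolution).

    Variable genes are selected once on the full input so correlations are
    comparable across the sweep. Clusters whose pseudo-bulk has zero
    variance over the variable genes cannot be correlated and are excluded
    up front.
    """
    from .markers import deg_count as _deg_count  # local import avoids cycle

    if res_grid is None:
        res_grid = [round(0.1 * k, 1) for k in range(1, 31)]
    norm = normalize_counts(adata)
    hvg = select_variable_genes(norm, n=n_hvg)

    best: SupergroupSolution | None = None
    trace_rows = []
    for res in res_grid:
        labels = pd.Series(
            np.asarray(backend(norm, float(res), seed), dtype=object),
            index=adata.obs_names,
        ).astype(str)
        n_fine = labels.nunique()
        if n_fine < 2:
            trace_rows.append((res, n_fine, n_fine, 0))
            candidate = SupergroupSolution(
                resolution=float(res),
                fine_labels=labels,
                excluded_clusters=set(),
                supergroup_map={g: g for g in labels.unique()},
                deg_count=0,
            )
            if best is None:
                best = candidate
            continue
        profile = pseudobulk(adata, labels)
        sub = profile.logcpm.loc[:, hvg]
        degenerate = set(sub.index[sub.std(axis=1, ddof=0) == 0])
        retained0 = [g for g in profile.raw.index if g not in degenerate]
        excluded: list[str] = sorted(degenerate)
        if len(retained0) >= 2:
            corr = correlation_matrix(
                PseudobulkProfile(
                    raw=profile.raw.loc[retained0],
                    logcpm=profile.logcpm.loc[retained0],
                    sizes=profile.sizes[retained0],
                ),
                hvg,
            )
            retained, excl2, _ = exclude_uncorrelated(corr, profile.sizes, r_min=r_exclude)
            excluded += excl2
        else:
            retained = retained0
        keep_cells = labels.isin(retained)
        if not keep_cells.any() or len(retained) == 0:
            trace_rows.append((res, n_fine, 0, 0))
            continue
        sub_adata = adata[keep_cells.to_numpy()]
        sg_map, _ = merge_supergroups(
            sub_adata, labels[keep_cells], hvg, r_merge=r_merge
        )
        sg_labels = labels[keep_cells].map(sg_map)
        n_sg = sg_labels.nunique()
        if n_sg >= 2:
            sub_norm = normalize_counts(sub_adata)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                n_deg, _ = _deg_count(sub_norm, sg_labels, q_max=q_max, lfc_min=lfc_min)
        else:
            n_deg = 0
        trace_rows.append((res, n_fine, n_sg, n_deg))
        candidate = SupergroupSolution(
            resolution=float(res),
            fine_labels=labels,
            excluded_clusters=set(excluded),
            supergroup_map=sg_map,
            deg_count=n_deg,
        )
        if best is None or candidate.deg_count > best.deg_count:
            best = candidate
    assert best is not None
    if max(t[1] for t in trace_rows) < 2:
        warnings.warn("backend returned a single cluster at every resolution")
    best.trace = pd.DataFrame(
        trace_rows, columns=["resolution", "n_clusters", "n_supergroups", "deg_count"]
    )
    return best
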
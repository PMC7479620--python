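"""Dissociation-stress gene exclusion.

Genes >= 10-fold discordant between the single-cell pseudo-bulk profile and
a matched bulk RNA-seq library are treated as preparation artifacts
(dissociation-induced stress responses up, metabolic programs down) and
excluded from downstream clustering and DEG reporting. Profiles are
CPM-normalized and the ratio uses a pseudocount so zero-expression genes
yield finite ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd


@dataclass
class FoldChangeTable:
    """Per-gene single-cell vs bulk CPM with sc/bulk ratio and flag
    (up / down / pass at the fold threshold used to build flags)."""

    table: pd.DataFrame  # columns: sc_cpm, bulk_cpm, ratio, flag
    pseudocount: float

    def __post_init__(self):
        if (self.table["ratio"] <= 0).any():
            raise ValueError("ratios must be positive")


def fold_change_table(
    adata: ad.AnnData, bulk: pd.Series, pseudocount: float = 1.0
) -> FoldChangeTable:
    """Compare the cohort's pseudo-bulk against a matched bulk profile.

    Both profiles are scaled to counts-per-million over the union gene set
    (genes absent from one side count 0); ratio = (sc_cpm + pc) / (bulk_cpm
    + pc). Flags are filled in by :func:`flag_stress_genes`.
    """
    sc = pd.Series(
        np.asarray(adata.X.sum(axis=0)).ravel().astype(float), index=adata.var_names
    )
    genes = sc.index.union(bulk.index)
    if sc.index.intersection(bulk.index).empty:
        raise ValueError("gene universes do not intersect")
    sc = sc.reindex(genes, fill_value=0.0)
    bk = bulk.reindex(genes, fill_value=0.0).astype(float)
    if sc.sum() == 0 or bk.sum() == 0:
        raise ValueError("zero total counts on one side")
    sc_cpm = sc / sc.sum() * 1e6
    bulk_cpm = bk / bk.sum() * 1e6
    ratio = (sc_cpm + pseudocount) / (bulk_cpm + pseudocount)
    table = pd.DataFrame(
        {"sc_cpm": sc_cpm, "bulk_cpm": bulk_cpm, "ratio": ratio, "flag": "pass"}
    )
    return FoldChangeTable(table=table, pseudocount=pseudocount)


def flag_stress_genes(
    table: FoldChangeTable, fold_threshold: float = 10.0
) -> tuple[set[str], int, int]:
    """Flag genes with sc/bulk ratio >= fold_threshold (up) or <=
    1/fold_threshold (down); returns (excluded genes, n_up, n_down) and
    writes flags into the table."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    t = table.table
    up = t["ratio"] >= fold_threshold
    down = t["ratio"] <= 1.0 / fold_threshold
    t["flag"] = np.where(up, "up", np.where(down, "down", "pass"))
    excluded = set(t.index[up | down])
    return excluded, int(up.sum()), int(down.sum())
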
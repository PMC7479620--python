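"""Cell-cycle phase scoring and the proliferative-subcluster filter.

Each phase score is the mean log-normalized expression of a small set of
phase genes (Drosophila defaults: Cdk1/CycD/CycE for G1, stg/CycA/CycB for
G2, polo/aurB/Det for M). Cells below the third quartile of the summed
score (G1 + G2 + M) are filtered out, and subclusters retaining more than
25% of their original population are reported as proliferative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .subcluster import NormalizedMatrix


@dataclass
class PhaseGeneSets:
    G1: tuple[str, ...] = ("Cdk1", "CycD", "CycE")
    G2: tuple[str, ...] = ("stg", "CycA", "CycB")
    M: tuple[str, ...] = ("polo", "aurB", "Det")

    def __post_init__(self):
        sets = {"G1": set(self.G1), "G2": set(self.G2), "M": set(self.M)}
        if any(len(s) == 0 for s in sets.values()):
            raise ValueError("phase gene lists must be non-empty")
        if len(sets["G1"] | sets["G2"] | sets["M"]) != sum(map(len, sets.values())):
            raise ValueError("phase gene lists must be disjoint")

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return {"G1": self.G1, "G2": self.G2, "M": self.M}


def phase_scores(norm: NormalizedMatrix, sets: PhaseGeneSets) -> pd.DataFrame:
    """Per-cell phase scores and their total; genes absent from the matrix
    are dropped with a warning, an entirely absent phase is an error."""
    gene_pos = {g: i for i, g in enumerate(norm.gene_names)}
    dense = norm.dense()
    out = {}
    for phase, genes in sets.as_dict().items():
        present = [g for g in genes if g in gene_pos]
        missing = set(genes) - set(present)
        if missing:
            warnings.warn(f"phase {phase}: genes absent from matrix: {sorted(missing)}")
        if not present:
            raise ValueError(f"phase {phase}: no genes present in matrix")
        idx = [gene_pos[g] for g in present]
        out[phase.lower()] = dense[:, idx].mean(axis=1)
    df = pd.DataFrame(out, index=norm.cell_names)
    df["total"] = df["g1"] + df["g2"] + df["m"]
    return df


def cycling_filter(
    scores: pd.DataFrame, quantile: float = 0.75
) -> tuple[pd.Index, float]:
    """Retain cells with total score >= the empirical quantile (linear
    interpolation); all-identical totals retain everything with a warning."""
    if len(scores) < 4:
        raise ValueError("need at least 4 cells")
    totals = scores["total"]
    if totals.nunique() == 1:
        warnings.warn("all cell-cycle totals identical; retaining all cells")
        return scores.index, float(totals.iloc[0])
    threshold = float(np.quantile(totals.to_numpy(), quantile, method="linear"))
    return scores.index[totals >= threshold], threshold


def proliferative_subclusters(
    retained: pd.Index, labels, min_frac: float = 0.25
) -> list[str]:
    """Subclusters whose retained share of their original population is
    strictly greater than min_frac."""
    labels = pd.Series(labels)
    retained_set = set(retained)
    out = []
    for g, grp in labels.groupby(labels):
        if len(grp) == 0:
            raise ValueError(f"empty subcluster: {g}")
        share = np.mean([c in retained_set for c in grp.index])
        if share > min_frac:
            out.append(str(g))
    return sorted(out)
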
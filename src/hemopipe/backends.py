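"""Clustering backends satisfying the ClusterBackend contract:
(NormalizedMatrix, resolution, seed) -> per-cell labels, deterministic
given the seed."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .subcluster import NormalizedMatrix


@dataclass
class PlantedBackend:
    """Granularity-controlled backend built from known cell labels.

    Intended for controlled experiments where the cell hierarchy is known
    (e.g. generator truth): low resolutions return the coarse partition,
    intermediate resolutions the fine partition, and high resolutions
    oversplit the largest fine group into random halves — emulating how a
    community-detection resolution parameter moves a real clustering from
    under- to over-segmentation.
    """

    fine_labels: np.ndarray
    coarse_labels: np.ndarray
    coarse_below: float = 1.0  # resolutions < this return coarse labels
    oversplit_at: float = 2.0  # resolutions >= this oversplit

    def __call__(self, norm: NormalizedMatrix, resolution: float, seed: int) -> np.ndarray:
        if norm.n_cells != len(self.fine_labels):
            raise ValueError("matrix does not match planted labels")
        if resolution < self.coarse_below / 2:
            return np.repeat("all", norm.n_cells)
        if resolution < self.coarse_below:
            return np.asarray(self.coarse_labels, dtype=object)
        labels = np.asarray(self.fine_labels, dtype=object).copy()
        if resolution >= self.oversplit_at:
            sizes = pd.Series(labels).value_counts()
            big = sizes.index[0]
            rows = np.where(labels == big)[0]
            rng = np.random.default_rng(seed + int(resolution * 10))
            half = rng.permutation(rows)[: len(rows) // 2]
            labels[half] = f"{big}/b"
            labels[np.setdiff1d(rows, half)] = f"{big}/a"
        return labels


@dataclass
class LeidenBackend:
    """Graph-based community detection (PCA -> kNN graph -> Leiden) via
    scanpy; the production backend for real cohorts."""

    n_pcs: int = 50
    n_neighbors: int = 15

    def __call__(self, norm: NormalizedMatrix, resolution: float, seed: int) -> np.ndarray:
        import anndata as ad
        import scanpy as sc

        adata = ad.AnnData(X=norm.values.copy())
        adata.obs_names = [str(c) for c in norm.cell_names]
        adata.var_names = [str(g) for g in norm.gene_names]
        n_pcs = min(self.n_pcs, adata.n_obs - 1, adata.n_vars - 1)
        sc.pp.pca(adata, n_comps=n_pcs, random_state=seed)
        sc.pp.neighbors(adata, n_neighbors=self.n_neighbors, random_state=seed)
        sc.tl.leiden(
            adata, resolution=resolution, random_state=seed, key_added="leiden",
            flavor="leidenalg",
        )
        return adata.obs["leiden"].to_numpy(dtype=object)
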
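"""Reading and writing the pipeline's on-disk formats.

A counts directory holds ``matrix.mtx`` (cells x genes, Matrix Market),
``barcodes.tsv``, ``genes.tsv`` and ``cells_metadata.tsv`` (barcode,
library, timepoint, condition). Bulk profiles, regulon definitions and
label tables are plain TSV; gene sets are YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import yaml

from .tf import Regulon


def write_counts(adata: ad.AnnData, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(adata.X))
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", index=False, header=False)
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", index=False, header=False)
    meta = adata.obs.reset_index()
    meta.to_csv(outdir / "cells_metadata.tsv", sep="\t", index=False)


def read_counts(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    x = sp.csr_matrix(sio.mmread(str(indir / "matrix.mtx")))
    barcodes = pd.read_csv(indir / "barcodes.tsv", header=None)[0].astype(str)
    genes = pd.read_csv(indir / "genes.tsv", header=None)[0].astype(str)
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    meta_path = indir / "cells_metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype={0: str}).set_index("barcode")
        obs = obs.join(meta, how="left")
    return ad.AnnData(X=x, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


def write_bulk(bulk: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"gene": bulk.index, "count": bulk.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def read_bulk(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "count"}.issubset(df.columns):
        raise ValueError("bulk table must have columns: gene, count")
    return pd.Series(df["count"].to_numpy(float), index=df["gene"].astype(str), name="count")


def read_regulons(path: str | Path) -> list[Regulon]:
    """Regulon TSV with columns ``tf`` and ``target``, one pair per row."""
    df = pd.read_csv(path, sep="\t")
    if not {"tf", "target"}.issubset(df.columns):
        raise ValueError("regulon table must have columns: tf, target")
    out = []
    for tf, grp in df.groupby("tf", sort=True):
        out.append(Regulon(tf=str(tf), targets=frozenset(grp["target"].astype(str))))
    return out


def write_regulons(regulons: list[Regulon], path: str | Path) -> None:
    rows = [(r.tf, t) for r in regulons for t in sorted(r.targets)]
    pd.DataFrame(rows, columns=["tf", "target"]).to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """YAML mapping of set name -> gene list (e.g. cell-cycle phases)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError("gene-set file must map set names to gene lists")
    return {str(k): [str(g) for g in v] for k, v in data.items()}


def read_gene_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def read_labels(path: str | Path, column: str) -> pd.Series:
    """Per-barcode labels from a TSV with a ``barcode`` column."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "barcode" not in df.columns or column not in df.columns:
        raise ValueError(f"labels table must have columns: barcode, {column}")
    return df.set_index("barcode")[column]


def counts_per_barcode(adata: ad.AnnData) -> pd.Series:
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    return pd.Series(totals, index=adata.obs_names, name="reads")
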
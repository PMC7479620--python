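"""Barcode selection from cumulative read curves and per-cell QC filters.

Real cells are separated from ambient barcodes by the knee of the
barcode-rank cumulative read curve; surviving cells are then filtered by
detected-gene bounds, a per-library UMI-count outlier rule (mean + k*SD,
against multiplets) and a mitochondrial-fraction cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd


class KneeError(ValueError):
    """Raised when a cumulative curve has no detectable knee."""


class AllCellsRemovedError(ValueError):
    """Raised when a QC step removes every remaining cell."""

    def __init__(self, step: str):
        super().__init__(f"all cells removed at step: {step}")
        self.step = step


@dataclass(frozen=True)
class CumulativeCurve:
    """Barcodes ranked by descending read count with cumulative read
    fraction; ranks are 1-based."""

    barcodes: np.ndarray
    reads: np.ndarray
    cum_fraction: np.ndarray

    def __post_init__(self):
        f = self.cum_fraction
        if np.any(np.diff(f) < -1e-12) or abs(f[-1] - 1.0) > 1e-9:
            raise ValueError("cumulative fraction must be non-decreasing and end at 1")


@dataclass
class QcThresholds:
    """Study QC rules: gene-count bounds (inclusive), UMI outlier rule at
    mean + umi_sd_mult*SD per library, and a mitochondrial-fraction cap."""

    min_reads_per_cell: int | dict | str = "auto"
    gene_upper: int = 5000
    gene_lower: int = 400
    umi_sd_mult: float = 2.0
    mito_max_fraction: float = 0.10
    mito_gene_set: tuple[str, ...] = ()

    def __post_init__(self):
        if self.gene_lower >= self.gene_upper:
            raise ValueError("gene_lower must be < gene_upper")
        if not (0.0 < self.mito_max_fraction < 1.0):
            raise ValueError("mito_max_fraction must be in (0, 1)")


@dataclass
class QcReport:
    barcodes_in: int
    removed: dict[str, int] = field(default_factory=dict)
    barcodes_retained: int = 0

    def check(self) -> None:
        assert self.barcodes_in == self.barcodes_retained + sum(self.removed.values())


def cumulative_curve(reads_per_barcode: pd.Series) -> CumulativeCurve:
    """Rank barcodes by reads (descending) and accumulate read fractions."""
    reads = pd.Series(reads_per_barcode).astype(float)
    if len(reads) < 2:
        raise ValueError("need at least 2 barcodes")
    if (reads < 0).any():
        raise ValueError("negative read counts")
    total = reads.sum()
    if total == 0:
        raise ValueError("total reads is zero")
    # stable sort: ties keep barcode order, so runs are reproducible
    order = np.lexsort((np.arange(len(reads)), -reads.to_numpy()))
    sorted_reads = reads.to_numpy()[order]
    return CumulativeCurve(
        barcodes=reads.index.to_numpy()[order],
        reads=sorted_reads,
        cum_fraction=np.cumsum(sorted_reads) / total,
    )


def detect_knee(curve: CumulativeCurve) -> int:
    """Read-count threshold at the knee of the cumulative curve.

    The knee is the rank maximizing perpendicular distance from the chord
    joining the curve's endpoints in (log10 rank, cumulative fraction)
    space; the threshold is the read count of the barcode at that rank, and
    barcodes with reads >= threshold are selected.
    """
    n = len(curve.reads)
    if n < 3:
        raise KneeError("need at least 3 ranked barcodes to locate a knee")
    x = np.log10(np.arange(1, n + 1, dtype=float))
    y = curve.cum_fraction
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    # signed distance, positive where the curve bulges above the chord —
    # the side where the slope drop from cells to ambient barcodes lives
    dist = (dx * (y - y[0]) - dy * (x - x[0])) / norm
    if dist.max() < 1e-12:
        raise KneeError("curve is linear in (log10 rank, fraction) space; no knee")
    knee_rank = int(np.argmax(dist))  # 0-based index of knee rank
    return int(curve.reads[knee_rank])


def select_cells(reads_per_barcode: pd.Series, min_reads: int | None = None) -> pd.Index:
    """Barcodes with reads >= threshold (knee-detected when not given)."""
    reads = pd.Series(reads_per_barcode)
    if min_reads is None:
        min_reads = detect_knee(cumulative_curve(reads))
    return reads.index[reads >= min_reads]


def _mito_fraction(adata: ad.AnnData, mito_genes: tuple[str, ...]) -> np.ndarray:
    present = [g for g in mito_genes if g in adata.var_names]
    absent = set(mito_genes) - set(present)
    if absent:
        warnings.warn(f"mito genes absent from matrix: {sorted(absent)}")
    totals = np.asarray(adata.X.sum(axis=1)).ravel().astype(float)
    if not present:
        return np.zeros(adata.n_obs)
    sub = adata[:, present].X
    mito = np.asarray(sub.sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / totals, 0.0)
    return frac


def qc_filter_cells(
    adata: ad.AnnData, thresholds: QcThresholds
) -> tuple[ad.AnnData, QcReport]:
    """Apply the QC rules in sequence, each barcode counted at its first
    failing rule: (1) minimum reads (knee per library when "auto"),
    (2) detected genes in [gene_lower, gene_upper], (3) total UMI above
    mean + k*SD within a library (mean/SD over step-2 survivors of that
    library), (4) mitochondrial fraction above the cap."""
    report = QcReport(barcodes_in=adata.n_obs)
    libraries = (
        adata.obs["library"].astype(str)
        if "library" in adata.obs
        else pd.Series("all", index=adata.obs_names)
    )
    totals = pd.Series(
        np.asarray(adata.X.sum(axis=1)).ravel().astype(float), index=adata.obs_names
    )

    # step 1: minimum reads per cell, per library
    keep = np.ones(adata.n_obs, dtype=bool)
    mr = thresholds.min_reads_per_cell
    for lib in libraries.unique():
        mask = (libraries == lib).to_numpy(dtype=bool)
        if mr == "auto":
            thr = detect_knee(cumulative_curve(totals[mask]))
        elif isinstance(mr, dict):
            thr = mr.get(lib, 0)
        else:
            thr = int(mr)
        keep[mask] = totals.to_numpy()[mask] >= thr
    report.removed["knee"] = int((~keep).sum())
    if not keep.any():
        raise AllCellsRemovedError("knee")
    adata = adata[keep].copy()
    libraries, totals = libraries[keep], totals[keep]

    # step 2: detected-gene bounds (inclusive)
    genes_detected = np.asarray((adata.X > 0).sum(axis=1)).ravel()
    keep = (genes_detected >= thresholds.gene_lower) & (
        genes_detected <= thresholds.gene_upper
    )
    report.removed["gene_bounds"] = int((~keep).sum())
    if not keep.any():
        raise AllCellsRemovedError("gene_bounds")
    adata = adata[keep].copy()
    libraries, totals = libraries[keep], totals[keep]

    # step 3: UMI outliers (multiplets), per library
    keep = np.ones(adata.n_obs, dtype=bool)
    for lib in libraries.unique():
        mask = (libraries == lib).to_numpy(dtype=bool)
        t = totals.to_numpy()[mask]
        cut = t.mean() + thresholds.umi_sd_mult * t.std(ddof=0)
        keep[mask] = t <= cut
    report.removed["umi_outlier"] = int((~keep).sum())
    if not keep.any():
        raise AllCellsRemovedError("umi_outlier")
    adata = adata[keep].copy()

    # step 4: mitochondrial fraction
    frac = _mito_fraction(adata, tuple(thresholds.mito_gene_set))
    keep = frac <= thresholds.mito_max_fraction
    report.removed["mito"] = int((~keep).sum())
    if not keep.any():
        raise AllCellsRemovedError("mito")
    adata = adata[keep].copy()

    report.barcodes_retained = adata.n_obs
    report.check()
    return adata, report
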
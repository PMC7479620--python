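"""Synthetic UMI-count cohorts with planted hematopoietic structure.

The generator emulates the statistical structure of a droplet scRNA-seq
experiment on the Drosophila larval lymph gland together with a matched
bulk RNA-seq profile: overdispersed (negative-binomial) UMI counts, planted
cell subtypes with marker programs, near-duplicate subtype pairs that form
coarse "super-groups", per-library batch effects, a per-cell mitochondrial
fraction, ambient low-depth barcodes, a dissociation-stress program present
only in the single-cell counts, cell-cycle programs, and regulons (TF target
sets) co-elevated in designated subtypes.

Every downstream stage of the pipeline (knee selection, QC, stress-gene
exclusion, subcluster optimization, cell-cycle scoring, regulon-activity
consensus) is testable against the ground truth record returned alongside
the matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp


class ConfigurationError(ValueError):
    """Raised when a SynthConfig is internally inconsistent."""


@dataclass(frozen=True)
class RegulonSpec:
    """A planted regulon: a TF name, its target genes, and the subtypes in
    which the targets are coordinately elevated (empty = never active)."""

    tf: str
    targets: tuple[str, ...]
    active_subtypes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise ConfigurationError(f"regulon {self.tf}: TF cannot be its own target")
        if len(set(self.targets)) != len(self.targets):
            raise ConfigurationError(f"regulon {self.tf}: duplicate targets")


#: default cell-cycle phase gene sets (Drosophila cyclins / mitotic kinases)
DEFAULT_CC_GENE_SETS: dict[str, tuple[str, ...]] = {
    "G1": ("Cdk1", "CycD", "CycE"),
    "G2": ("stg", "CycA", "CycB"),
    "M": ("polo", "aurB", "Det"),
}


@dataclass
class SynthConfig:
    """Parameters of a synthetic cohort.

    Counts for cell ``c`` and gene ``g`` are drawn NB(mean = m_cg, shared
    dispersion ``nb_dispersion``) where m_cg is a per-gene base weight
    (log-normal across genes, sd ``base_weight_sd``) modulated by subtype
    marker effects, library batch effects, planted programs (stress,
    cell cycle, regulons) and a per-cell depth factor, then scaled so each
    cell's expected depth is ``mean_depth`` with the drawn mitochondrial
    fraction assigned to the mitochondrial genes.
    """

    n_cells: int = 2000
    n_genes: int = 1000
    n_subtypes: int = 4
    subtype_proportions: tuple[float, ...] | None = None
    libraries: int = 4
    batch_logfc_sd: float = 0.1
    marker_genes_per_subtype: int = 30
    marker_logfc: float = 2.0
    private_markers_per_subtype: int = 5
    supergroup_map: Mapping[int, str] | None = None
    noise_subtypes: tuple[int, ...] = ()
    nb_dispersion: float = 2.0
    mean_depth: float = 2000.0
    depth_logsd: float = 0.3
    base_weight_sd: float = 1.5
    mito_fraction_range: tuple[float, float] = (0.01, 0.08)
    n_mito_genes: int = 10
    n_ambient_barcodes: int = 0
    ambient_depth_factor: float = 0.02
    stress_gene_count: int = 0
    stress_logfc: float = math.log(20.0)
    regulons: tuple[RegulonSpec, ...] = ()
    regulon_logfc: float = math.log(100.0)
    regulon_target_weight: float = 0.005
    cc_gene_sets: Mapping[str, Sequence[str]] | None = None
    cc_program_weight: float = 2.0
    cc_logfc: float = math.log(4.0)
    cycling_subtypes: tuple[int, ...] = ()
    timepoints: tuple[str, ...] = ("96h",)
    condition: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subtype_proportions is None:
            self.subtype_proportions = tuple([1.0 / self.n_subtypes] * self.n_subtypes)
        if self.supergroup_map is None:
            self.supergroup_map = {s: f"G{s}" for s in range(self.n_subtypes)}
        self.validate()

    def validate(self) -> None:
        if min(self.n_cells, self.n_genes, self.n_subtypes, self.libraries) <= 0:
            raise ConfigurationError("n_cells, n_genes, n_subtypes, libraries must be positive")
        if len(self.subtype_proportions) != self.n_subtypes:
            raise ConfigurationError("subtype_proportions length != n_subtypes")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ConfigurationError("subtype_proportions must sum to 1")
        if any(p < 0 for p in self.subtype_proportions):
            raise ConfigurationError("subtype_proportions must be non-negative")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if not (0.0 <= self.mito_fraction_range[0] <= self.mito_fraction_range[1] < 1.0):
            raise ConfigurationError("mito_fraction_range must be an interval in [0, 1)")
        if not (0.0 < self.ambient_depth_factor < 1.0):
            raise ConfigurationError("ambient_depth_factor must be in (0, 1)")
        if set(self.supergroup_map) != set(range(self.n_subtypes)):
            raise ConfigurationError("supergroup_map must cover every subtype index")
        if any(s not in range(self.n_subtypes) for s in self.noise_subtypes):
            raise ConfigurationError("noise_subtypes out of range")
        cc = self.cc_gene_sets or {}
        n_named = sum(len(v) for v in cc.values()) + sum(
            1 + len(r.targets) for r in self.regulons
        )
        n_coarse = len(set(self.supergroup_map.values()))
        demand = (
            self.n_mito_genes
            + n_named
            + self.stress_gene_count
            + n_coarse * self.marker_genes_per_subtype
            + self.n_subtypes * self.private_markers_per_subtype
        )
        if demand > self.n_genes:
            raise ConfigurationError(
                f"gene demands ({demand}) exceed n_genes ({self.n_genes})"
            )


@dataclass
class SyntheticTruth:
    """Ground truth for a generated cohort (real cells only carry subtype
    labels; ambient barcodes carry the ambient flag)."""

    cell_subtype: np.ndarray  # int per real cell
    cell_library: np.ndarray  # str per real cell
    coarse_group: np.ndarray  # str per real cell
    ambient_flag: np.ndarray  # bool per barcode (real + ambient)
    stress_genes: tuple[str, ...]
    marker_map: dict[int, tuple[str, ...]]
    regulon_truth: dict[str, tuple[int, ...]]
    stress_logfc: float = 0.0

    def to_json(self) -> str:
        d = {
            "cell_subtype": self.cell_subtype.tolist(),
            "cell_library": self.cell_library.tolist(),
            "coarse_group": self.coarse_group.tolist(),
            "ambient_flag": self.ambient_flag.astype(bool).tolist(),
            "stress_genes": list(self.stress_genes),
            "marker_map": {str(k): list(v) for k, v in self.marker_map.items()},
            "regulon_truth": {k: list(v) for k, v in self.regulon_truth.items()},
            "stress_logfc": self.stress_logfc,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            cell_subtype=np.asarray(d["cell_subtype"], dtype=int),
            cell_library=np.asarray(d["cell_library"], dtype=object),
            coarse_group=np.asarray(d["coarse_group"], dtype=object),
            ambient_flag=np.asarray(d["ambient_flag"], dtype=bool),
            stress_genes=tuple(d["stress_genes"]),
            marker_map={int(k): tuple(v) for k, v in d["marker_map"].items()},
            regulon_truth={k: tuple(v) for k, v in d["regulon_truth"].items()},
            stress_logfc=float(d["stress_logfc"]),
        )


def _exact_counts(proportions: Sequence[float], n: int) -> np.ndarray:
    """Largest-remainder allocation so subtype sizes are deterministic."""
    raw = np.asarray(proportions, dtype=float) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw with variance mean + mean^2/dispersion (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        m = mean[pos]
        p = dispersion / (dispersion + m)
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def generate_cohort(config: SynthConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Generate a cohort: sparse UMI counts with obs metadata plus the truth.

    The returned AnnData has real cells first, then ambient barcodes;
    ``obs`` columns: library, timepoint, condition, ambient.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_cells, n_genes = config.n_cells, config.n_genes

    # --- gene universe and named-gene allocation -------------------------
    gene_names = np.array([f"g{i + 1:05d}" for i in range(n_genes)], dtype=object)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        idx = np.arange(cursor, cursor + k)
        cursor += k
        return idx

    mito_idx = take(config.n_mito_genes)
    for j, i in enumerate(mito_idx):
        gene_names[i] = f"mt:{j + 1:02d}"

    cc_sets = {k: tuple(v) for k, v in (config.cc_gene_sets or {}).items()}
    cc_idx: dict[str, np.ndarray] = {}
    for phase, genes in cc_sets.items():
        idx = take(len(genes))
        gene_names[idx] = list(genes)
        cc_idx[phase] = idx

    regulon_tf_idx: dict[str, int] = {}
    regulon_target_idx: dict[str, np.ndarray] = {}
    for reg in config.regulons:
        i = take(1)[0]
        gene_names[i] = reg.tf
        regulon_tf_idx[reg.tf] = i
        idx = take(len(reg.targets))
        gene_names[idx] = list(reg.targets)
        regulon_target_idx[reg.tf] = idx

    stress_idx = take(config.stress_gene_count)

    # shared (coarse-group) and private marker genes
    coarse_of = {s: str(config.supergroup_map[s]) for s in range(config.n_subtypes)}
    coarse_labels = sorted(set(coarse_of.values()))
    shared_marker_idx = {c: take(config.marker_genes_per_subtype) for c in coarse_labels}
    private_marker_idx = {
        s: take(config.private_markers_per_subtype) for s in range(config.n_subtypes)
    }

    # --- per-gene base weights ------------------------------------------
    weights = rng.lognormal(mean=0.0, sigma=config.base_weight_sd, size=n_genes)
    for idx in cc_idx.values():
        weights[idx] = config.cc_program_weight
    for tf, idx in regulon_target_idx.items():
        weights[idx] = config.regulon_target_weight
    # noise subtypes get an independently drawn weight profile, emulating a
    # contaminating cell type (neurons / ring gland in a lymph-gland prep)
    noise_weights = {
        s: rng.lognormal(mean=0.0, sigma=config.base_weight_sd, size=n_genes)
        for s in config.noise_subtypes
    }

    # --- cell assignments ------------------------------------------------
    sizes = _exact_counts(config.subtype_proportions, n_cells)
    subtype = rng.permutation(np.repeat(np.arange(config.n_subtypes), sizes))
    lib_ids = np.array([f"lib{i + 1}" for i in range(config.libraries)], dtype=object)
    library = lib_ids[rng.integers(0, config.libraries, size=n_cells)]
    tp_of_lib = {
        lib: config.timepoints[i % len(config.timepoints)] for i, lib in enumerate(lib_ids)
    }
    timepoint = np.array([tp_of_lib[l] for l in library], dtype=object)

    batch_fx = np.exp(
        rng.normal(0.0, config.batch_logfc_sd, size=(config.libraries, n_genes))
    )
    lib_index = {lib: i for i, lib in enumerate(lib_ids)}

    # --- expected-count matrix ------------------------------------------
    mean = np.empty((n_cells, n_genes), dtype=float)
    for s in range(config.n_subtypes):
        rows = np.where(subtype == s)[0]
        if rows.size == 0:
            continue
        w = (noise_weights[s] if s in noise_weights else weights).copy()
        w[shared_marker_idx[coarse_of[s]]] *= math.exp(config.marker_logfc)
        w[private_marker_idx[s]] *= math.exp(config.marker_logfc)
        if config.stress_gene_count:
            w[stress_idx] *= math.exp(config.stress_logfc)
        if s in config.cycling_subtypes:
            for idx in cc_idx.values():
                w[idx] *= math.exp(config.cc_logfc)
        for reg in config.regulons:
            if s in reg.active_subtypes:
                w[regulon_target_idx[reg.tf]] *= math.exp(config.regulon_logfc)
                w[regulon_tf_idx[reg.tf]] *= math.exp(config.regulon_logfc / 2)
        mean[rows] = w
    mean *= batch_fx[[lib_index[l] for l in library], :]

    # mitochondrial mass set per cell, remainder renormalized to depth
    mito_frac = rng.uniform(*config.mito_fraction_range, size=n_cells)
    depth = config.mean_depth * rng.lognormal(0.0, config.depth_logsd, size=n_cells)
    non_mito = np.ones(n_genes, dtype=bool)
    non_mito[mito_idx] = False
    mean[:, mito_idx] = 0.0
    row_tot = mean.sum(axis=1, keepdims=True)
    mean *= ((1.0 - mito_frac) * depth)[:, None] / row_tot
    if config.n_mito_genes:
        mito_w = np.full(config.n_mito_genes, 1.0 / config.n_mito_genes)
        mean[:, mito_idx] = (mito_frac * depth)[:, None] * mito_w[None, :]

    counts = _nb_sample(rng, mean, config.nb_dispersion)

    # --- ambient barcodes: pooled profile at a fraction of the depth -----
    n_amb = config.n_ambient_barcodes
    if n_amb:
        pooled = mean.mean(axis=0)
        pooled = pooled / pooled.sum()
        amb_depth = config.ambient_depth_factor * config.mean_depth * rng.lognormal(
            0.0, config.depth_logsd, size=n_amb
        )
        amb_mean = amb_depth[:, None] * pooled[None, :]
        amb_counts = _nb_sample(rng, amb_mean, config.nb_dispersion)
        counts = np.vstack([counts, amb_counts])

    barcodes = [f"cell{i + 1:06d}" for i in range(n_cells)] + [
        f"ambient{i + 1:06d}" for i in range(n_amb)
    ]
    # ambient barcodes occur within the real libraries, like empty droplets
    amb_library = lib_ids[rng.integers(0, config.libraries, size=n_amb)]
    amb_timepoint = np.array([tp_of_lib[l] for l in amb_library], dtype=object)
    obs = pd.DataFrame(
        {
            "library": np.concatenate([library, amb_library]),
            "timepoint": np.concatenate([timepoint, amb_timepoint]),
            "condition": np.repeat(config.condition, n_cells + n_amb),
            "ambient": np.concatenate(
                [np.zeros(n_cells, bool), np.ones(n_amb, bool)]
            ),
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    var = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    var["mito"] = [g.startswith("mt:") for g in gene_names]
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)

    truth = SyntheticTruth(
        cell_subtype=subtype,
        cell_library=library,
        coarse_group=np.array([coarse_of[s] for s in subtype], dtype=object),
        ambient_flag=obs["ambient"].to_numpy(),
        stress_genes=tuple(gene_names[stress_idx]),
        marker_map={
            s: tuple(
                gene_names[np.concatenate([shared_marker_idx[coarse_of[s]], private_marker_idx[s]])]
            )
            for s in range(config.n_subtypes)
        },
        regulon_truth={r.tf: tuple(r.active_subtypes) for r in config.regulons},
        stress_logfc=config.stress_logfc if config.stress_gene_count else 0.0,
    )
    return adata, truth


def make_bulk_profile(adata: ad.AnnData, truth: SyntheticTruth) -> pd.Series:
    """Matched bulk profile: per-gene sums over non-ambient cells with the
    dissociation-stress multiplier removed (stress genes divided by
    exp(stress_logfc)). Stands in for a bulk RNA-seq library prepared
    without tissue dissociation into single cells."""
    if adata.n_obs != truth.ambient_flag.size:
        raise ValueError("truth/matrix mismatch: barcode counts differ")
    missing = set(truth.stress_genes) - set(adata.var_names)
    if missing:
        raise ValueError(f"truth/matrix mismatch: stress genes absent: {sorted(missing)}")
    real = ~truth.ambient_flag
    sums = np.asarray(adata.X[real].sum(axis=0)).ravel().astype(float)
    bulk = pd.Series(sums, index=adata.var_names, name="count")
    if truth.stress_genes:
        bulk.loc[list(truth.stress_genes)] /= math.exp(truth.stress_logfc)
    return bulk


def write_cohort(adata: ad.AnnData, truth: SyntheticTruth, outdir: str | Path) -> None:
    """Write MTX + barcodes.tsv + genes.tsv + cells_metadata.tsv + bulk.tsv
    + truth.json into ``outdir``."""
    from . import io as hio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hio.write_counts(adata, outdir)
    bulk = make_bulk_profile(adata, truth)
    hio.write_bulk(bulk, outdir / "bulk.tsv")
    (outdir / "truth.json").write_text(truth.to_json())
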
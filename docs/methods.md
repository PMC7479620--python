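# Methods

hemopipe re-implements, as a tested and reusable library, the bespoke
computational procedures used in single-cell transcriptomic studies of
*Drosophila* lymph-gland hematopoiesis: knee-based barcode selection,
per-cell QC, exclusion of dissociation-induced stress genes against a
matched bulk library, a resolution-optimized subclustering algorithm with
pseudo-bulk correlation pruning and merging, cell-cycle scoring with a
proliferative-subcluster filter, and a balanced-resampling consensus for
transcription-factor (regulon) activity. Every stage is exercised end to
end on a synthetic cohort generator whose planted structure the stages must
recover.

## Synthetic cohorts

Counts for cell *c*, gene *g* are negative binomial with mean
m<sub>cg</sub> and shared dispersion θ (default 2), i.e. variance
m + m²/θ — overdispersed UMI data rather than Poisson, so that the
downstream rank tests face realistic variance. The mean is a product of:

- a per-gene base weight, log-normal across genes with sd 1.5 (log scale);
- subtype marker effects: each coarse group carries 30 shared marker genes
  and each subtype 5 private markers, multiplied by e^2.0. Subtypes that
  share a coarse group differ only in their private markers, which by
  construction puts their pseudo-bulk Pearson correlation above 0.95 while
  distinct coarse groups land in [0.90, 0.95) — the regime the
  prune-and-merge subclustering algorithm is designed for. "Noise"
  subtypes (contaminating cell types such as neurons or ring gland in a
  lymph-gland dissection) draw an independent weight profile and correlate
  near zero with everything else;
- per-library batch effects, log-normal with sd 0.1 over 4 libraries
  (studies of this organ typically sequence at least four libraries per
  timepoint);
- a per-cell depth factor (mean 2000 UMIs, log-sd 0.3), with the
  mitochondrial genes pinned to a per-cell fraction drawn uniformly from
  [0.01, 0.08];
- optional programs: a dissociation-stress program (multiplier e^ln20 on
  20 genes, single-cell counts only), cell-cycle programs (the nine
  *Drosophila* phase genes at weight 2.0, ×4 in cycling subtypes), and
  regulons — target sets at a low base weight (0.005 relative, i.e.
  near-silent outside their active population) induced ×100 in active
  subtypes, the expression pattern of a master-regulator program.

Ambient barcodes are drawn from the pooled mean profile at 2% of the mean
depth, which creates the two-slope cumulative read curve the knee detector
needs. Subtype sizes use largest-remainder allocation so that stated
population sizes (e.g. a 63-cell subcluster) are exact. A fixed seed gives
byte-identical output.

The matched "bulk" profile is the per-gene sum over non-ambient cells with
the stress multiplier divided out — a bulk library prepared without
dissociation into single cells, which is the premise of the stress filter.

What the generator does **not** emulate: doublets, trajectory/pseudotime
continuity, read-level errors, gene-length or GC biases, and
cross-timepoint composition shifts. Tests passing on these cohorts show
the algorithms recover the structure they are specified against, not that
any particular biological dataset satisfies those assumptions.

## Barcode selection and QC

The cumulative read-fraction curve over barcodes ranked by descending
reads is examined in (log₁₀ rank, cumulative fraction) space; the knee is
the rank maximizing the signed perpendicular distance above the chord
joining the curve's endpoints, and its read count becomes the per-library
minimum-reads threshold. The signed (not absolute) distance matters: below
the knee the curve dips under the chord, and the unsigned maximum can land
on the wrong side. An explicit per-library `min_reads` override reproduces
thresholds chosen by eye (studies report values like 30,000 down to 2,000
reads per cell per library).

QC applies, in order, with each barcode counted at its first failing rule:
(1) the minimum-reads rule per library; (2) detected-gene bounds, inclusive
[400, 5000]; (3) removal of cells whose total UMI exceeds mean + 2·SD,
with mean/SD computed per library over step-2 survivors (a multiplet
guard); (4) removal of cells with >10% mitochondrial UMIs. Whether the
2-SD rule precedes or follows the gene bounds is a convention (order 2→3
here); rerunning the filter is non-increasing and is a no-op whenever step
3 removed nothing.

## Stress-gene filter

Single-cell pseudo-bulk (column sums) and bulk profiles are both scaled to
counts per million; the per-gene ratio uses a pseudocount of 1 on the CPM
scale so zero-expression genes yield finite ratios (the original
procedure's zero handling is unstated; the pseudocount is reported in the
output). Genes with ratio ≥ 10 (up) or ≤ 0.1 (down) are excluded.
Swapping the two sides inverts every ratio exactly, and raising the fold
threshold never enlarges the exclusion set.

## Optimal subclustering

For each resolution r in 0.1…3.0 (step 0.1):

1. cluster (pluggable backend; the production backend is PCA → kNN →
   Leiden via scanpy, deterministic given a seed);
2. aggregate fine clusters to pseudo-bulk (summed counts → log1p CPM) and
   correlate over the top-2000 dispersion-ranked variable genes, selected
   once on the full input so correlation scales are comparable across the
   sweep;
3. iteratively exclude the least correlated cluster — operationalized as
   smallest mean off-diagonal r, ties broken by smaller size then label —
   while the minimum off-diagonal r is below 0.90, keeping at least two
   groups (a correlation matrix needs two rows, and the stop condition is
   undefined for one);
4. iteratively merge the most correlated pair while the maximum
   off-diagonal r is ≥ 0.95, re-pooling member-cell counts (not averaging
   profiles) before recomputing correlations, so group sizes are
   respected;
5. count DEGs among the resulting super-groups: one-vs-rest Wilcoxon
   rank-sum per gene (genes detected in ≥3 cells; groups of <3 cells
   excluded), BH within each comparison, a gene counted once if q < 0.05
   and |log₂FC| ≥ 0.25 in any comparison (unique genes, not gene-group
   pairs; thresholds config-exposed).

The chosen solution maximizes the DEG count, ties to the lowest
resolution. Exclusion recomputes its statistic after every removal
(iterative, not batch). Clusters whose pseudo-bulk is constant over the
variable genes cannot be correlated and are pruned up front. On ≤6-group
instances the merge order provably equals brute-force re-pooling
agglomeration (tested against an independent oracle, 100 random
structures).

For recovery scoring, the excluded clusters count as their own groups in
the recovered partition: a planted cohort with two near-duplicate pairs,
one singleton group and one noise group (4 coarse groups in total) is
recovered as 3 merged super-groups plus the excluded noise cluster, and
this 4-group partition is compared against the planted coarse labels by
adjusted Rand index.

## Marker statistics

`rank_sum_test` uses exact null enumeration when n₁+n₂ ≤ 20 without ties,
otherwise the tie-corrected normal approximation with continuity
correction (both via scipy); two constant identical samples return p = 1
with a degenerate flag. Tests are two-sided except the activity caller's
one-sided "greater" contrast. BH adjustment wraps the standard step-up
with monotonicity. log₂ fold changes are computed on
expm1-back-transformed group means with pseudocount 1, since "fold change"
on log-normalized values is otherwise ambiguous. Proportion tables report
raw counts, within-condition shares, counts normalized to the first
condition's total, and share ratios between condition pairs (a zero
denominator yields NaN, not infinity).

## Cell-cycle scoring

Phase scores are the per-cell mean log-normalized expression of the phase
gene sets (G1: Cdk1, CycD, CycE; G2: stg, CycA, CycB; M: polo, aurB, Det);
normalized rather than z-scored expression is used (configurable). The
retention threshold is the empirical third quartile of the total score
under the linear-interpolation (type-7) quantile definition, recorded in
the output — the published cut of 0.784 is an empirical quantile of a
particular dataset, so the rule, not the value, is reproduced. Cells with
total ≥ Q3 are retained and subclusters retaining strictly more than 25%
of their population are reported as proliferative.

## Balanced-resampling regulon consensus

Activity calls on a full dataset are biased against small populations.
The gene filter that precedes activity scoring keeps genes with total UMI
> 3·(3% of N) expressed in ≥ 3% of N cells; both thresholds scale with the
dataset size N, so targets of a regulon confined to a 63-cell subcluster
of a 10,000-cell cohort are filtered out before scoring (they would need
300 expressing cells), and a single whole-data call cannot see the
regulon. In a balanced subsample — floor(2/3 × smallest subcluster) cells
drawn without replacement from every subcluster — the same relative
thresholds are small enough for the subcluster's cells to carry its
targets through the filter.

The consensus runs 100 such trials (trial seeds derived deterministically
from the master seed and trial index), tallies the per-trial active TF
sets from a pluggable caller, and keeps TFs active in ≥ 25 trials. The
reference caller scores each regulon per cell as the mean normalized
expression of its surviving targets and calls a TF active when some
subcluster exceeds all other cells (one-sided rank-sum, BH over all
TF × subcluster tests, q < 0.05, positive mean difference). A full
regulon-discovery engine can be substituted through the same callable
contract; regulon definitions are inputs here because motif databases and
network inference are outside this package's scope. Failed trials are
recorded; more than 10% aborts the run.

Pseudo-bulk activity profiles per (group, timepoint) average z-scored
normalized expression, dropping combinations below 0.1% of all cells
(19 cells in a 19,332-cell cohort).

## Problem sizes and numerical choices

The test-suite and acceptance-script cohorts use 2,000 cells × 1,000 genes
for subclustering and stress recovery, 10,000 cells × 500 genes × 20
generator seeds for the consensus study, and 3,000 barcodes for knee
selection — sizes at which every planted effect is comfortably powered
and the whole acceptance run completes in a few minutes. Tie-breaks
(label order in merges, smaller-size-first in exclusion, lowest resolution
on DEG ties) make every run deterministic given a seed. Degenerate inputs
(zero-total cells, constant genes, single clusters, empty conditions)
raise explicit errors naming the offender rather than propagating NaNs.

## Known limitations

- The reference activity caller is a deliberately simple rank-sum
  contrast; it shares only the gene-filter and consensus layers with
  motif-based regulon discovery pipelines.
- The exclusion statistic ("least correlated" = smallest mean off-diagonal
  r) is one reasonable operationalization of a criterion that is usually
  stated only qualitatively.
- Batch effects are multiplicative and library-uniform; the generator
  cannot produce the timepoint-specific subcluster artifacts that
  motivated the original library-bias filter, only uniform mixing under
  which the filter should stay silent.
- DEG counting under the asymptotic rank-sum approximation is slightly
  conservative for very small groups; groups under 3 cells are excluded
  outright.
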
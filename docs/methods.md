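# Methods notes

## Normalization

Pseudo-bulk profiles are built by summing raw UMI counts over the cells of
a cluster; no per-cell normalization precedes pooling. Pooled columns are
scaled to counts-per-million and divided by a TMM scaling factor. The TMM
implementation follows the standard published definition: the reference
column is the one whose upper quartile of nonzero CPM is closest to the
mean upper quartile; M-values against the reference are doubly trimmed
(30% from each tail by M rank, 5% by average-abundance rank) and averaged
with inverse asymptotic binomial variance weights; factors are rescaled to
geometric mean 1. The implementation reproduces edgeR's `calcNormFactors`
to at least six significant digits on negative-binomial test data (checked
in the test suite via `Rscript`). Genes with zero counts in either column
are excluded from the M/A computation.

TMM factors are computed **within each tissue's clusters** and the
normalized columns concatenated, since each tissue is mapped and
quantified as its own dataset; joint normalization across all clusters is
available by passing `by_tissue=False`. There is no gene-length division:
the data are UMI counts.

Consensus cell-type profiles are the **unweighted** mean of the
contributing cluster columns, so one very large cluster cannot dominate a
cell type that also appears in small clusters elsewhere.

## Classifier

Parameters, with defaults: detection limit 1 nTPM, fold threshold 4,
maximum group size 10. The fold threshold of 4 is the established atlas
convention; it is a parameter, not a constant. Decision order is fixed
(not detected → enriched → group enriched → enhanced → low specificity)
and all comparisons are multiplicative, so zero expression outside a
candidate group needs no special casing. Two choices were genuinely open
and are resolved as follows:

- *Ties at the maximum.* "Enriched in a single cell type" is only
  meaningful for a strict unique maximum; exact ties fall through to the
  group rule (two tied maxima far above the rest are a group of two).
- *Group search.* The smallest qualifying size wins, and the candidate
  group of size g is always the top-g prefix of the descending sort (ties
  broken by cell-type identifier). A prefix that fails cannot be rescued
  by a different member choice — swapping any member for a smaller value
  lowers the group mean and can only raise the outside maximum — so the
  prefix search is equivalent to exhaustive subset search; the suite
  verifies this by enumeration over all K = 6 vectors on a 4-value
  alphabet.
- *Group members must each be detected*: an "enriched group" containing an
  undetected member is biologically incoherent.

Tau is computed on untransformed nTPM, matching the normalized-expression
form of the original definition; a log2(x+1) variant is available via
`ClassifierParams(log_transform_tau=True)`. Tau is reported missing for
genes below the detection limit everywhere — the specificity of an
undetected gene is undefined, and such genes are excluded from tau-based
comparisons. The detection-breadth boundary between "some" and "many" is
one third of the cell types (configurable), the atlas convention.

## Bulk comparison

Bulk tissue profiles are classified by the same algorithm over tissue
columns. The polyserial correlation between tau and the ordered categories
uses the two-step estimator (thresholds from cumulative category
proportions, then ρ̂ = r·s_y/Σφ(τ̂)) rather than full maximum likelihood:
it is closed-form, deterministic and adequate for a concordance summary.
Category order is low specificity < enhanced < group enriched < enriched;
not-detected genes are excluded (tau undefined). The paired single-cell vs
bulk tau comparison uses a one-sided Wilcoxon signed-rank test with zero
differences dropped — the taus are paired, bounded and non-normal, so a
paired rank test is the natural choice.

## Deconvolution

The signature matrix restricts the consensus profile to cell-type-enriched
genes; cell types with no enriched gene are flagged unidentifiable. Per
bulk sample: the bulk vector is rescaled to the signature's per-million
scale (a scale mismatch would bias the weights); proportions start at the
normalized nonnegative least squares solution and are refined by
iteratively reweighted NNLS with weights 1/max(Ŝp, 1e-8)², capped at
d × (smallest positive weight); iteration stops when max|Δp| < 1e-6 or at
100 iterations. The dampening constant d is selected from {2⁰ … 2¹⁴} by
4-fold cross-validation over signature genes with a fixed fold seed,
minimizing held-out weighted squared error with the held-out weights
normalized to sum one (without that normalization the error scale grows
mechanically with d and the selection is meaningless). The CV scheme is
our design choice; the dampening idea itself is the published DWLS
approach of capping the dynamic range of inverse-expression weights.

Exact mixtures are recovered to machine precision (the initial NNLS is
already exact); on 20 Dirichlet mixtures with 10% multiplicative
log-normal noise and the default synthetic signature (~25 enriched genes
per cell type) the mean L1 error of the recovered proportion vectors is
about 0.04.

## Synthetic data generator

The generator emulates the data regime of a multi-organ droplet atlas:
per-gene log-normal baseline means with mild (σ = 0.05) per-type jitter,
log-normal library sizes (median ≈ 4,900 UMIs, σ = 0.35 on the log scale),
gamma-Poisson counts with dispersion 0.1, ~1% mitochondrial and ~4%
ribosomal genes, 3% doublets (expected profile = sum of two random
parents; emitted doublet score 0.9 vs 0.05 baseline — scores are planted,
not estimated, so threshold filtering is testable without a doublet
algorithm), and 2% QC outliers with mitochondrial share inflated to 45%.
Tissues are cluster replicates: tissue *r* holds the *r*-th cluster of
every cell type, so shared cell types recur across tissues. Defaults
(2,000 genes, 12 cell types, 2 clusters/type, 300 cells/cluster) keep a
full generate-to-classify run under ten seconds; these sizes are the
package's test conditions, chosen as a down-scaled but structurally
faithful version of an atlas dataset.

Planted category fractions follow atlas proportions: 15% enriched (≈25
enriched genes per cell type, matching the per-type signature density of
genome-wide atlases and hence the information available to deconvolution),
7.5% group enriched, 10% enhanced, 6% undetected, remainder
low-specificity background. Constructions:

- *enriched*: one type at F × max(others), F = 8 by default;
- *group enriched*: g ∈ [2, 4] types at F × max(non-members), non-members
  damped ×0.15 so the group contrast — and therefore tau — clearly exceeds
  that of enhanced genes;
- *enhanced*: one shadow type at 1.5 × max(baseline) keeps a runner-up
  close enough that the enriched rule cannot fire, then the target is set
  to 0.55 F × mean(others), just clear of the elevation-over-mean bar;
- *not detected*: rows scaled to an expected 0.2 nTPM everywhere;
- after planting, baseline genes are rescaled per column so all column
  totals are equal — otherwise per-million normalization would distort the
  planted ratios by the (category-mass-dependent) column-sum differences.

With these constructions, classification of the noise-free profile
recovers every planted category exactly, and the full pipeline (counts →
QC → pooling → nTPM → consensus → classification) recovers ≥ 99% of
planted enriched genes at the default noise level. The planted tau medians
order enriched > group enriched > enhanced > low specificity
(≈ 0.88/0.81/0.77/0.10 on default data); the ordering is the tested
property — the magnitudes depend on the planted contrasts, not on any real
tissue's biology.

What the generator does **not** emulate: batch effects between datasets,
ambient RNA, cell-cycle structure, realistic gene-gene correlation, or any
specific accession's gene count. Passing tests therefore demonstrate the
correctness of the algorithms under the stated noise model, not robustness
to the full messiness of real atlas data.

## Numerical conventions

- Percentages in QC are on raw counts; zero-total cells get 0% and are
  removable via `min_genes ≥ 1`.
- Spearman correlations use average ranks for ties; constant columns give
  missing correlations, which the dendrogram refuses (it lists the pairs).
- The Ward-D2 dendrogram is scipy's `linkage(method="ward")` on condensed
  1 − ρ distances (equivalent to R's `hclust(method="ward.D2")`); leaves
  are pre-sorted by identifier so equal-distance merges are deterministic.
  Newick export carries branch lengths derived from merge heights.
- Hypergeometric tail probabilities come from `scipy.stats.hypergeom.sf`,
  cross-checked against exhaustive enumeration for N ≤ 12 in the suite.
- All randomness flows through `numpy.random.default_rng` generators
  seeded explicitly; no global state. Derived stage seeds are small fixed
  offsets of the config seed.

## Known limitations

- The reliability grades, cluster labels and doublet scores are consumed
  as inputs; the package does not implement clustering, annotation or
  doublet detection.
- nTPM columns are comparable within a tissue batch by construction; no
  between-dataset batch correction is attempted.
- The DWLS cross-validation assumes enough signature genes per fold to
  keep the design full-rank; with very small signatures the grid falls
  back to its first dampening constant.
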
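# Methods

This note documents the statistical models implemented in `ithkit`, the
defaults and their rationale, what the synthetic-data generators do and
do not emulate, and the numerical choices that matter for
reproducibility.

## RNA quality control

Cells are removed when any of three rules fires: ≥ 5200 genes at
TPM ≥ 10 (a doublet/amplification signature for full-length single-cell
chemistry), < 2.2 × 10⁶ uniquely mapped reads, or a unique-mapping rate
below 20%.  Genes are retained when TPM ≥ 10 in at least one kept cell;
the boundary value 10 itself is kept (the rule is `>=`, configurable via
`QcThresholds.gene_keep_tpm`).  Filters run cells-first, then genes, and
the pair is idempotent.

Replicate variability of expression is estimated by a read-resampling
bootstrap: the cell's per-gene assigned read counts are resampled
multinomially at the observed library size, log2(TPM+1) is recomputed,
and the relative error |boot − obs|/obs is averaged over expressed genes
and replicates (default 3).  This captures the counting-noise component
of replicate variability; it deliberately excludes alignment and
quantification variability, which would require re-running an aligner.

## Corrected-CV variable-gene detection

Let x_g be a gene's log2(TPM+1) vector across cells, m_g its mean and
CV_g = sd(x_g)/m_g.  Raw CV is strongly mean-dependent, so genes are
split by mean expression into three ranges — below 4, 4 to 8.5, and
above 8.5 log2 units — and within each range two LOWESS curves are
fitted against the mean: one through the CVs (the trend) and one through
the squared residuals (square-rooted, the local scatter).  The upper
variability band is `trend + z · local_sd` with z = 1.96, and
`cCV = CV / band`.  A gene is highly variable when cCV > 1.3 (strict)
and m_g ≥ 4.

Choices worth knowing:

* LOWESS span is 2/3 with 3 robustness iterations (the classic defaults
  of the R `lowess` family); both are configurable in `HvgParams`.  The
  robustness iterations matter — they stop strongly inflated genes from
  dragging the trend upward.
* Ranges are fitted independently (no stitching at the breaks); a gene
  exactly at a break belongs to the higher range.  A non-empty range
  with fewer than 5 genes raises an error (no meaningful smooth); an
  empty range is simply skipped, since no gene needs a band there.
* Genes with zero mean get NA statistics and can never be HVGs.
* cCV is exactly invariant to multiplying all CVs by a constant: LOWESS
  is linear in the response and the bisquare robustness weights are
  scale-equivariant, so trend and band scale together (this is asserted
  in the test-suite, not just assumed).

## Diversity indices

**RNA.**  Cells are embedded by PCA of log2(TPM+1), centred but *not*
variance-scaled (scaling would equalise exactly the variance differences
the analysis is about).  The diversity index of a cell group is the
median per-cell Euclidean distance from the group centroid using all
components; medians are robust to the stray outlier cells that survive
QC.  Group comparisons use the two-sided Wilcoxon rank-sum test — exact
when both groups have ≤ 25 cells and no ties, the tie-corrected normal
approximation otherwise.

**DNA.**  From the 0/1/NA genotype matrix (construction below),
p-distance between two cells is the fraction of differing sites among
sites observed (non-NA) in both — pairwise deletion, as in molecular
phylogenetics.  Classical MDS double-centres the squared distances,
eigendecomposes, and scales eigenvectors by √max(λ, 0); p-distance
matrices are generally not exactly Euclidean, so small negative
eigenvalues are expected and clipped.  The diversity index is the mean
distance from the group centroid over the first
min(6, #positive-eigenvalue) dimensions; 6 reflects the eigenvalue drop
observed in data of this type and is a parameter (`mds_dims`).

**Bootstrap inference (DNA).**  Cells are resampled with replacement
within each group; each replicate re-runs p-distance → MDS → index.  The
index is rotation- and translation-invariant, so replicate embeddings
need no Procrustes alignment.  Reported are the 2.5/97.5 percentile CI
and SD per group, and pairwise two-sided p-values
`2 · min(P(Δ ≤ 0), P(Δ ≥ 0))` on the replicate index differences.  A
replicate containing a cell pair with no co-observed site is redrawn and
counted.  The default replicate count is 10 000; the test-suite and the
acceptance script use 1000, which is where the percentile endpoints
stabilise for matrices of this size.  Calibration: over 200 simulated
datasets (25 cells, 150 sites, 30% ADO), the 95% CI covers the
large-sample index — estimated by averaging five independent 300-cell
datasets, so that reference noise (~0.002) is negligible against the CI
scale — in ~96% of datasets.

## Single-cell SNV calling and the genotype matrix

At each bulk-defined site, every non-reference base is scored by the
Yates-corrected χ² of (cell variant vs reference counts) against the
matched background sample; the maximal base is the candidate
(alphabetical order breaks exact ties, for determinism).  The candidate
is retained when variant reads ≥ 2 and VAF ≥ 2% (high-quality depth in
the denominator), then intersected with the bulk call set *allele-aware*
(chrom, pos, alt).  Coordinates are 1-based fully closed throughout.

The bulk site list itself is an input; the provided
`simple_bulk_site_filter` (two-sided Fisher exact of fore-vs-background
allele counts, plus a one-sided binomial test of AF > 1%) is a
deliberately small stand-in for a production bulk caller and is labelled
as such — its Fisher α is a required argument, not a claimed default.

Genotype-matrix entries at polymorphic sites (bulk VAF within
[0.10, 0.35] at ≥ 1 time point, called in ≥ 1 cell): 1 when called, 0
when not called at depth ≥ 30 (a confident reference call), NA when not
called below depth 30 (undetermined).  Cells/sites whose NA fraction
falls outside `na_frac_bounds` (default (0, 0.8)) are removed
iteratively; the exact bounds used by any given study are rarely
recoverable, so they are parameters with a conservative default that
removes only uninformative rows/columns.

**ADO.**  The per-cell ADO rate is the fraction of bulk-heterozygous
sites (bulk VAF 0.45–0.55) at which the cell looks homozygous.  Both
homozygous states count: no call at depth ≥ 30 (reference-homozygous)
*or* a call with VAF ≥ 0.9 (variant-homozygous — the reference allele
dropped).  Counting only missing calls would halve the estimate, since
dropout removes either allele with equal probability.  Cells with
ADO > 0.80 are flagged as outliers.  On simulations the estimator
recovers configured rates of 0.1/0.3/0.5 within ±0.01.

## Copy-number and coverage summaries

ACN treats the genome as diploid outside the called segments and
length-weights the segment log-ratios inside (formula in the README).
Segment overlap is an error, not a silent merge — the length weighting
assumes a partition.  The genome-length constants (50 Gb mouse, 40 Gb
human) are deliberately round, conservative conventions and are
configurable.  The Gini coefficient uses the trapezoid rule over the
sorted cumulative-share curve, which is algebraically identical to the
mean-absolute-difference form Σ|xᵢ−xⱼ|/(2n²x̄); round-off can produce
−1e-16 on perfectly uniform input, so the value is clipped at 0.

## Cohort matching

The matcher normalises a sample's 1 − Pearson-r distance to a group
centroid by the group's own cell-to-centroid MADN spread, making
distances comparable between tight and loose groups.  Centroids are
per-gene *medians*; the log scale is log2(TPM+1) on the single-cell side
and log2(normalised count + 1) on the cohort side — cross-platform
normalisation and ortholog mapping are the caller's responsibility (a
two-column mapping table suffices; no mapping logic is embedded).
Assignment requires d₁ < 4.05 and d₂ − d₁ > 0.31 (strict inequalities;
exact ties are left unassigned).  These thresholds are empirical
operating points, not derived quantities; they are exposed in
`AssignmentParams`.  The HVG set used for the correlations is the pooled
set over all time points.

Downstream, Fisher's exact test (two-sided, hypergeometric) tests
group–phenotype association after collapsing groups into
"groups of interest vs rest"; the Kruskal–Wallis filter (χ²
approximation with tie correction) selects variables at a caller-chosen
α; and classification delegates to a standard random forest
(10 000 trees, 5 candidate variables per split, majority vote).  The
tree count follows the convention for stable variable importances; tests
use a few hundred trees, which is ample for the separable cases they
check.

## Synthetic data: what it emulates, and what it does not

**DNA generator.**  A small set of clones with fixed (all-clone) and
polymorphic (proper-subset) heterozygous SNVs; cells drawn from clone
fractions; per-site depth ~ negative binomial with mean 50 and
overdispersion α = 0.5 (variance m + αm²), reproducing the uneven
amplification coverage that high Gini coefficients summarise (α = 0
gives Poisson depths for noise-free checks); ADO firing independently
per cell × site with the dropped allele uniform (default rate 0.45,
matching typical multiple-displacement-amplification data); sequencing
errors substituting reads uniformly among the three other bases (default
10⁻³ post-quality-filter).  The bulk pileup is the deterministic
infinite-population limit — expected base fractions times a large depth
— so bulk VAFs equal the clone-fraction arithmetic exactly, which the
noise-free truth-recovery tests rely on.  Not emulated: read-level
artefacts, alignment error, doublets, chimeric MDA products, or
correlated dropout along amplicons; conclusions about those failure
modes cannot be drawn from these simulations.

**RNA generator.**  Log2-scale group mean profiles (uniform on [1, 11]
with ±2 log2 marker shifts for groups beyond the first), Gaussian noise
of SD 0.5 with a ×3 SD inflation on a designated overdispersed gene set
(the truth HVGs, placed at means in [5, 9]), expression-dependent
dropout, and column renormalisation to a fixed TPM total (set so the
renormalisation is mean-preserving).  Dropout follows a logistic decay
in realised log2 expression — probability `rate / (1 + e^{(x−3)/0.5})`,
default rate 0.3 — because in full-length single-cell chemistry dropout
is concentrated below ~10 TPM and detection saturates above it; a
uniform dropout would contaminate the CV of strongly expressed genes and
misrepresent the data the detector is meant for.  Not emulated:
count-level (negative binomial) noise, gene–gene correlation beyond the
group structure, cell-cycle or batch covariates, or coupling between
copy number and expression.  Passing tests therefore demonstrate
correctness of the *statistics*, not robustness to every artefact of
real data.

**Cohort generator.**  Samples are group centroids plus i.i.d. Gaussian
noise on the log scale with a per-group binary phenotype probability —
the minimal structure needed to exercise assignment and association;
real bulk cohorts add platform effects the matcher's MADN normalisation
only partly absorbs.

## Determinism and numerical notes

All stochastic routines take an explicit seed (`numpy.random.default_rng`)
and never touch global state; equal seeds give byte-identical outputs.
Vectorised multinomial sampling uses the conditional-binomial
decomposition.  MDS eigenvalues below 1e-12 are treated as zero when
counting positive dimensions.  Exact-tie handling is deterministic
everywhere (alphabetical alt bases, higher range at CV breaks,
unassigned on tied cohort distances).

## Known limitations

* The bulk SNV stand-in is far simpler than production callers; with
  real data, supply an externally generated bulk site list.
* ADO estimation assumes bulk-heterozygous sites are diploid-balanced;
  copy-number alterations at those sites bias the estimate.
* The bootstrap resamples cells only; site-level uncertainty is not
  propagated (site resampling would break the fixed site universe the
  index is defined on).
* Problem sizes in the tests and acceptance script (hundreds of genes,
  tens of cells, ~150 sites, 1000 bootstrap replicates) are chosen so
  the full suite runs in minutes; all are parameters, and the defaults
  for scientific use (e.g. 10 000 replicates) are larger.
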
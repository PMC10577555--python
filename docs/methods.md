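# Methods

`lungage` implements a pseudobulk aging analysis for single-cell lung
transcriptomes: per-cell-type differential expression between young and
aged donors, consensus "LungAge" gene signatures, control-subtracted
module scores (including senescence scores), and a random-forest age-state
classifier — together with a synthetic count generator that plants known
effects so every stage can be validated against ground truth.

## Statistical model

### Pseudobulk differential expression

Raw counts are summed within each (sample, cell type) stratum, making
donors the units of replication and sidestepping the pseudo-replication of
cell-level tests. For cell type *t* and gene *g*, the pseudobulk count of
sample *s* is modeled as negative binomial with

    log mu_gs = log(sf_s) + beta_0 + beta_batch(s) + beta_age * 1[s aged]
    Var(y)    = mu + alpha_g * mu^2

where `sf_s` are median-of-ratios size factors (total-count fallback when
no gene has all-positive counts). The age effect is tested by a
likelihood-ratio test against the batch-only reduction, with the statistic
referred to chi-square(1); `log2FC = beta_age / ln 2` is reported unshrunk.
Batch enters as a model covariate rather than as a separate correction
pass: this preserves the count nature of the data and lets the synthetic
generator's batch shifts validate the adjustment directly. GLM fits use
statsmodels' IRLS with a fixed per-gene dispersion; separation or
non-convergence falls back to a ridge-penalized fit (penalty 1e-6) and the
gene is flagged.

Cells from MIDDLE-aged donors are excluded before aggregation; cell types
with fewer than 500 cells, or without at least 2 samples per age group, are
not tested. Genes with pseudobulk total below 10 are not tested and do not
count toward multiplicity.

### Dispersion estimation

The per-gene dispersion `alpha_g` is estimated in two parts:

1. **Cell-level bound.** Within each sample, cells share the gene mean up
   to a library-size factor, so the NB dispersion at cell level is
   estimable from per-sample cell moments with thousands of degrees of
   freedom. A sum of n cells with cell size factors `sf_c` then has
   `Var = M + alpha_cell * (sum sf_c^2 / (sum sf_c)^2) * M^2`, giving a
   per-gene dispersion the pseudobulk cannot fall below. This bound is
   computed during aggregation and carried on the pseudobulk matrix.
2. **Donor-level method of moments.** `(s^2 - m)/m^2` on size-factor-
   normalized pseudobulk values, with moments taken within each
   age-by-batch design cell and pooled with df weights (so a real age
   effect does not inflate its own gene's dispersion). This captures
   biological donor-to-donor variance beyond cell sampling.

The working dispersion shrinks the noisy donor-level estimate toward the
cell-level value (weight 0.3) and floors at it. With roughly 8 residual df
the raw moment estimator is noisy enough that, used alone, it inflates the
chi-square tail severalfold; the cell-level bound removes exactly that
failure mode. When cell-level information is unavailable (a pseudobulk
matrix constructed directly), the estimator shrinks toward the median
dispersion instead — and only upward, because pulling genuinely
high-dispersion genes toward the center understates their variance. The
global floor is 0.001, the order of magnitude implied by hundreds of cells
per pseudobulk sample; `alpha` of an all-zero gene is the floor, flagged.

### Multiple testing

"FDR" is Benjamini–Hochberg, applied within each cell type (each cell type
is its own family), with significance at FDR < 0.1 and direction from the
sign of the fold change. `call_degs` additionally performs independent
filtering on mean expression — scanning lower-quantile cutoffs and keeping
the one that maximizes discoveries, the default behavior of standard
count-model packages; the mean is independent of the statistic under the
null, so the procedure preserves FDR control. Under a global null the
scan keeps the no-filter solution.

### Consensus signatures

A gene joins the up (down) signature when called up (down) in at least
`min_celltypes` (default 2) tested cell types. Genes significant in both
directions anywhere are directionally ambiguous and are excluded from both
lists at every threshold — this keeps the signature monotone in
`min_celltypes` (evaluating conflicts per threshold would not). Gene order
is descending cell-type support, then lexicographic. Upset-style exact
intersection sets (full membership patterns, their sizes, and per-pattern
cell-type counts) are emitted for reporting.

### Module scores

The score of a gene set in a cell is the mean log-CP10K expression of the
set genes minus the mean of a pooled control panel: genes are ranked by
dataset-mean expression, cut into `n_bins` (24) equal-frequency bins, and
each set gene draws `n_ctrl_per_gene` (100) controls with replacement from
its own bin, with all set genes excluded from the pool (self-subtraction
would bias scores toward zero). Matching controls on expression centers
random sets at zero and absorbs depth effects, which is why log-CP10K
suffices here and no variance-stabilizing regression layer is kept; the
DEG test never sees normalized values at all. Ties in the mean-expression
ranking break by stable gene order, and a degenerate bin fully occupied by
set genes widens its pool to all non-set genes with a warning. Scores are
deterministic given the seed.

Group comparisons use the two-sided Wilcoxon rank-sum test: exact
enumeration when both groups have at most 10 observations and no ties,
otherwise the normal approximation with tie and continuity corrections.
Cells are the test units by default, matching how such scores are usually
compared; because cells of one donor are correlated, a per-sample mode
(`per_sample=True`) first averages scores within donors and tests donors.

### Age-state classifier

Features are the log-normalized expression of the signature genes (all,
up-only, or down-only); the label is the donor age group; cells are the
classification units. Cells are split 90:10 within (sample, cell type,
age group) strata — cell types with 200 or fewer cells are removed first,
singleton strata go to train — and a random forest (500 trees, sqrt-p
features per split, Gini impurity, no depth limit) is trained with
three-times-repeated stratified 10-fold cross-validation. AUROC is
computed from the midrank statistic (ties count 1/2); accuracy uses a 0.5
vote threshold; variable importance is mean decrease in impurity with
lexicographic tie-breaks, annotated with the cell types where each gene
was a DEG. Cell-level splits put cells of one donor on both sides, so a
`leave_samples_out_split` mode is provided for donor-level
generalization; training never pools multiple batch labels through the
CLI.

## Synthetic data generator

`generate_dataset` emulates the structure the analysis assumes: donors in
two age groups across batches, cell types with unequal abundances
(Poisson cell counts around configured means), NB counts with per-gene
dispersion `alpha_g ~ Gamma(shape, scale)` with mean 0.5, log-normal cell
size factors, per-gene-by-batch log2 mean shifts, planted up/down age
effects assigned to `k ~ sharing_profile` cell types each, a senescence
gene set elevated in aged cells of target cell types, and Beta-distributed
mitochondrial fractions independent of counts. One seed feeds named
substreams per stage, so outputs are reproducible and stage-stable.

Preset study conditions:

- **default fixture** — 12 donors (6 young / 6 aged, 2 batches), 5 cell
  types at 40:25:15:12:8 relative abundance (~500 cells/donor), 3,000
  genes with per-cell means in [0.1, 3], 60 up + 30 down planted at
  log2FC 1.0 with sharing profile {1: 0.5, 2: 0.3, 3: 0.2} (about half of
  planted genes affect 2 or more cell types), and a 15-gene senescence set
  (+1 log2FC) in aged monocytes and AT2 cells. The rarest cell type
  (~480 cells) deliberately falls under the 500-cell exclusion rule, so
  the exclusion path is exercised on every run.
- **null fixture** — same cohort shape, 3 cell types, 2,000 genes, nothing
  planted; used for calibration checks.
- **strong-effect fixture** — 8 donors, 3 cell types, 1,500 genes, 60
  planted genes at log2FC 2.0 shared across most cell types; age state is
  nearly separable per cell, which is what a positive-control classifier
  check requires.

What the generator does **not** model: doublets, empty droplets, ambient
RNA, UMI saturation, donor-level biological variance beyond batch shifts,
mitochondrial genes as actual features, or continuous age. Passing tests
therefore demonstrate correctness of the machinery under the assumed
model — calibration, recovery, and reproducibility — not performance on
real tissue, where donor heterogeneity typically dominates and AUROCs of
1.0 should not be expected.

## Numerical choices and edge cases

- QC boundaries are strict: kept cells need more than 200 detected
  features and mitochondrial fraction strictly below 0.35.
- Log-normalization: `ln(1 + count / cell_total * 1e4)`; a zero-total cell
  is an error naming the cell.
- Size factors are scaled to geometric mean 1; LRT statistics are clipped
  at 0; a constant age column raises "contrast not estimable".
- BH passes NA p-values through untouched; they never count toward m.
- Stage seeds derive as `(global_seed * 1000003 + crc32(stage)) mod 2^31-1`.
- MTX files are 1-based on disk, 0-based in memory; duplicate feature IDs
  are suffixed `.1`, `.2`, ...; gene matching is exact and case-sensitive
  (an opt-in upper-casing helper exists).

## Validation problem sizes

The bundled checks run the null fixture (~6,000 cells x 2,000 genes), the
default fixture (~6,000 cells x 3,000 genes) and the strong-effect fixture
(~2,600 cells x 1,500 genes); these sizes keep a full validation run in a
few minutes on one core while leaving every stage's statistical behavior
measurable (per-cell-type recall, empirical FDR, null tail calibration,
AUROC under signal and under permutation).

## Known limitations

- The dispersion model assumes cells within a sample share a gene's mean
  up to depth; real cell populations have within-type heterogeneity that
  would push the cell-level bound upward.
- Cell-level Wilcoxon comparisons are pseudo-replicated by design
  (fidelity to the usual presentation); use the per-sample mode for
  donor-level inference.
- The classifier's cell-level split leaks donor identity between train
  and test; the leave-samples-out mode is the defensible alternative.
- Senescence gene lists are user-supplied via GMT; none ship with the
  package.
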
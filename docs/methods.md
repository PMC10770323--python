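# Methods

`pe_immunodx` implements a cell-type-specific diagnostic pipeline for
preeclampsia (PE) from annotated single-cell PBMC expression data, together
with a synthetic-data generator that reproduces the statistical structure
the pipeline assumes. This note documents the models, the tunable
parameters, the numerical conventions, and the design choices made where
the procedure left genuine freedom.

## The diagnostic pipeline

### Quality control

Cells are kept when the number of detected genes lies in the inclusive
range [200, 6000], the mitochondrial count fraction is below 10%, and the
fraction of counts in ten hemoglobin genes (HBA1, HBA2, HBB, HBD, HBE1,
HBG1, HBG2, HBM, HBQ1, HBZ) is below 1%. Dropped cells are attributed to
the first rule they violate (gene range, then mito, then hemoglobin), so
per-rule counts in the QC report sum to the total dropped. Genes are kept
when expressed (count > 0) in **more than** 3 cells; ribosomal,
mitochondrial, pseudogene and lincRNA genes are removed outright.
Mitochondrial genes are identified by the `category` annotation when
present and by the "MT-" name prefix otherwise. Cells are filtered before
genes, matching the conventional order.

### Normalization and feature space

Counts are depth-normalized to 10,000 per cell and log1p-transformed:
`x = log(1 + 10000 * c / total_c)`. Highly variable genes are ranked by the
community-default binned-dispersion recipe for log-normalized data: de-log,
per-gene mean and dispersion (variance/mean, unbiased variance), log
dispersion z-scored within 20 equal-width bins of log1p mean (a gene alone
in its bin receives z = 1), top 2,000 kept. Ties break by gene name so the
ranking is deterministic. The recipe is verified in the test suite against
scanpy's `highly_variable_genes(flavor="seurat")` on shared input.

### Pseudo-cells

Classification operates on *pseudo-cells*: within one annotated cell type
(or a named union such as "total monocytes"), each patient's cells are
shuffled (seeded) and partitioned into disjoint blocks of k = 5; the
pseudo-cell feature vector is the arithmetic mean of the block's
log-normalized HVG expression, and its binary label is the patient's group
(PE = positive). Remainder cells (n mod k) are discarded: a partial block
would change the averaging variance, and "every 5 cells" admits no partial
pseudo-cell. Patients with fewer than k cells contribute nothing (logged).
Full provenance (member barcodes per pseudo-cell) is retained, and tests
recompute every feature vector from provenance to 1e-12.

### Splitting and standardization

Pseudo-cells are split 7:3 stratified by label (per class, round half up;
seeded shuffle). Per-gene mean and population SD (ddof 0) are fitted on the
training set only and applied unchanged to the test set; zero-variance
genes map to exactly 0. The unit of stratification is the pseudo-cell, so
one patient's pseudo-cells may span both sets; `group_by_patient=True`
provides a leakage-free patient-level split as a non-default alternative
for quantifying that effect.

### Dual feature selection

A gene enters the model only if selected by **both**:

- **Mutual-information filter.** Each gene is scored by the Ross
  nearest-neighbor estimator of I(gene; label) for a continuous variable
  against a discrete one (k = 3 neighbors, negative estimates clipped to
  0). The implementation is an exact, fast re-derivation for 1-D features
  (sorted arrays instead of KD-trees) and is tested to ~1e-15 agreement
  with `sklearn.feature_selection.mutual_info_classif` per column.
  Tie-break jitter is seeded from a hash of the column content, so
  duplicated columns receive identical estimates. Because the estimator's
  sampling noise under independence is symmetric around zero, a bare
  "estimate > 0" rule would retain roughly half of all label-independent
  genes (measured: 47/100 null simulations); the default selection rule
  therefore requires the estimate to exceed the maximum over 9 seeded
  label-permutation re-estimates — a permutation-shadow threshold with
  effective level 1/(9+1) = 0.1. The permissive rule remains available via
  `threshold_mode="positive"`.
- **Boruta.** Implemented in full: each iteration appends one
  independently permuted shadow copy of every undecided feature, fits a
  class-weighted random forest (default 100 trees, depth 5,
  impurity importance; permutation importance by flag), and records a hit
  for features whose importance exceeds the maximum shadow importance.
  After each iteration a two-sided binomial test (p = 0.5) with Bonferroni
  correction over the currently undecided features confirms features with
  significantly more hits than expected and rejects those with
  significantly fewer. After `max_iter` = 100 iterations, remaining
  tentative features are resolved by comparing their median importance to
  the median of the per-iteration shadow maxima. Constant features are
  rejected up front. Truncating the run (e.g. max_iter = 30) leaves more
  features to the median resolution and measurably raises the null
  confirmation rate, which is why the default iteration count should be
  kept for calibrated behavior.

The intersection is taken in stable gene order; an empty intersection is a
hard error advising relaxed parameters, since the model would otherwise
have no features.

### Classifier, cutoff, evaluation

The classifier is a random forest with inverse-class-frequency weights
(PE pseudo-cells are the minority). Hyperparameters are tuned by random
search — 100 draws by default — over trees ∈ [100, 1000], depth ∈
{unbounded, 3..20}, features-per-split ∈ {√p, log2 p, 0.1..1.0},
min-samples-leaf ∈ [1, 10], min-samples-split ∈ [2, 20]; each draw is
scored by mean AUROC over stratified 5-fold CV and the winner is refit on
the full training set. A `cv_repeats` option supports averaging several
5-fold replicates per draw (default 1).

The decision threshold maximizes Youden's J = sensitivity + specificity − 1
over every unique predicted score, with "score ≥ t ⇒ predict PE" and ties
resolved to the smallest threshold. J is computed on the winning draw's
pooled out-of-fold training predictions rather than on refit-on-train
scores, which would be optimistically separated. AUROC uses the
Mann–Whitney rank statistic with midranks for ties. The metric battery
(sensitivity, specificity, PPV, NPV, class-size-weighted F1, confusion
matrix) reports undefined ratios (zero denominators) as NaN with a flag.
Test-set stability is assessed by B = 100 bootstrap resamples of test-set
size with replacement, each scored at the *fixed* training-phase cutoff;
resamples missing a class are redrawn so B stays fixed. Reports carry both
raw floats and "mean ± SD" strings.

### Shapley gene ranking

Global gene importance is the mean absolute Shapley attribution across
samples, computed by the polynomial-time path-dependent tree-Shapley
algorithm (absent features follow the tree's own training split fractions).
The implementation is numba-jitted and validated against a brute-force
exact-Shapley oracle (subset enumeration over the path-dependent value
function) on small trees; per-sample additivity — attributions plus base
value equal the predicted PE probability — is asserted to 1e-6 on every
call. Rankings are computed on both the independent test set (reported as
primary) and the training set (reported alongside), since either convention
is defensible; ties break by gene name.

### Differential expression

Per gene, a two-sided Wilcoxon rank-sum test on log-normalized values
between PE and NP cells of a subset: exact enumeration when both groups
have ≤ 25 cells (a dynamic program over doubled midranks, so ties are
handled exactly; two-sided p sums all rank-sum outcomes at least as far
from the mean as observed), normal approximation with tie correction
otherwise. Fold change follows the convention for log-normalized data:
`avg_log2fc = log2((mean(expm1 x | PE) + 1) / (mean(expm1 x | NP) + 1))`.
Significance requires Bonferroni-adjusted p < 0.05 AND |avg_log2fc| > 0.15,
both strict. All QC-passing genes in the subset are tested (no
minimum-fraction prefilter).

### Clinical cohort statistics

Controls are matched 1:2 to cases by greedy nearest neighbor on the logit
of an unpenalized logistic propensity score, cases in seeded random order,
controls without replacement; no caliper by default (optional parameter);
standardized mean differences are reported before and after matching.
Continuous variables: each group is tested against Normal(sample mean,
sample SD) by one-sample Kolmogorov–Smirnov at α = 0.05 (estimated
parameters — anti-conservative, acknowledged); if both pass, a
pooled-variance two-sided t-test with mean (SD) summaries, otherwise a
two-sided Mann–Whitney U with median (IQR) summaries. 2×2 tables: Fisher's
exact test when any expected count is below 5, Yates-corrected chi-square
otherwise. The two-sided Fisher p-value follows the probability-based
convention — the sum of hypergeometric probabilities of all tables (fixed
margins) no more likely than observed, with the standard 1 + 1e-7
tolerance — evaluated in exact integer arithmetic and tested against full
enumeration for every table with N ≤ 40.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: 23 subjects
(8 PE, 15 NP), per-patient counts, annotated cell types, and a clinical
covariate table whose group means/SDs and event rates mirror a
third-trimester PE/NP comparison (higher BMI, blood pressure and cesarean
rate in PE; lower gestational age at delivery and fetal weight).

Counts for gene g in cell j of patient p are negative binomial with

    mean = baseline_g · libsize_j · patient_p · 2^(effect_g · 1[PE, matching cell type])
    size = nb_dispersion (default 2.0)

where `baseline_g` is log-normal (default log-mean −1.0, log-SD 1.3,
giving ~1,700 counts and ~700 detected genes per cell on a 2,000-gene
panel), `libsize_j` is log-normal (σ = 0.3), and `patient_p` is a scalar
log-normal patient effect (σ = 0.15). Mitochondrial and hemoglobin gene
baselines are rescaled to ~4% and ~0.05% of total expression, far from the
QC thresholds, so only injected violators fail QC. Planted differential
genes have their baselines floored at the panel-median baseline
(`de_min_baseline_quantile = 0.5`): the markers being emulated are
well-expressed genes, and an effect planted on a ~0.05-counts-per-cell gene
is undetectable by any method at this depth.

A configurable fraction of cells (default 5%) is perturbed post hoc to
violate exactly one QC rule — mitochondrial fraction raised to 15–35%,
hemoglobin fraction to 3–8%, or detected genes reduced below 200 — cycling
through the three rules. The generator emits a truth record (violator
barcodes and rules, planted genes, per-patient cell counts) that is
consumed only by tests, never by the pipeline.

What the generator does **not** model: ambient RNA, doublets, batch
effects, UMI chemistry, gene–gene correlation beyond the shared patient and
library-size factors, and per-gene patient effects. The scalar patient
effect is deliberately removed by depth normalization, so passing the null
(permuted-label) calibration here does not rule out patient-memorization
leakage on real data with gene-specific patient effects — that risk is
what the `group_by_patient` split option exists to quantify.

## Calibration and problem sizes

The test suite exercises the pipeline at sizes chosen to keep the full run
in the tens of minutes on one CPU while preserving the study's structure:

- **Strong-signal end-to-end run**: the full 23-subject study, 300 cells
  per subject, 2,000 genes, 50 planted genes at log2 effect 1.0, 10 random
  search draws. Expected behavior: test AUROC ≥ 0.90, bootstrap mean
  consistent with the point estimate.
- **Null (permuted-label) runs**: group labels are permuted across
  patients; because feature selection correctly returns (near-)empty sets
  under the null, these runs use a label-independent feature set (the top
  50 HVGs) and a tree range capped at [100, 300], with the same pseudo-cell
  construction, 10 draws and 5-fold CV. Expected: best CV AUROC in
  [0.40, 0.70] and test AUROC in [0.35, 0.65] across 5 seeds.
- **Marker recovery**: 20 planted genes at log2 effect 1.5; at least half
  of the top-20 Shapley-ranked genes are planted markers.
- **Boruta calibration**: 80 samples, 50 noise features, 100 runs; a
  label-copy feature must be confirmed in ≥ 95 runs, and ≤ 5% of pure-noise
  features may be confirmed (Boruta at default max_iter = 100, α = 0.05,
  with a 25-tree depth-5 forest inside).
- **MI null calibration**: an independent feature is selected in < 20% of
  100 null simulations at n = 200.

The acceptance script (`scripts/acceptance.py`) reruns the strong-signal
study, the marker-recovery study, the differential-expression power
simulation (30 planted effects at log2 1.0, 200 cells per patient, 630
genes) and the clinical 2×2 statistics from a single seed.

## Known limitations

- The MI permutation-shadow threshold costs 10 MI passes over the feature
  matrix; for very large panels use `threshold_mode="positive"` and rely on
  Boruta for stringency.
- Boruta's repeated binomial testing over iterations is mildly
  anti-conservative (measured ~4.7% null confirmations at α = 0.05); this
  matches the original algorithm's behavior.
- The KS normality gate uses estimated parameters and is anti-conservative
  for small clinical tables; with n ≈ 8–15 per group it rarely rejects, so
  most continuous variables route to the t-test.
- Pseudo-cell-level stratification reproduces the target design but allows
  a patient's pseudo-cells to span train and test; patient-level splitting
  is available and reported when used.
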
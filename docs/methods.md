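# Methods

`cfmodal` implements a multimodal analysis of plasma cell-free DNA (cfDNA)
methylation sequencing: window-level methylomes, unsupervised structure and
feature enrichment, differential-methylation classification, tissue-of-origin
deconvolution, fragment-length profiling, binned copy-number calling, and a
three-class integration of the modalities. Because real plasma cohorts of
this kind are not freely redistributable, the package ships a first-class
synthetic-data generator that reproduces the statistical structure every
stage assumes, with known ground truth, so the full pipeline is testable
offline.

## Window methylome

Input is one bedGraph-style call table per sample (chrom, start, end,
`n_meth`, `n_unmeth`; 0-based half-open, one row per CpG). `n_meth` counts
converted read bases: in the TAPS chemistry 5mC/5hmC read as T, so a
converted base at a CpG is evidence of methylation; the polarity is resolved
upstream by the methylation caller.

Sites overlapping exclusion masks (common SNPs, blacklisted regions,
centromeres) and sites on sex chromosomes are removed first; overlap is
any-bp against merged mask intervals, half-open throughout. Windows tile
each chromosome from position 0 at a fixed width (1 kb for regulatory-scale
analyses, 1 Mb for coarse profiles). The window level is the pooled ratio
Σ n_meth / Σ (n_meth + n_unmeth) over the CpGs in the window — not a mean of
per-CpG ratios — and a window with zero covered CpGs in a sample is missing
for that sample, never imputed. Windows whose mean CpG coverage (total calls
divided by the number of distinct CpG positions observed in the window
across the cohort) falls below 2 are dropped. The coverage filter is
cohort-wide rather than per-sample so every downstream analysis sees one
common window universe; the per-sample alternative would give each sample a
different feature set, which leave-one-out classification cannot use.

Spike-in QC: the conversion rate is the converted fraction at
CpG-methylated control molecules (e.g. CpG-methylated lambda DNA), the
false-positive rate the converted fraction at unmodified control cytosines.
Samples are excluded when conversion falls below a threshold; the default is
0.90, configurable (values of 0.85–0.90 are in common use), and a sample
exactly at the threshold is kept.

## Unsupervised structure

PCA operates on windows with complete data, centered and (by default)
unit-scaled; scaling is exposed as a flag because practice varies. Component
signs are fixed by making each component's largest-magnitude loading
positive, which makes scores reproducible across runs. Windows most
associated with a component are ranked by the Pearson correlation between
their levels and the component scores; the correlation-test p-value uses the
t transform of r (df = n − 2), windows are kept at p < 0.01 and the top 200
by |r| reported — the dimdesc-style contributor list. Constant windows have
undefined correlation and are silently excluded.

Feature enrichment uses a window-level 2×2 contingency: the query windows
versus the rest of the background, split by ≥1-bp overlap with the feature
BED. Because windows are fixed-width and disjoint the window-count table is
well-defined and exactly checkable, unlike bp-level interval statistics. The
two-sided exact p is the sum of hypergeometric probabilities not exceeding
the observed table's probability (computed with vectorized log-gamma terms;
a brute-force enumeration oracle and scipy's `fisher_exact` cross-check it
in the tests). The sample odds ratio (a·d)/(b·c) is reported as `inf`/0 when
a cell zeroes the denominator or numerator.

## Two-class DMR classification

The central discipline is that differentially methylated region (DMR)
selection runs **inside** each leave-one-out (LOO) fold, on training samples
only. Within a fold, candidate windows (those overlapping the designated
regulatory class — enhancers for the liver-cancer contrast, promoters for
the pancreatic contrast) are tested with a two-sample t test; windows with
p < 0.002 **and** |mean difference| > 0.05 are the fold's DMRs. The t test
is Welch by default (the equal-variance flavour is an option); with two
thresholds of this kind the binding constraint depends on the cohort's
noise level, which is why the synthetic cohorts are calibrated to realistic
between-patient variability (below).

The fold model is an L1-regularized logistic regression (features
standardized; penalty chosen by internal stratified cross-validation over a
log-spaced grid, folds capped at min(10, smallest class size), seeded) — a
cv.glmnet-style fit with a lasso-leaning mixing default of 1.0, both
configurable. A fold that selects zero DMRs is scored by the training-set
class prior and logged as degenerate rather than aborting the run. External
samples are scored by one model refit on all primary samples over the union
of per-fold DMRs; model features missing from the external matrix are
imputed with training means, and scoring refuses if fewer than half the
features are present at all.

AUC is computed from midranks (Mann–Whitney probability with ties counted
half); the test suite checks it exactly against O(n²) pair enumeration. DMR
stability between a full-depth reference run and a down-sampled run is
|intersection| / |reference|.

The test suite also contains a deliberately leaky variant that selects the
top-20 windows by full-cohort t-test p **before** LOO. It exists only to
demonstrate that the fold structure matters: on label-free null cohorts the
honest path stays near chance while the leaky path inflates the AUC well
above 0.8. Rank-based top-k selection is used for the leaky control because
threshold-based selection on null data passes so few windows that the
leaked signal would be erratic across seeds; top-k is the standard way to
exhibit selection leakage.

## Tissue-of-origin deconvolution

Tissue reference construction aggregates per-CpG calls over enhancer regions
(pooled ratio per region; regions with fewer covered CpGs than a minimum are
missing) and then selects tissue-specific regions one-versus-all: per
tissue, regions are ranked by |median(tissue) − median(other tissues)|,
filtered for replicate consistency (within-tissue max − min ≤ 0.25), floored
at a minimum difference of 0.1, and the top k in each direction kept
(k = 100 by default, the scale used by published whole-genome deconvolution
atlases; the consistency threshold and k are both configurable because no
canonical values exist). The same top-k selection is additionally run
against each tissue's two most Pearson-correlated neighbours, which
sharpens separation between related tissues. The minimum-difference floor
is what makes the degenerate case sane: two identical tissue groups are each
other's closest neighbour, all their pairwise differences are ~0, and the
floor drops everything rather than returning noise ranks.

The reference matrix A is the per-tissue median over replicates restricted
to the selected regions. Per-sample contributions solve
min‖Ax − y‖₂ s.t. x ≥ 0 (scipy's NNLS); regions missing in the sample are
dropped pairwise and the count of regions used is recorded. Contributions
are reported raw and sum-normalized; group comparisons on a tissue's
contributions default to an unpaired Welch t test, the correct choice for
independent patient groups, with a paired variant available for matched
designs. A contribution-based classifier reuses the LOO
machinery with the contribution matrix as features and no selection step.

## Fragmentomics

Fragment lengths come from paired-end template lengths (absolute value,
read 1 of each proper pair, duplicates excluded) or a one-column table,
restricted to [1, 1000] bp. Profiles are 10-bp bins, half-open and aligned
to multiples of 10 (a 300-bp fragment falls in [300, 310)), with the
full-window total as the denominator for every bin so the bin vector lies on
one simplex and long-bin fractions are comparable across samples with
different short-fragment loads. Summary fractions default to short
[70, 150) and long [300, 500) — the figure-legend ranges; the running-text
variants (<150, 310–500) are reachable through the configurable ranges.
Group tests use tie-corrected Kruskal–Wallis, with the all-identical
degenerate case defined as (H = 0, p = 1). The fragment classifier feeds the
20 long-range bin fractions to the shared LOO machinery with no selection
step.

## Copy number

Reads (or fragment midpoints) are counted in 100-kb bins; bins that are
blacklisted or have mappability < 80 are dropped. Copy ratio is count
divided by the median count over retained autosomal bins — a deliberate
simplification of the GC/mappability loess chain of read-depth CNV packages,
preserving the decision rule that is actually specified: ratio < 0.8 calls a
loss, > 1.2 a gain, runs of identical non-neutral calls merge into segments
(bridging across at most one dropped bin so a low-mappability hole does not
split a segment), and a patient is CNV-positive iff some segment is
**strictly** longer than 500 kb — five 100-kb bins are not enough, six are.
The interface accepts per-bin covariates should a fuller correction chain be
added later.

## Three-class integration

For the methylation modality, the top five DMRs of each pairwise group
comparison (ranked purely by t-test p, no thresholds — so three identical
groups still yield rank-based features) are re-selected inside every LOO
fold; tissue-contribution and fragment-bin matrices are used raw. Each
fold fits a linear SVM with pairwise-coupled Platt probability calibration
(seeded); the held-out sample's three-class probability vector is recorded.
Integration averages the probability matrices across modalities and calls
the argmax; exact ties break toward the control class and then
lexicographically, a declared rule chosen for reproducibility. Evaluation
reports overall accuracy, the 3×3 confusion table, and the binary accuracy
after collapsing the two cancer classes.

## Synthetic data: what it emulates and what it does not

The generator encodes the study conditions the pipeline is validated under:

- **Atlas** (`make_atlas`): a shared per-region baseline drawn from a
  bimodal beta mixture (component means 0.08/0.92, mixture weight set so the
  global mean is 0.755, matching control plasma cfDNA; concentration 8 gives
  the heavy bimodal shape of real per-CpG methylation). Each tissue gets
  disjoint planted marker regions shifted ±effect; hypermethylated markers
  are planted in low-baseline regions and vice versa so the contrast is
  exact and the global mean undisturbed. Replicates add beta noise around
  tissue means (concentration 150 ≈ replicate sd 0.02–0.04, typical of
  WGBS tissue replicates).
- **Cohort** (`make_cohort`): window expectation is A·x for a
  blood-dominant Dirichlet mixture (first tissue carries 20× the Dirichlet
  mass of the others — plasma cfDNA is dominated by blood and immune cells;
  between-patient variability is exposed as the Dirichlet concentration
  because no quantitative model of it exists to copy). The synthetic genome
  maps windows to regions 1:1, with alternating windows labelled enhancer /
  promoter in generated BED files, so all interval logic is exercised
  without a real genome. Group-specific DMR shifts of ±effect are planted
  in the appropriate regulatory class. Between-patient biological noise is
  additive Gaussian with sd 0.06, clipped to [0, 1] — a noise floor that
  does not vanish at extreme methylation, matching the 0.05–0.1
  window-level variability of real plasma cohorts, and the regime in which
  the paired selection thresholds p < 0.002 / |Δβ| > 0.05 are comparably
  binding (a multiplicative beta model instead starves the thresholds at
  bimodal baselines and makes every null fold degenerate). Observed counts
  are binomial at Poisson(coverage) depth over 10 CpGs per window. A
  noise-free mode emits expectation-preserving counts at depth 1e9 for
  exact-recovery tests.
- **Fragments** (`make_fragments`): a discrete mixture over 1–1000 bp —
  narrow Gaussian at 167 bp (σ = 3), comb of Gaussians at 167 − 10k
  (k = 1..6, σ = 1.8, geometrically decaying weights), dinucleosomal
  Gaussian at 320 bp (σ = 12), a short band on [70, 150) and a broad
  background. `group_shift` moves that fraction of mass from the long
  component to the short band, reproducing the cancer-associated
  shortening; the induced change in short-fraction equals the shift to
  within ~0.005.
- **CNV / spike-in**: Poisson bin counts at depth × copy-ratio inside
  planted segments; binomial conversion counts at stated rates.

Everything is deterministic given the seed (PCG64 generators; byte-identical
outputs).

What the generator does **not** model: read-level artifacts (adapters,
alignment error, carrier-DNA contamination), GC/mappability bias,
correlated noise between neighbouring windows, realistic chromosome
structure, or the true between-patient covariance of tissue contributions.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under the stated statistical assumptions — not clinical
performance on real plasma samples, whose headline accuracies depend on a
real cohort that is not distributable here.

## Problem sizes and numerical choices

Simulation-based checks use 20-vs-20 cohorts at coverage 10 — 2500 windows
for null calibration (10 seeds) and 2000 for planted-signal recovery
(5 seeds) — 3-tissue × 300-region atlases for marker recovery, 100 seeds
for the CNV false-positive rate, and 10 seeds of 24-sample three-class
cohorts for integration; sizes chosen to keep the full validation suite
fast on one CPU while leaving the statistical conclusions stable across
seeds. Pooled leave-one-out AUC on a 40-sample null cohort is a
high-variance statistic squeezed between two finite-cohort artifacts:
with very few candidate windows most folds select nothing and the
prior-scored folds anti-correlate with the held-out label (AUC biased
toward 0), while with very many candidates the selection locks onto
chance group differences that persist cohort-wide (AUC biased toward
0.7). The null-calibration window count sits where the pooled statistic
is centred, so the check measures calibration rather than either
artifact.
Tolerances: exact recovery thresholds at 1e-6 (NNLS on noise-free input),
1e-10 for the Fisher oracle agreement, 1e-9 for probability-simplex checks;
AUC/accuracy bands as listed in the tests. Degenerate inputs are defined
rather than left to chance: empty DMR folds score by prior, constant
windows drop out of correlation and t tests, all-identical group tests
return (0, 1), and zero-coverage windows are missing, not zero.
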
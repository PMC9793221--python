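# Methods

`soygs` evaluates how training-population design and marker selection shape
genomic-selection (GS) accuracy on a structured crop diversity panel. The
pipeline mirrors a common study design in soybean seed-composition genetics:
an RR-BLUP prediction engine, a mixed-linear-model (MLM) association scan
with structure and kinship control, and four evaluation designs
(training-size sweep, phenotype-stratified prediction, structure-stratified
prediction, association-thresholded marker subsets). Because the package is
validated on simulation, every design has a synthetic panel generator whose
ground truth the tests can interrogate.

## Prediction model

RR-BLUP treats all markers as random effects with a common variance:

    y = 1 mu + Z u + e,     u ~ N(0, sigma_u^2 I),   e ~ N(0, sigma_e^2 I),

where `Z` is the column-centered training dosage matrix (n samples x m
markers). This is equivalent to GBLUP with genetic covariance
`sigma_u^2 Z Z'`, so after one eigendecomposition `Z Z' = U D U'` the
restricted likelihood is a one-dimensional function of the variance ratio
`delta = sigma_e^2 / sigma_u^2`. We profile out the intercept and scale in
rotated coordinates and maximize over `log(delta)` on [log 1e-9, log 1e9]:
a 41-point coarse grid locates the basin, then bounded Brent refinement
reaches `xatol = 1e-8`. The grid pass costs O(n) per evaluation and makes
the optimization robust to the (rare) flat or multimodal profiles that a
single bounded search can fall into. Marker effects use the push-through
identity `u = Z'(Z Z' + delta I)^{-1}(y - mu 1)`, so only n x n systems are
ever formed. Because `Z` is column-centered, `1` is a null eigenvector of
`Z Z'` and the GLS intercept equals the training mean; the fit is exactly
the dense Henderson mixed-model-equation solution (verified to 1e-8 against
an extended-precision dense solve in the test suite).

Prediction accuracy is the Pearson correlation between predicted and
observed values in the prediction set. Negative values are reported as-is;
a constant vector yields a flagged missing value (NaN), never a silent drop.
Reported `estimated_h2` is `sigma_u^2 tr(ZZ')/n / (sigma_u^2 tr(ZZ')/n +
sigma_e^2)`, the genomic heritability implied by the fit.

An optional `gram` argument to `fit_rrblup` accepts the uncentered dosage
cross-product `D D'` of the training rows; it is double-centered internally
(`Z Z' = H D D' H`). Evaluation designs compute one panel-wide gram and
slice it per training subset, cutting the dominant cost of repeated fits.
This is purely a cache: results are identical either way.

## Association scan

The MLM per marker is `y = mu + x alpha + P beta + g + e`, with `P` the
leading principal components of the standardized genotypes (3 by default)
and `g ~ N(0, K sigma_g^2)` on the VanRaden method-1 kinship

    K = W W' / (2 sum_k p_k (1 - p_k)),

`W` the column-centered dosages, monomorphic markers excluded from both
numerator and denominator. Variance components are estimated once by REML
on the null (no-marker) model and held fixed across markers — the
P3D/EMMAX approximation that mainstream MLM GWAS software defaults to.
Each marker is then an F-test (1, n−p−1 df) in the whitened regression;
scores are `-log10(P)` computed via the log survival function so strong
hits stay finite. Markers constant after covariate projection are flagged
untestable. Under an unstructured null the p-values are KS-uniform; under
a structured null the PCs+K scan keeps the genomic-control inflation factor
near 1 while an unadjusted scan inflates catastrophically (both are
asserted in the acceptance tests).

Marker sets for downstream GS use strict thresholds on the score
(`score > t`, with `t = 0` meaning "all testable markers"), plus
size-matched uniform random control sets.

## Synthetic panels

The generator emulates the structure of a large cultivated soybean
germplasm panel genotyped on a dense chip (≈1,000 accessions, thousands of
post-MAF-filter biallelic SNPs, several genetic subpopulations, an additive
seed-composition trait in mg/g):

* **Allele frequencies.** Ancestral frequencies are Uniform(0.05, 0.95);
  subpopulation frequencies follow the Balding–Nichols construction
  `Beta(p(1-F)/F, (1-p)(1-F)/F)` with divergence `F` = `fst` (default 0.1
  for the benchmark panel; 0 collapses all groups onto the ancestral
  frequency).
* **Haplotypes and LD.** Within a subpopulation each haplotype is a
  first-order Markov chain along the marker map: with probability `ld_rho`
  (default 0.5) the allele copies its left neighbour, otherwise it is a
  fresh Bernoulli draw. The chain restarts at chromosome boundaries (20
  simulated chromosomes, evenly spaced positions on a 1 kb grid). Adjacent
  genotype correlation therefore rises monotonically with `ld_rho`, and
  genotypes are exactly Hardy–Weinberg within a group.
* **Trait.** `n_qtl` causal markers (default 150) are drawn without
  replacement with standard-normal effects; genetic values are centered
  dosages times effects; Gaussian noise is calibrated on the realized
  genetic variance so var(g)/var(y) equals `h2` (default 0.5) in
  expectation; an affine rescale then sets the trait mean and CV (defaults
  434.2 mg/g and 6.9%, typical of soybean seed protein). The rescale is
  applied after calibration, so heritability and all correlation-based
  accuracies are unaffected.
* **Cross-group effect heterogeneity.** `qtl_effect_corr` (default 1.0)
  sets the correlation of QTL effects across subpopulations: each group
  expresses `r_g * shared + sqrt(1 - r_g^2) * group-specific` effects.
  With shared effects and genotyped causal markers, RR-BLUP transfers
  across subpopulations almost losslessly, and the strong within-group
  advantage that real structured panels show (near-zero intergroup
  accuracy next to 0.4–0.5 intragroup accuracy) cannot arise from
  frequency divergence alone. Real panels plausibly combine ungenotyped
  QTL, group-specific LD phase, allelic series and within-group family
  structure; a sub-unity cross-group genetic correlation is the minimal
  stand-in for all of these. The structure-stratified benchmark uses
  `qtl_effect_corr = 0.4`, inside the range reported for across-group
  genetic correlations in crop panels; every other design runs at the
  default 1.0.
* **Benchmark panel.** `benchmark_config()` gives 1,007 samples in five
  subpopulations with sizes proportional to 259/174/108/86/79 (the genetic
  groups of the panel being emulated, allocated by largest remainder:
  369/248/154/123/113), 3,000 markers, 150 QTL, h2 = 0.5.

What the generator does **not** emulate: family/pedigree structure within
groups, ungenotyped causal variants, LD phase differences beyond what
effect heterogeneity absorbs, genotyping error, missing-data patterns
(an optional uniform `missing_rate` exists for exercising imputation), and
multi-environment trait variation (one value per sample). Passing tests
therefore certify the statistical machinery and the direction of design
effects under an additive polygenic model — not real-data accuracy levels,
which depend on LD with unobserved QTL and on relatedness structure the
simulator deliberately omits.

## Population structure surrogate

Discrete genetic subpopulations come from k-means over the leading
principal components (10 by default) of the LD-pruned, standardized
genotypes, with k chosen over 2–6 by mean silhouette and groups relabelled
by descending size. This replaces Bayesian admixture MCMC: the downstream
designs need only a defensible discrete partition, and on simulated
structure the surrogate recovers the true grouping essentially perfectly
at moderate divergence (asserted in tests). A best silhouette below 0.2 is
flagged as weak structure. LD pruning is the standard greedy
kept-neighbour scan: keep the first marker per chromosome, then keep each
subsequent marker iff its squared Pearson correlation with the most
recently kept marker is below `r2_max` (default 0.50).

## Evaluation designs

All designs derive every repeat/fold from its own seed substream
(`SeedSequence([master, design-specific ints...])`), so results are
bit-reproducible and reducing a repeat count never changes the repeats
that remain.

* **Training-size sweep** — sizes 100–900 (step 100) sampled uniformly
  without replacement, the rest of the panel predicted, 150 repeats per
  size by default (reduced in tests; see below). Mean and SD per size.
* **Phenotype strata** — samples ranked by trait value and cut into four
  contiguous blocks (floor(n/4) with the remainder going to the
  lowest-value groups, ties broken by sample ID: 1,007 → 252/252/252/251).
  Off-diagonal cells train on all of one group and predict all of another;
  diagonal cells are fivefold CV within the group.
* **Structure strata** — the same g × g matrix over the genetic partition,
  plus leave-one-group-out (train on the union of the other groups).
* **Marker subsets** — for each `-log10(P)` threshold in {0,1,2,3,4}, the
  associated set and size-matched random sets run through the same
  fivefold 80/20 CV folds (paired comparisons). Two selection modes exist
  deliberately: the default recomputes GWAS inside each training fold, so
  selection never sees test phenotypes; `paper_mode=True` reproduces the
  original design of selecting once on the full panel before CV. The
  full-panel mode leaks test phenotypes into selection and visibly
  inflates CV accuracy at aggressive thresholds — the package keeps both
  so the size of that bias can be measured rather than guessed.

Degenerate cells (undersized groups, empty selections, constant
predictions) are flagged missing (NaN) and carried through summaries, not
dropped or zeroed.

## Numerical and edge-case conventions

* MAF boundary is inclusive: a marker at exactly the 5% default threshold
  is retained ("less than 5%" is removed). All-missing markers are removed
  by the filter, and mean imputation refuses them with a pointer to the
  filter.
* Descriptive trait statistics use sample (n−1) SD/variance and the
  bias-corrected sample skewness and excess kurtosis (the conventions of
  mainstream statistics packages). CV is undefined (flagged) for
  non-positive means; skewness/kurtosis are undefined for constant traits.
* Kinship symmetry is enforced to 1e-10; PSD is asserted in tests as
  min eigenvalue > −1e-8 × max.
* PCA component signs are fixed by making each component's
  largest-magnitude loading positive, so scores are fully deterministic.
* Zero-variance markers: dropped inside PCA standardization, treated as
  r² = 0 (kept, logged) by the LD pruner, untestable (NaN) in the scan,
  and excluded from the kinship denominator.
* `sigma_u^2 -> 0` (no usable marker signal) yields `u = 0`, mean-only
  predictions and `lambda = inf`, flagged rather than failing.

## Problem sizes used in the automated checks

The shipped tests and the acceptance script run the designs at reduced
sizes chosen to keep the full suite fast while leaving every effect
clearly resolvable: sweeps use 25 repeats at sizes 100 and 900 on ten
1,007 × 3,000 panels; stratification checks use ten panels of 1,000–1,007
samples × 2,000 markers; marker-subset checks use ten 1,007 × 3,000 panels
in full-panel selection mode; calibration checks use 300–400 samples ×
1,000–1,500 markers over 10–20 seeds. The acceptance script runs one
benchmark panel end to end with 15 repeats per sweep size.

## Known limitations

* Real-data accuracy magnitudes are not reproduced and are not a target:
  with 3,000 markers, 150 QTL and h2 = 0.5 the benchmark panel tops out
  around r ≈ 0.3–0.4 in the sweep, versus 0.6–0.85 reported on dense-chip
  soybean data; the directional structure of the results is the subject of
  the tests.
* The leave-one-group-out design on phenotype quartiles does not show
  "extreme quartiles predict worse": under a purely additive panmictic
  model the middle quartiles' narrower trait range depresses their Pearson
  accuracy instead. This is a genuine property of the generative model,
  documented rather than asserted away.
* The k-means structure surrogate gives hard assignments; admixed
  individuals have no representation.
* REML profiles are unimodal in essentially all practical fits, but the
  coarse-grid-plus-refinement optimizer only guarantees a local optimum
  within the bracketing interval.
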
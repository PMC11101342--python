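# Methods

This note documents the statistical procedures `gutlink` implements, the
modelling choices behind the synthetic cohort generator, and the numerical
conventions — in enough detail that every default could be re-derived or
deliberately changed.

## Study design being modelled

Two birth cohorts are analysed in parallel: a larger cohort (A, default 212
subjects) whose caregiver-rated SRS-2 T-scores sit below the normative mean
(intercept 43.6, residual SD 4.8), and a smaller validation cohort (B,
default 92 subjects) near the normative distribution (49.9, 8.5). Each
subject contributes up to two stool samples, assigned to an **early**
([0, 6 months), half-open) or **late** ([6 months, 2 years]) window on the
sample-age field. Windows and cohorts are always analysed separately; no
model pools early and late samples, so repeated-measures correlation never
enters the likelihood (and random effects are deliberately out of scope).

The covariate set is fixed across all adjusted models: gestational age,
child's sex, peripartum antibiotic exposure, delivery mode, exclusive
breastfeeding at collection, maternal smoking, maternal and paternal age,
marital status, parity, maternal education, and the child's age at SRS-2
completion. Binary covariates are 0/1-coded; missingness is an explicit NaN
mask.

## Community structure

Bray–Curtis dissimilarity is computed on total-sum-scaled profiles. A pair
of all-zero samples has an undefined quotient and is reported as 0 with a
warning rather than an error — degenerate samples are flagged upstream.

PERMANOVA uses **marginal** (type-III-like) sums of squares, since each
term's contribution is assessed given all other terms: with G the
Gower-centred matrix of −½d², SSₜ = tr(H_full G) − tr(H₋ₜ G), where the hat
matrices are pseudoinverse projections of the full design and the design
with term t removed. Significance comes from **free permutation of metadata
rows** (equivalently, joint permutation of G's rows and columns), 9,999
permutations by default, with the add-one estimator
p = (1 + #{F\* ≥ F}) / (1 + N) so p has resolution 1/(N+1) and is never
zero. Residual permutation schemes are not implemented; free permutation is
the common default of the R implementation this mirrors, and the test
calibrates correctly in the package's own null simulations (rejection rate
0.02–0.08 at α = 0.05). Rank-deficient designs are an error naming the
collinear columns, not a silent drop.

Alpha diversity: Shannon uses the natural logarithm (the base cannot be
inferred from typical reported index values, so ln is chosen and stated);
inverse Simpson is 1/Σp². Diversity regressions standardise diversity to
z-scores so the coefficient reads "SRS-2 difference per SD of diversity".

## Per-feature association models

The screen follows the MaAsLin2 convention: OLS of log2(relative abundance +
pseudocount) on score + covariates, per feature, BH-FDR across retained
features. The **pseudocount is half the smallest nonzero relative abundance
in the table** (per table, not per feature) — the standard choice that keeps
the transform order-preserving without letting rare features dominate. The
**prevalence floor defaults to 10%** of samples; the two-stage convention
(screen at q < 0.1, then reverse regression) is a pipeline default with both
thresholds configurable. Reverse regressions report SRS-2 difference per
doubling of relative abundance, i.e. the slope on log2 abundance.

Sex-specific effects use a product term (log2-abundance × sex) in the full
model; p_interaction is the Wald test of that coefficient. Stratified
estimates refit the reverse regression within each sex, which is
algebraically identical to fitting the full model on the subset (verified to
1e-10 in tests). A comparison-of-stratified-fits test would be an
alternative; the product-term test was chosen as the conventional one.

Confidence intervals throughout are **normal-approximation ±1.96·SE** rather
than t quantiles. At the study's sample sizes (n ≈ 90–480) the difference is
under 1% of the interval width; the choice is uniform across single fits and
Rubin-pooled fits so intervals are comparable.

## Imputation and pooling

Missing covariates are imputed by chained equations: continuous covariates
by predictive-mean matching (OLS on all other covariates, donor pool k = 5),
binary covariates by matching on the logistic decision score with a fallback
to an observed-frequency draw if the logistic fit fails. Defaults: 10
sweeps, m = 20 copies, independent seeded RNG streams per copy; observed
cells are bit-identical across copies. This is a deliberately compact
chained-PMM engine, not a port of any particular R package; its contract is
checked by MCAR recovery and by exact agreement with complete-case fits at
zero missingness. MAR/MNAR mechanisms are not generated (the simulator is
MCAR-only), so the imputation path is validated for bias under MCAR, not for
selection-bias correction.

Rubin's rules pool the m fits: β̄ = mean, total variance W̄ + (1 + 1/m)B.
With m = 1 the between-imputation variance is defined as zero.

## Gene-set enrichment (FSEA)

For each measure — the raw SRS-2 score, and residuals from OLS of the score
on the full covariate set — Pearson correlations are computed between the
measure and every UniRef90 gene family **found in at least 4 subjects**,
with zero abundances entering as observed zeros (prevalence governs
inclusion; zeros are data, not missingness). Zero-variance families are
excluded and counted.

Each named set is tested by Mann–Whitney U of in-set vs out-of-set
correlations; a family in the set never appears in the comparison pool. The
exact null is used when n_in·n_out ≤ 10,000 and the pooled correlations are
tie-free; otherwise the tie-corrected normal approximation with continuity
correction (within 0.02 of exact at group sizes ≥ 20 in tests). Two-sided p
throughout, since both positively and negatively enriched sets are
scientifically meaningful. BH-FDR is applied across sets **within a measure
(and, in the pipeline, within cohort × window)**, mirroring separately
reported analyses; the significance flag is q < 0.1. `med` is reported as
the **median in-set correlation**; the alternative reading (in-set minus
out-of-set median difference) is available via `med_mode =
"median_difference"`. Sets emptied by prevalence filtering are flagged
untestable, kept in the output, and excluded from the FDR family.

Taxon contributions divide the summed stratified abundance of in-set
families per taxon by the total, with an `unclassified` remainder where
strata undershoot the unstratified parent; ties rank lexicographically.
Stratified rows are read from the gene-family tables (stratification is a
property of the functional profiler's output; a species-stratified "taxonomic"
table is interpreted as such).

## Cross-cohort transfer and metabolites

The transfer model is OLS of the score on log2-transformed **shared**
species (prevalence ≥ 10% in both cohorts — motivated by the observation
that single-cohort hits often fail to transfer simply because the species is
rare in the other cohort; per-cohort prevalences are reported for every
non-shared feature) plus covariates. When features ≥ samples, a ridge fit
with seeded 5-fold cross-validated penalty replaces OLS — a numerical
fallback for stress tests, not the default path. Prediction is a
deterministic linear map; model features absent from the test table are
imputed as zero abundance, counted and warned. Evaluation reports Pearson r,
RMSE and MAE; no ordering between RMSE and MAE is assumed.

Metabolite models regress the score on log2 relative concentration,
unadjusted or fully adjusted. Concentrations must be strictly positive — NMR
relative concentrations are, and a pseudocount would silently change the
per-doubling scale — so nonpositive values are an error, not a patch.

## The synthetic cohort generator

The generator's role is to produce data with exactly the structure the
models assume, with planted parameters recoverable by construction:

- **Abundances** are per-feature log-normal intensities (feature-level mean
  offsets ~ N(0,1); within-feature log SD defaults: species 1.0, gene
  families 1.0), Bernoulli-zeroed at the sparsity rate (defaults: species
  0.7, gene families 0.5), then total-sum scaled. An all-zero sample is
  resampled once, then flagged. The marginal distribution of real
  gene-family abundances is not identifiable from summary statistics alone;
  sparse log-normal is the modelling choice and is recorded in `truth.json`.
- **Scores** are assembled in stages: intercept + covariate effects +
  Gaussian noise (metadata stage), plus β·centred-log2(abundance) for each
  planted species (taxonomic stage; planted species are exempt from
  zeroing so the per-doubling scale is well defined), plus β·centred-log2
  for each planted metabolite. Planting on the log2 scale makes the
  "per-doubling" regression coefficient the direct estimand.
- **Planted gene-set correlations** use the exact Gaussian construction:
  in-set family log-intensity = δ·z(score) + √(1−δ²)·ε, giving expected
  Pearson correlation δ on the log scale before sparsification — analytic,
  not rejection-sampled, so recovery tests have closed-form expectations.
  Gene families are generated after the score is finalised; the cohort
  orchestrator enforces this ordering.
- **Covariate marginals and MCAR missingness rates** default to the
  published characteristics of the larger cohort (e.g. gestational age
  N(39.2, 1.7) weeks, 56% male, ~10% missing breastfeeding status).
  Missingness is MCAR only.
- **Metabolites** are log-normal with **log2 SD 2.0** — fecal short-chain
  fatty acid relative concentrations span several doublings, and this
  dispersion makes a planted 0.86-per-doubling coefficient estimable to
  about ±0.1 (1 SE) at n = 500. A configurable formula-feeding shift raises
  a metabolite's log2 concentration among non-exclusively-breastfed
  subjects, creating the confounding path under which covariate adjustment
  attenuates the unadjusted estimate.
- Two samples per subject (early/late) are drawn independently given the
  subject's score; the generator does not model longitudinal
  autocorrelation, strain structure, or phylogenetic correlation between
  features. Passing tests therefore certify the statistics under the assumed
  sampling model, not robustness to real-data pathologies (batch effects,
  compositional correlation, MNAR missingness).

Determinism: every stage draws from its own `SeedSequence([seed, stage,
cohort])` stream, so any generator can be called independently and the full
cohort is bit-reproducible from config + seed (the end-to-end pipeline is
byte-identical across reruns, including output files and manifest hashes).

## Pipeline conventions

Stages run per cohort × window; complete cases are used for adjusted models,
and covariates that are constant within a stratum (a rare binary level can
vanish in a small cohort-window subset) are dropped from that stratum's
design rather than raising a rank error. The manifest records package
version, seed, thresholds, per-stage counts, and a SHA-256 per output file;
it contains no timestamps, by design, so identical runs hash identically.
Any stage failure halts the run and writes a partial manifest naming the
stage.

## Problem sizes in the checked properties

The test suite validates calibration and recovery at deliberately moderate
scales — e.g. 200 null PERMANOVA datasets of n = 60 with 999 permutations,
50 planted-enrichment seeds at 2,000 gene families × 100 subjects, 200
coverage simulations per planted coefficient — sizes at which Monte-Carlo
bands (binomial SE on a rejection rate, CI coverage over 200 draws) are tight
enough to detect miscalibration while each property remains re-runnable in
seconds to a few minutes.

## Known limitations

- Only OLS model families (no zero-inflated or negative-binomial screens).
- Bray–Curtis is the only beta-diversity metric; no ordination or PERMDISP.
- The FSEA measure is the Pearson correlation of untransformed relative
  abundance with the score; results are not invariant to monotone transforms
  of abundance, and no rank-based correlation variant is provided.
- The imputation engine is intentionally minimal; covariates with strong
  nonlinear dependence would need a richer chained model.
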
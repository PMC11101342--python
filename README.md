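# gutlink

`gutlink` is a tested, reusable implementation of a prospective
microbiome-epidemiology analysis: does the infant/toddler gut metagenome,
profiled in the first two years of life, associate with later autism-related
social behavior measured by the Social Responsiveness Scale (SRS-2, T-scores
with normative mean 50 and SD 10)?

It is written for microbiome epidemiologists who have MetaPhlAn-style species
profiles, HUMAnN-style UniRef90 gene-family tables (including
taxon-stratified rows), sample covariates, and optionally fecal-metabolite
relative concentrations — and who want the full analysis stack behind one
library surface, exercisable end-to-end on a seeded synthetic cohort
generator with planted, recoverable effects.

## What it computes

Per cohort and age window (early, < 6 months; late, 6 months–2 years,
analyzed separately and never pooled):

- **Community structure.** Bray–Curtis dissimilarity
  d(x, y) = Σᵢ|xᵢ − yᵢ| / Σᵢ(xᵢ + yᵢ), and a marginal-SS PERMANOVA on the
  Gower-centred matrix G of squared distances: for each term,
  SSₜ = tr(H_full G) − tr(H₋ₜ G), R² = SSₜ / tr(G), pseudo-F =
  (SSₜ/dfₜ)/(SS_res/df_res), with p from free permutation of metadata rows
  (add-one estimator). Cross-checked against `vegan::adonis2(by = "margin")`.
- **Diversity.** Shannon H = −Σ pᵢ ln pᵢ and inverse Simpson 1/Σ pᵢ²,
  regressed against SRS-2 scores per SD of diversity, covariate-adjusted.
- **Per-species screen.** MaAsLin2-style models with log2(relative abundance
  + pseudocount) as the outcome; hits at BH-FDR q < 0.1 are refit in reverse
  so effects are reported as SRS-2 difference per doubling of relative
  abundance, with sex-interaction and sex-stratified models.
- **Gene-set enrichment (FSEA).** Neuroactive gene sets (named KO
  collections resolved to UniRef90 ids through a mapping table) are tested by
  Pearson-correlating every gene family found in ≥ 4 subjects with the score
  (and with residuals of score ~ all covariates), then comparing in-set vs
  out-of-set correlations with a Mann–Whitney U test (exact when feasible,
  tie-corrected normal otherwise), BH-FDR across sets. `med` is the median
  in-set correlation. Taxon-stratified tables decompose a set's abundance
  into per-taxon shares.
- **Covariate imputation.** Chained-equation imputation (predictive-mean
  matching, logistic-score matching for binaries) with Rubin's-rules pooling:
  pooled β = mean; total variance = W̄ + (1 + 1/m)·B.
- **Cross-cohort transfer.** A score model (log2 shared species +
  covariates) fit on one cohort predicts the other; evaluated by Pearson r,
  RMSE and MAE.
- **Metabolites.** SRS-2 regressed on log2 relative concentrations,
  unadjusted and fully adjusted (per-doubling coefficients).

The `synth` module generates two-cohort synthetic studies matching the
analysis' assumptions — compositional log-normal abundance tables with
configurable sparsity, the standard covariate set with MCAR missingness, and
planted effects on the log2 scale so every estimand is recoverable — plus a
`truth.json` record sufficient to verify recovery.

## Worked example

```python
from gutlink.synth import SimulationConfig, CohortSpec, generate_cohort, make_catalog
from gutlink.fsea import run_fsea
from gutlink.assoc import reverse_regression
from gutlink.profiles import COVARIATES

cfg = SimulationConfig(
    seed=42,
    cohorts={"A": CohortSpec(n_subjects=120, srs2_intercept=43.6, srs2_noise_sd=4.8)},
    n_species=80, n_genefamilies=1000, n_sets=10, set_size=25,
    set_delta={"set_00": 0.2},            # planted "butyrate-synthesis-like" set
    species_beta={"Species_0000": 0.41},  # planted per-doubling species effect
)
catalog = make_catalog(cfg)
cohort = generate_cohort(cfg, "A", catalog)

early = cohort.metadata[cohort.metadata["window"] == "early"]
covs = [c for c in COVARIATES if early[c].nunique(dropna=True) > 1]
cc = early.dropna(subset=covs)

gf = cohort.genefamilies.copy()
gf.data = gf.data.loc[cc.index]
enrich = run_fsea(gf, cc, catalog, covs, min_subjects=4)
print(enrich[enrich.measure == "score"].head(3)[
    ["set", "n_in", "U", "med", "p", "q", "significant"]].to_string(index=False))

rev = reverse_regression(cohort.taxonomic.data.loc[cc.index, "Species_0000"], cc, covs)
c = rev.coef("log2_abundance")
print(f"Species_0000: beta = {c.beta:.2f} per doubling, "
      f"95% CI ({c.ci_low:.2f}, {c.ci_high:.2f}), p = {c.p:.2g}")
```

prints

```
   set  n_in       U       med        p        q  significant
set_00    25 17145.0  0.047485 0.000508 0.005083         True
set_07    25  9194.0 -0.052056 0.035819 0.179094        False
set_03    25  9850.0 -0.029998 0.101228 0.337427        False
Species_0000: beta = 0.42 per doubling, 95% CI (-0.25, 1.09), p = 0.23
```

The planted gene set (`set_00`) is the only one flagged at q < 0.1: its
in-set gene-family correlations with the score sit measurably above the
out-of-set pool (median in-set r = 0.047), and the Mann–Whitney U of 17,145
against 25 × 975 comparisons yields p ≈ 5 × 10⁻⁴ after prevalence filtering.
The planted species effect (true β = 0.41 per doubling) is recovered at
β̂ = 0.42, though — as in real cohorts of this size — the covariate-adjusted
interval is wide.

A full run (both cohorts, both windows, transfer and metabolite stages,
hashed output manifest) is one call:

```bash
gutlink pipeline run --config cfg.yaml
```

or `gutlink synth / community / screen / fsea / metab` for the individual
stages on files.

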
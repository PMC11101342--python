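"""Seeded synthetic cohorts with the statistical structure the analyses assume.

Two birth cohorts are emulated: cohort A (the larger, with two stool samples
per subject and fecal metabolomics on a subset-like basis) and cohort B (the
smaller validation cohort).  Each subject carries the standard covariate set
with missing-completely-at-random masks, a behavioral T-score, and sparse
compositional species and UniRef90 gene-family profiles for an early
(< 6 month) and a late (6 month - 2 year) sample window.

Effects are planted on the log2 scale so per-doubling regression
coefficients are directly recoverable, and in-set gene-family correlations
use an exact Gaussian construction (family log-intensity = delta * z(score) +
sqrt(1 - delta^2) * noise) so the expected Pearson correlation with the score
equals the planted delta before sparsification.

Score assembly is staged: ``generate_metadata`` draws covariates, covariate
effects and noise; ``generate_taxonomic`` and ``generate_metabolites`` add
their planted log2-scale contributions to the score; ``generate_genefamilies``
must run last because planted sets correlate with the finalised score.
``generate_cohort`` orchestrates the stages in that order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import AbundanceTable, GeneSetCatalog

# Stage tags keep the per-operation RNG streams independent of call order.
_STAGES = {"metadata": 1, "taxonomic": 2, "genefamilies": 3,
           "metabolites": 4, "catalog": 5}


@dataclass
class CohortSpec:
    """Size and score scale of one cohort (marginals follow the two study
    cohorts: the larger cohort scores below the normative mean of 50, the
    smaller near it)."""

    n_subjects: int
    srs2_intercept: float
    srs2_noise_sd: float


def _default_cohorts() -> dict:
    return {
        "A": CohortSpec(n_subjects=212, srs2_intercept=43.6, srs2_noise_sd=4.8),
        "B": CohortSpec(n_subjects=92, srs2_intercept=49.9, srs2_noise_sd=8.5),
    }


def _default_covariate_marginals() -> dict:
    # (kind, params): Bernoulli rate or Normal (mean, sd), matching the
    # published cohort characteristics table.
    return {
        "gestational_age": ("normal", (39.2, 1.7)),
        "sex_male": ("bernoulli", 0.56),
        "peripartum_antibiotics": ("bernoulli", 0.53),
        "csection": ("bernoulli", 0.27),
        "exclusive_breastfeeding": ("bernoulli", 0.59),
        "maternal_smoking": ("bernoulli", 0.04),
        "maternal_age": ("normal", (32.4, 4.2)),
        "paternal_age": ("normal", (33.9, 5.8)),
        "married": ("bernoulli", 0.89),
        "parous": ("bernoulli", 0.49),
        "maternal_education": ("bernoulli", 0.44),
        "age_at_srs2": ("normal", (3.2, 0.4)),
    }


def _default_missingness() -> dict:
    # MCAR rates per covariate, following the larger cohort's missing-data
    # pattern (breastfeeding status is the leakiest questionnaire item).
    return {
        "gestational_age": 0.0,
        "sex_male": 0.0,
        "peripartum_antibiotics": 0.024,
        "csection": 0.024,
        "exclusive_breastfeeding": 0.104,
        "maternal_smoking": 0.014,
        "maternal_age": 0.0,
        "paternal_age": 0.024,
        "married": 0.028,
        "parous": 0.014,
        "maternal_education": 0.028,
        "age_at_srs2": 0.0,
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with the planted truth.

    Planted effects:

    ``species_beta``
        species name -> score units per doubling of relative abundance
        (applied to the early-window sample of cohort-A-style analyses).
    ``set_delta``
        gene-set name -> target Pearson correlation of each in-set family's
        log-intensity with the score.
    ``metabolite_beta``
        metabolite name -> score units per doubling of relative concentration.
    ``covariate_effects``
        covariate -> additive score effect per unit (binary covariates: per
        level).
    ``formula_metabolite_shift``
        metabolite -> log2-concentration shift among formula-fed subjects
        (confounding path: formula feeding raises the metabolite while the
        breastfeeding covariate can independently shift the score).
    """

    seed: int
    cohorts: dict = field(default_factory=_default_cohorts)
    n_species: int = 150
    n_genefamilies: int = 2000
    n_sets: int = 20
    set_size: int = 25
    unirefs_per_ko: int = 2
    n_metabolites: int = 10
    species_sparsity: float = 0.7
    genefamily_sparsity: float = 0.5
    species_log_sd: float = 1.0
    genefamily_log_sd: float = 1.0
    metabolite_log2_sd: float = 2.0
    covariate_marginals: dict = field(default_factory=_default_covariate_marginals)
    covariate_effects: dict = field(default_factory=dict)
    missingness: dict = field(default_factory=_default_missingness)
    species_beta: dict = field(default_factory=dict)
    set_delta: dict = field(default_factory=dict)
    metabolite_beta: dict = field(default_factory=dict)
    formula_metabolite_shift: dict = field(default_factory=dict)
    windows: tuple = ("early", "late")
    stratify: bool = True  # emit per-taxon strata for gene families

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_species", "n_genefamilies", "n_sets", "set_size",
                     "n_metabolites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("species_sparsity", "genefamily_sparsity"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        for d in self.set_delta.values():
            if not abs(d) < 1:
                raise ValueError("planted |delta| must be < 1")
        if self.set_size > self.n_genefamilies:
            raise ValueError("set_size exceeds n_genefamilies")
        if self.n_sets * self.set_size > self.n_genefamilies:
            raise ValueError("catalog larger than the gene-family pool")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohorts"] = {k: dataclasses.asdict(v) if dataclasses.is_dataclass(v)
                        else dict(v) for k, v in self.cohorts.items()}
        d["windows"] = list(self.windows)
        return d


@dataclass
class SyntheticCohort:
    cohort: str
    metadata: pd.DataFrame  # one row per sample (subject x window)
    taxonomic: AbundanceTable
    genefamilies: AbundanceTable
    metabolites: pd.DataFrame  # subjects x metabolites, early window
    truth: dict


def _rng(config: SimulationConfig, stage: str, cohort: str = "") -> np.random.Generator:
    key = [config.seed, _STAGES[stage]] + [ord(c) for c in cohort]
    return np.random.default_rng(np.random.SeedSequence(key))


def species_names(config: SimulationConfig) -> list[str]:
    return [f"Species_{i:04d}" for i in range(config.n_species)]


def genefamily_names(config: SimulationConfig) -> list[str]:
    return [f"UniRef90_G{i:05d}" for i in range(config.n_genefamilies)]


def metabolite_names(config: SimulationConfig) -> list[str]:
    return [f"metabolite_{i:02d}" for i in range(config.n_metabolites)]


def make_catalog(config: SimulationConfig) -> GeneSetCatalog:
    """Disjoint gene sets over the simulated UniRef90 pool, expressed through
    a KO -> UniRef90 mapping so the catalog loader path is exercised."""
    rng = _rng(config, "catalog")
    fams = genefamily_names(config)
    perm = rng.permutation(config.n_genefamilies)
    sets, ko_members, mapping = {}, {}, {}
    cursor = 0
    for s in range(config.n_sets):
        name = f"set_{s:02d}"
        members = [fams[j] for j in perm[cursor:cursor + config.set_size]]
        cursor += config.set_size
        kos = []
        for g in range(0, len(members), config.unirefs_per_ko):
            ko = f"K{s:02d}{g:04d}"
            mapping[ko] = set(members[g:g + config.unirefs_per_ko])
            kos.append(ko)
        ko_members[name] = set(kos)
        sets[name] = set(members)
    return GeneSetCatalog(sets=sets, ko_members=ko_members, mapping=mapping)


def generate_metadata(config: SimulationConfig, cohort: str = "A") -> pd.DataFrame:
    """Per-sample metadata rows (subject x window) with the provisional score.

    The score at this stage is intercept + covariate effects + Gaussian
    noise; microbiome and metabolite contributions are added by the profile
    generators.  Missingness is MCAR per covariate.  Covariate values,
    the score, and missingness are constant across a subject's windows.
    """
    config.validate()
    spec = config.cohorts[cohort]
    rng = _rng(config, "metadata", cohort)
    n = spec.n_subjects
    subjects = [f"{cohort}{i:04d}" for i in range(n)]

    cov = {}
    for name, (kind, params) in config.covariate_marginals.items():
        if kind == "bernoulli":
            cov[name] = rng.binomial(1, params, size=n).astype(float)
        elif kind == "normal":
            mu, sd = params
            cov[name] = rng.normal(mu, sd, size=n)
        else:
            raise ValueError(f"unknown marginal kind {kind!r}")
    cov_df = pd.DataFrame(cov, index=subjects)

    effect = np.zeros(n)
    for name, beta in config.covariate_effects.items():
        effect += beta * cov_df[name].values
    noise = rng.normal(0.0, spec.srs2_noise_sd, size=n)
    score = spec.srs2_intercept + effect + noise

    mask = {}
    for name, rate in config.missingness.items():
        if name in cov_df.columns and rate > 0:
            mask[name] = rng.random(n) < rate

    rows = []
    age_early = rng.uniform(0.08, 0.45, size=n)   # years; ~6 weeks to <6 months
    age_late = rng.uniform(0.5, 2.0, size=n)
    for i, subj in enumerate(subjects):
        for window in config.windows:
            row = {"subject_id": subj, "sample_id": f"{subj}_{window}",
                   "cohort": cohort, "window": window,
                   "sample_age": age_early[i] if window == "early" else age_late[i],
                   "srs2_tscore": score[i]}
            for c in cov_df.columns:
                row[c] = np.nan if mask.get(c, np.zeros(n, bool))[i] else cov_df.at[subj, c]
            rows.append(row)
    md = pd.DataFrame(rows).set_index("sample_id")
    # stash the noise-free assembly pieces for the truth record
    md.attrs["score_noise_sd"] = spec.srs2_noise_sd
    return md


def _lognormal_table(rng, n_samples, names, log_sd, sparsity, protect=None):
    """Sparse compositional table: per-feature log-normal intensities with
    feature-level mean offsets, Bernoulli zeroing, then total-sum scaling."""
    n_feat = len(names)
    mu = rng.normal(0.0, 1.0, size=n_feat)
    intensity = np.exp(mu[None, :] + log_sd * rng.normal(size=(n_samples, n_feat)))
    if sparsity > 0:
        keep = rng.random((n_samples, n_feat)) >= sparsity
        if protect is not None:
            keep[:, protect] = True
        intensity = intensity * keep
    return intensity


def _tss(mat: np.ndarray, rng, resample_fn=None) -> tuple[np.ndarray, list[int]]:
    sums = mat.sum(axis=1)
    flagged = []
    for i in np.where(sums == 0)[0]:
        if resample_fn is not None:
            mat[i] = resample_fn(i)
            if mat[i].sum() == 0:
                flagged.append(i)
        else:
            flagged.append(i)
    sums = mat.sum(axis=1)
    sums[sums == 0] = 1.0
    return mat / sums[:, None], flagged


def generate_taxonomic(config: SimulationConfig, metadata: pd.DataFrame,
                       cohort: str = "A") -> AbundanceTable:
    """Species table per sample; plants per-species score effects.

    For each planted species, beta * centred log2(early-window relative
    abundance) is added to the subject's score in ``metadata`` (in place),
    so a per-doubling reverse regression on the early window recovers beta.
    Planted species are kept structurally present (no Bernoulli zeroing) so
    the per-doubling scale is well defined.
    """
    rng = _rng(config, "taxonomic", cohort)
    names = species_names(config)
    samples = list(metadata.index)
    protect = [names.index(s) for s in config.species_beta if s in names]
    raw = _lognormal_table(rng, len(samples), names, config.species_log_sd,
                           config.species_sparsity, protect=protect or None)

    def resample(i):
        return np.exp(rng.normal(0, config.species_log_sd, size=len(names))) * (
            rng.random(len(names)) >= config.species_sparsity)

    vals, flagged = _tss(raw, rng, resample)
    table = AbundanceTable(
        data=pd.DataFrame(vals, index=samples, columns=names),
        feature_kind="taxon",
        zero_samples=[samples[i] for i in flagged],
    )
    if config.species_beta:
        early = metadata["window"] == "early"
        by_subject = metadata.loc[early].set_index("subject_id")
        for sp, beta in config.species_beta.items():
            if sp not in names:
                raise ValueError(f"planted species {sp!r} not in the pool")
            ab = table.data.loc[by_subject.index.map(lambda s: f"{s}_early"), sp].values
            la = np.log2(ab + 1e-12)
            contrib = beta * (la - la.mean())
            per_subj = pd.Series(contrib, index=by_subject.index)
            metadata["srs2_tscore"] = metadata["srs2_tscore"].values + \
                per_subj.reindex(metadata["subject_id"]).values
    return table


def generate_metabolites(config: SimulationConfig, metadata: pd.DataFrame,
                         cohort: str = "A") -> pd.DataFrame:
    """Strictly positive relative concentrations (subjects x metabolites).

    Planted metabolites add beta * centred log2(concentration) to the score.
    A configured formula shift raises the metabolite's log2 concentration in
    formula-fed subjects (exclusive_breastfeeding == 0), creating the
    confounding path that attenuates adjusted estimates.
    """
    rng = _rng(config, "metabolites", cohort)
    subjects = metadata.loc[metadata["window"] == "early", "subject_id"].tolist()
    names = metabolite_names(config)
    log2c = rng.normal(0.0, config.metabolite_log2_sd,
                       size=(len(subjects), len(names)))
    early = metadata.loc[metadata["window"] == "early"].set_index("subject_id")
    bf = early["exclusive_breastfeeding"].reindex(subjects)
    formula = (bf.fillna(bf.dropna().mean() if bf.notna().any() else 0.5) < 0.5
               ).values.astype(float)
    for m, shift in config.formula_metabolite_shift.items():
        j = names.index(m)
        log2c[:, j] = log2c[:, j] + shift * formula
    conc = pd.DataFrame(np.exp2(log2c), index=subjects, columns=names)
    for m, beta in config.metabolite_beta.items():
        la = np.log2(conc[m].values)
        contrib = pd.Series(beta * (la - la.mean()), index=subjects)
        metadata["srs2_tscore"] = metadata["srs2_tscore"].values + \
            contrib.reindex(metadata["subject_id"]).values
    return conc


def generate_genefamilies(config: SimulationConfig, metadata: pd.DataFrame,
                          catalog: GeneSetCatalog,
                          cohort: str = "A") -> AbundanceTable:
    """UniRef90 table with planted in-set correlations and stratified taxa.

    Out-of-set families are null log-normals.  For a set with planted shift
    delta, each in-set family's log-intensity is delta * z + sqrt(1-delta^2)
    * noise, with z the standardised finalised score of the sample's subject,
    giving expected Pearson correlation delta on the log scale before
    sparsification.  Each family is split across 1-3 taxa by Dirichlet
    weights constant over samples, so strata sum exactly to the parent.
    """
    for name in config.set_delta:
        if name not in catalog.sets:
            raise ValueError(f"planted set {name!r} not in the catalog")
        if len(catalog.sets[name]) > config.n_genefamilies:
            raise ValueError(f"set {name!r} larger than the gene-family pool")
    rng = _rng(config, "genefamilies", cohort)
    names = genefamily_names(config)
    samples = list(metadata.index)
    score = metadata["srs2_tscore"].values.astype(float)
    z = (score - score.mean()) / score.std()

    shared = np.zeros(len(names))
    for set_name, delta in config.set_delta.items():
        for fam in catalog.sets[set_name]:
            j = names.index(fam)
            shared[j] = delta
    planted = shared != 0
    base_noise = rng.normal(size=(len(samples), len(names)))
    log_core = np.where(
        planted[None, :],
        shared[None, :] * z[:, None] + np.sqrt(1 - shared[None, :] ** 2) * base_noise,
        base_noise,
    )
    mu = rng.normal(0.0, 1.0, size=len(names))
    intensity = np.exp(mu[None, :] + config.genefamily_log_sd * log_core)
    if config.genefamily_sparsity > 0:
        keep = rng.random(intensity.shape) >= config.genefamily_sparsity
        intensity = intensity * keep

    vals, flagged = _tss(intensity, rng)
    df = pd.DataFrame(vals, index=samples, columns=names)

    strat: dict[str, pd.DataFrame] | None = None
    if config.stratify:
        taxa = [f"g__Genus{i:02d}.s__Genus{i:02d}_sp" for i in range(12)]
        strat = {}
        n_strata = rng.integers(1, 4, size=len(names))
        for j, fam in enumerate(names):
            k = int(n_strata[j])
            chosen = rng.choice(len(taxa), size=k, replace=False)
            w = rng.dirichlet(np.ones(k))
            strat[fam] = pd.DataFrame(
                df[fam].values[:, None] * w[None, :],
                index=samples, columns=[taxa[c] for c in chosen],
            )
    return AbundanceTable(
        data=df, feature_kind="genefamily", stratified=strat,
        zero_samples=[samples[i] for i in flagged],
    )


def generate_cohort(config: SimulationConfig, cohort: str = "A",
                    catalog: GeneSetCatalog | None = None) -> SyntheticCohort:
    """Orchestrate all four generators in the score-assembly order and attach
    the truth record."""
    config.validate()
    if catalog is None:
        catalog = make_catalog(config)
    metadata = generate_metadata(config, cohort)
    taxonomic = generate_taxonomic(config, metadata, cohort)
    metabolites = generate_metabolites(config, metadata, cohort)
    genefamilies = generate_genefamilies(config, metadata, catalog, cohort)
    truth = {
        "config": config.to_dict(),
        "cohort": cohort,
        "species_beta": dict(config.species_beta),
        "set_delta": dict(config.set_delta),
        "metabolite_beta": dict(config.metabolite_beta),
        "covariate_effects": dict(config.covariate_effects),
        "score_model": ("intercept + covariate effects + species log2 terms "
                        "+ metabolite log2 terms + N(0, noise_sd)"),
        "abundance_model": "log-normal with Bernoulli zeroing, TSS-closed",
    }
    return SyntheticCohort(cohort=cohort, metadata=metadata,
                           taxonomic=taxonomic, genefamilies=genefamilies,
                           metabolites=metabolites, truth=truth)


def write_cohort(sc: SyntheticCohort, outdir) -> dict:
    """Write the cohort in the pipeline's standard on-disk formats."""
    from pathlib import Path

    from .profiles import (write_genefamily_profiles, write_geneset_catalog,
                           write_taxonomic_profiles)

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxonomic": out / f"{sc.cohort}_taxa.tsv",
        "genefamilies": out / f"{sc.cohort}_genefamilies.tsv",
        "metadata": out / f"{sc.cohort}_metadata.csv",
        "metabolites": out / f"{sc.cohort}_metabolites.tsv",
        "truth": out / f"{sc.cohort}_truth.json",
    }
    write_taxonomic_profiles(sc.taxonomic, paths["taxonomic"])
    write_genefamily_profiles(sc.genefamilies, paths["genefamilies"])
    sc.metadata.reset_index().to_csv(paths["metadata"], index=False)
    sc.metabolites.to_csv(paths["metabolites"], sep="\t")
    with open(paths["truth"], "w") as fh:
        json.dump(sc.truth, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
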
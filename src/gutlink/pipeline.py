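"""End-to-end orchestration: per cohort and age window, community statistics,
the per-species screen, and gene-set enrichment; then cross-cohort transfer
and metabolite regressions; everything written to a result bundle with a
hashed manifest.

Age windows follow the half-open convention [0, 6 months) for early and
[6 months, 2 years] for late, on the sample-age field in years.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import SCORE_COL, feature_screen, reverse_regression
from .community import (alpha_diversity, bray_curtis, diversity_regression,
                        permanova_marginal)
from .fsea import run_fsea, taxon_contribution
from .profiles import COVARIATES
from .synth import SimulationConfig, CohortSpec, generate_cohort, make_catalog
from .transfer import (evaluate_predictions, fit_transfer_model,
                       metabolite_regression, predict_scores)

EARLY_MAX_YEARS = 0.5   # < 6 months
LATE_MAX_YEARS = 2.0


def assign_window(sample_age_years: float) -> str:
    if 0 <= sample_age_years < EARLY_MAX_YEARS:
        return "early"
    if EARLY_MAX_YEARS <= sample_age_years <= LATE_MAX_YEARS:
        return "late"
    raise ValueError(f"sample age {sample_age_years} outside [0, {LATE_MAX_YEARS}] years")


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    synthetic: SimulationConfig
    covariates: list[str] = field(default_factory=lambda: list(COVARIATES))
    permanova_terms: list[str] = field(default_factory=lambda: [SCORE_COL, "sex_male"])
    n_permutations: int = 999
    min_subjects: int = 4
    fdr_threshold: float = 0.1
    min_prevalence: float = 0.1

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if not 0 <= self.min_prevalence < 1:
            raise ValueError("min_prevalence must lie in [0, 1)")
        if self.min_subjects < 1:
            raise ValueError("min_subjects must be >= 1")
        self.synthetic.validate()

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "seed" not in raw:
            raise ValueError("config must declare a seed")
        syn = dict(raw.get("synthetic", {}))
        syn.setdefault("seed", raw["seed"])
        if "cohorts" in syn:
            syn["cohorts"] = {k: CohortSpec(**v) for k, v in syn["cohorts"].items()}
        cfg = cls(
            seed=raw["seed"],
            output_dir=raw.get("output_dir", "gutlink_out"),
            synthetic=SimulationConfig(**syn),
            covariates=list(raw.get("covariates", COVARIATES)),
            permanova_terms=list(raw.get("permanova_terms", [SCORE_COL, "sex_male"])),
            n_permutations=int(raw.get("n_permutations", 999)),
            min_subjects=int(raw.get("min_subjects", 4)),
            fdr_threshold=float(raw.get("fdr_threshold", 0.1)),
            min_prevalence=float(raw.get("min_prevalence", 0.1)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _window_view(cohort, window: str):
    """One sample per subject within the window: metadata + aligned tables."""
    md = cohort.metadata.loc[cohort.metadata["window"] == window].copy()
    tax = cohort.taxonomic.copy()
    tax.data = tax.data.loc[md.index]
    gf = cohort.genefamilies.copy()
    gf.data = gf.data.loc[md.index]
    if gf.stratified:
        gf.stratified = {k: v.loc[md.index] for k, v in gf.stratified.items()}
    return md, tax, gf


def _complete_cases(md: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    return md.dropna(subset=[c for c in covariates if c in md.columns])


def _usable_covariates(md: pd.DataFrame, covariates: list[str]) -> list[str]:
    """Drop covariates that are constant within this stratum (a rare binary
    level can vanish in a small cohort/window subset), which would make the
    design rank-deficient."""
    out = []
    for c in covariates:
        if c in md.columns and md[c].nunique(dropna=True) > 1:
            out.append(c)
    return out


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", **kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk).

    Any stage failure halts the pipeline; the partial manifest written so far
    names the failing stage.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_subjects": config.min_subjects,
            "fdr": config.fdr_threshold,
            "min_prevalence": config.min_prevalence,
            "n_permutations": config.n_permutations,
        },
        "stages": {},
        "outputs": {},
    }

    def _finish_output(name: str, path: Path, n_rows: int) -> None:
        manifest["outputs"][name] = {
            "path": path.name, "sha256": _sha256(path), "n_rows": n_rows,
        }

    stage = "synthesis"
    try:
        catalog = make_catalog(config.synthetic)
        cohorts = {name: generate_cohort(config.synthetic, name, catalog)
                   for name in config.synthetic.cohorts}
        manifest["stages"][stage] = {
            name: {"n_subjects": config.synthetic.cohorts[name].n_subjects,
                   "n_samples": len(c.metadata)}
            for name, c in cohorts.items()
        }

        permanova_rows, diversity_rows, screen_rows, fsea_frames = [], [], [], []
        contrib_rows = []
        for name, cohort in cohorts.items():
            for window in config.synthetic.windows:
                stage = f"community:{name}:{window}"
                md, tax, gf = _window_view(cohort, window)
                terms = [t for t in config.permanova_terms if t in md.columns]
                cc = _complete_cases(md, terms)
                dm = bray_curtis(_subset(tax, cc.index))
                pr = permanova_marginal(dm, cc, terms,
                                        n_permutations=config.n_permutations,
                                        seed=config.seed)
                for term, row in pr.terms.iterrows():
                    permanova_rows.append({"cohort": name, "window": window,
                                           "term": term, **row.to_dict()})

                ccov = _complete_cases(md, config.covariates)
                covs = _usable_covariates(ccov, config.covariates)
                for index in ("shannon", "inverse_simpson"):
                    div = pd.Series(
                        [alpha_diversity(tax.data.loc[s].values, index)
                         for s in ccov.index], index=ccov.index)
                    res = diversity_regression(div, ccov, covs)
                    c = res.coef("diversity_sd")
                    diversity_rows.append({
                        "cohort": name, "window": window, "index": index,
                        "beta_per_sd": c.beta, "se": c.se, "ci_low": c.ci_low,
                        "ci_high": c.ci_high, "p": c.p, "n": res.n})

                stage = f"screen:{name}:{window}"
                scr = feature_screen(_subset(tax, ccov.index), ccov,
                                     covs,
                                     min_prevalence=config.min_prevalence)
                hits = scr.table.loc[scr.table["q"] < config.fdr_threshold]
                for feat in scr.table.index:
                    row = {"cohort": name, "window": window, "species": feat,
                           **scr.table.loc[feat].to_dict(), "screen_hit": feat in hits.index}
                    if feat in hits.index:
                        rev = reverse_regression(
                            tax.data.loc[ccov.index, feat], ccov, covs)
                        c = rev.coef("log2_abundance")
                        row.update({"beta_per_doubling": c.beta,
                                    "rev_ci_low": c.ci_low, "rev_ci_high": c.ci_high,
                                    "rev_p": c.p})
                    screen_rows.append(row)

                stage = f"fsea:{name}:{window}"
                fs = run_fsea(_subset_gf(gf, ccov.index), ccov, catalog,
                              covs,
                              min_subjects=config.min_subjects,
                              fdr_threshold=config.fdr_threshold)
                fs.insert(0, "window", window)
                fs.insert(0, "cohort", name)
                fsea_frames.append(fs)

                top = fs.loc[fs["significant"] == True]  # noqa: E712
                for set_name in top["set"].unique():
                    shares = taxon_contribution(gf, catalog.sets[set_name])
                    for taxon, r in shares.iterrows():
                        contrib_rows.append({"cohort": name, "window": window,
                                             "set": set_name, "taxon": taxon,
                                             "share": r["share"]})

        stage = "write:per-window"
        perm_df = pd.DataFrame(permanova_rows)
        _write_tsv(perm_df, out / "permanova.tsv", index=False)
        _finish_output("permanova", out / "permanova.tsv", len(perm_df))
        div_df = pd.DataFrame(diversity_rows)
        _write_tsv(div_df, out / "diversity.tsv", index=False)
        _finish_output("diversity", out / "diversity.tsv", len(div_df))
        scr_df = pd.DataFrame(screen_rows)
        _write_tsv(scr_df, out / "screen.tsv", index=False)
        _finish_output("screen", out / "screen.tsv", len(scr_df))
        fsea_df = pd.concat(fsea_frames, ignore_index=True)
        _write_tsv(fsea_df, out / "fsea.tsv", index=False)
        _finish_output("fsea", out / "fsea.tsv", len(fsea_df))
        contrib_df = pd.DataFrame(contrib_rows,
                                  columns=["cohort", "window", "set", "taxon", "share"])
        _write_tsv(contrib_df, out / "taxon_contributions.tsv", index=False)
        _finish_output("taxon_contributions", out / "taxon_contributions.tsv",
                       len(contrib_df))
        manifest["stages"]["fsea"] = {
            "n_sets_flagged": int(fsea_df["significant"].sum()),
            "n_tests": len(fsea_df),
        }

        stage = "transfer"
        names = list(cohorts)
        if len(names) >= 2:
            train, test = cohorts[names[0]], cohorts[names[1]]
            md_tr, tax_tr, _ = _window_view(train, "early")
            md_te, tax_te, _ = _window_view(test, "early")
            cc_tr = _complete_cases(md_tr, config.covariates)
            cc_te = _complete_cases(md_te, config.covariates)
            tcovs = sorted(set(_usable_covariates(cc_tr, config.covariates))
                           & set(_usable_covariates(cc_te, config.covariates)))
            model = fit_transfer_model(
                _subset(tax_tr, cc_tr.index), cc_tr, tcovs,
                test_table=_subset(tax_te, cc_te.index),
                min_shared_prevalence=config.min_prevalence,
                train_cohort=names[0], seed=config.seed)
            pred = predict_scores(model, _subset(tax_te, cc_te.index), cc_te)
            ev = evaluate_predictions(pred, cc_te[SCORE_COL])
            tr_df = pd.DataFrame([{
                "train_cohort": names[0], "test_cohort": names[1],
                "window": "early", "method": model.method,
                "n_features": len(model.features), "pearson_r": ev.pearson_r,
                "rmse": ev.rmse, "mae": ev.mae, "n": ev.n}])
            _write_tsv(tr_df, out / "transfer_eval.tsv", index=False)
            _finish_output("transfer_eval", out / "transfer_eval.tsv", len(tr_df))

        stage = "metabolites"
        cohort = cohorts[names[0]]
        md_early = cohort.metadata.loc[cohort.metadata["window"] == "early"]
        md_by_subj = md_early.set_index("subject_id")
        cc = _complete_cases(md_by_subj, config.covariates)
        mcovs = _usable_covariates(cc, config.covariates)
        conc = cohort.metabolites.loc[cc.index]
        rows = []
        for adjusted in (False, True):
            fits = metabolite_regression(conc, cc, mcovs,
                                         adjusted=adjusted)
            for m, res in fits.items():
                c = res.coef("log2_concentration")
                rows.append({"metabolite": m, "adjusted": adjusted,
                             "beta_per_doubling": c.beta, "se": c.se,
                             "ci_low": c.ci_low, "ci_high": c.ci_high,
                             "p": c.p, "n": res.n})
        met_df = pd.DataFrame(rows)
        _write_tsv(met_df, out / "metab.tsv", index=False)
        _finish_output("metab", out / "metab.tsv", len(met_df))
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _subset(table, index):
    t = table.copy()
    t.data = t.data.loc[index]
    return t


def _subset_gf(table, index):
    t = table.copy()
    t.data = t.data.loc[index]
    if t.stratified:
        t.stratified = {k: v.loc[index] for k, v in t.stratified.items()}
    return t
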
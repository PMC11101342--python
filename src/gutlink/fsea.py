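"""Feature-set enrichment analysis (FSEA) of neuroactive gene sets.

For each measure (raw behavioral score, or residuals of the score on the full
covariate set) a Pearson correlation is computed between every sufficiently
prevalent UniRef90 gene family and the measure.  Each named gene set is then
tested with a Mann-Whitney U comparing the in-set correlations against the
correlations of all gene families outside the set, with Benjamini-Hochberg
correction across sets within a measure.  A species-stratified table
decomposes a set's abundance into per-taxon contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .assoc import SCORE_COL, bh_fdr
from .community import ols_table
from .profiles import AbundanceTable, GeneSetCatalog

#: Exact null enumeration is used when the product of group sizes is at most
#: this and the pooled correlations are tie-free; otherwise the tie-corrected
#: normal approximation.
EXACT_LIMIT = 10_000


@dataclass
class CorrelationVector:
    """Per-gene-family Pearson correlation with a measure."""

    table: pd.DataFrame  # index: feature; columns: r, prevalence
    measure: str  # "score" | "residual"
    n: int
    n_excluded_low_prevalence: int
    n_excluded_zero_variance: int


@dataclass
class FseaResult:
    set_name: str
    measure: str
    n_in: int
    n_out: int
    u_statistic: float
    p: float
    med: float
    q: float | None = None
    testable: bool = True
    exact: bool = False


def residualize(metadata: pd.DataFrame, covariates: list[str],
                score_col: str = SCORE_COL) -> pd.Series:
    """Residuals of an OLS of the score on the full covariate set."""
    res = ols_table(metadata[score_col].values, metadata[covariates],
                    model="score ~ covariates")
    return pd.Series(np.asarray(res.extra["resid"]), index=metadata.index)


def correlate_features(
    table: AbundanceTable,
    measure: pd.Series,
    min_subjects: int = 4,
    measure_tag: str = "score",
) -> CorrelationVector:
    """Pearson r of every gene family with the measure, zeros included.

    Subjects with zero abundance enter the correlation as observed zeros.
    Families nonzero in fewer than ``min_subjects`` subjects are excluded, as
    are zero-variance families (counted, not fatal).
    """
    X = table.data.loc[measure.index] if set(measure.index).issubset(
        set(table.data.index)) else table.data
    y = measure.values.astype(float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    prev_counts = (X > 0).sum(axis=0)
    keep = prev_counts >= min_subjects
    n_low = int((~keep).sum())
    Xk = X.loc[:, keep].values.astype(float)

    xc = Xk - Xk.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    zero_var = sx == 0
    if sy == 0:
        raise ValueError("measure has zero variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    cols = X.columns[keep]
    out = pd.DataFrame({"r": r, "prevalence": prev_counts[keep].values}, index=cols)
    n_zero_var = int(zero_var.sum())
    out = out.loc[~zero_var]
    return CorrelationVector(
        table=out, measure=measure_tag, n=n,
        n_excluded_low_prevalence=n_low,
        n_excluded_zero_variance=n_zero_var,
    )


def mwu_enrichment(
    correlations: CorrelationVector,
    geneset: set[str],
    set_name: str = "",
    med_mode: str = "in_set_median",
) -> FseaResult:
    """Mann-Whitney U of in-set vs out-of-set correlations.

    U counts, over in-set correlations, the out-of-set correlations below
    them (ties at one half).  The two-sided p comes from exact enumeration
    when the group-size product is small and the pooled values are tie-free,
    otherwise from the tie-corrected normal approximation with continuity
    correction.  ``med`` is the median in-set correlation (or, behind the
    ``med_mode="median_difference"`` flag, in-set minus out-of-set median).
    """
    r = correlations.table["r"]
    in_mask = r.index.isin(geneset)
    r_in = r.values[in_mask]
    r_out = r.values[~in_mask]
    if len(r_in) == 0 or len(r_out) == 0:
        warnings.warn(f"set {set_name!r} untestable after prevalence filtering",
                      stacklevel=2)
        return FseaResult(set_name, correlations.measure, len(r_in), len(r_out),
                          np.nan, np.nan, np.nan, testable=False)
    pooled = np.concatenate([r_in, r_out])
    tie_free = len(np.unique(pooled)) == len(pooled)
    exact = tie_free and len(r_in) * len(r_out) <= EXACT_LIMIT
    res = mannwhitneyu(r_in, r_out, alternative="two-sided",
                       method="exact" if exact else "asymptotic")
    if med_mode == "in_set_median":
        med = float(np.median(r_in))
    elif med_mode == "median_difference":
        med = float(np.median(r_in) - np.median(r_out))
    else:
        raise ValueError(f"unknown med_mode {med_mode!r}")
    return FseaResult(set_name, correlations.measure, len(r_in), len(r_out),
                      float(res.statistic), float(res.pvalue), med, exact=exact)


def run_fsea(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    catalog: GeneSetCatalog,
    covariates: list[str],
    min_subjects: int = 4,
    fdr_threshold: float = 0.1,
    measures: tuple[str, ...] = ("score", "residual"),
    score_col: str = SCORE_COL,
    med_mode: str = "in_set_median",
) -> pd.DataFrame:
    """Full enrichment run: correlate, test every set, BH-FDR within measure.

    Returns one row per (set, measure), sorted by q within measure, with a
    ``significant`` flag at ``q < fdr_threshold``.  Untestable sets keep NaN
    statistics and are excluded from the FDR family.
    """
    frames = []
    for tag in measures:
        if tag == "score":
            measure = metadata[score_col].astype(float)
        elif tag == "residual":
            measure = residualize(metadata, covariates, score_col=score_col)
        else:
            raise ValueError(f"unknown measure {tag!r}")
        corr = correlate_features(table, measure, min_subjects=min_subjects,
                                  measure_tag=tag)
        results = [mwu_enrichment(corr, catalog.sets[name], name, med_mode)
                   for name in catalog.set_names]
        df = pd.DataFrame(
            [{"set": x.set_name, "measure": x.measure, "n_in": x.n_in,
              "n_out": x.n_out, "U": x.u_statistic, "med": x.med, "p": x.p,
              "testable": x.testable} for x in results]
        )
        ok = df["testable"].values
        df["q"] = np.nan
        if ok.any():
            df.loc[ok, "q"] = bh_fdr(df.loc[ok, "p"].values)
        df["significant"] = df["q"] < fdr_threshold
        frames.append(df.sort_values("q", na_position="last"))
    return pd.concat(frames, ignore_index=True)


def taxon_contribution(table: AbundanceTable, geneset: set[str]) -> pd.DataFrame:
    """Per-taxon share of the summed stratified abundance of in-set families.

    share(taxon) = sum over in-set families and samples of the taxon's
    stratified abundance, divided by the total stratified in-set abundance
    (including an ``unclassified`` remainder where strata undershoot the
    unstratified value).  Ranked descending, ties broken lexicographically.
    """
    if not table.stratified:
        warnings.warn("no stratified rows available", stacklevel=2)
        return pd.DataFrame(columns=["taxon", "share"]).set_index("taxon")
    totals: dict[str, float] = {}
    unclassified = 0.0
    found = False
    for fid in geneset:
        if fid not in (table.stratified or {}):
            continue
        found = True
        sub = table.stratified[fid]
        for taxon in sub.columns:
            totals[taxon] = totals.get(taxon, 0.0) + float(sub[taxon].sum())
        if fid in table.data.columns:
            gap = float(table.data[fid].reindex(sub.index).sum() - sub.values.sum())
            unclassified += max(gap, 0.0)
    if not found:
        warnings.warn("no stratified rows for this gene set", stacklevel=2)
        return pd.DataFrame(columns=["taxon", "share"]).set_index("taxon")
    if unclassified > 0:
        totals["unclassified"] = totals.get("unclassified", 0.0) + unclassified
    grand = sum(totals.values())
    df = pd.DataFrame(
        {"taxon": list(totals), "share": [v / grand for v in totals.values()]}
    )
    df = df.sort_values(["share", "taxon"], ascending=[False, True],
                        kind="stable").set_index("taxon")
    return df
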
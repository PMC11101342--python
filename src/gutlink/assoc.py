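"""Per-feature association models, sex-interaction tests, chained-equation
covariate imputation with Rubin pooling, and Benjamini-Hochberg FDR.

The screen mirrors the MaAsLin2 convention (log-transformed relative abundance
as the outcome, behavioral score plus covariates as predictors); species
passing the screen are then refit in the reverse direction so coefficients are
reported as score difference per doubling of relative abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from .community import RegressionResult, ols_table
from .profiles import COVARIATES, AbundanceTable

SCORE_COL = "srs2_tscore"


@dataclass
class FeatureScreenResult:
    table: pd.DataFrame  # index: feature; columns: beta, se, p, q
    transform: str
    min_prevalence: float
    n_dropped: int
    dropped: list[str] = field(default_factory=list)


@dataclass
class ImputedSet:
    copies: list[pd.DataFrame]
    n_iterations: int
    seed: int

    @property
    def m(self) -> int:
        return len(self.copies)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pseudocount(table: AbundanceTable) -> float:
    """Half the smallest nonzero relative abundance in the whole table."""
    vals = table.data.values
    nz = vals[vals > 0]
    if nz.size == 0:
        raise ValueError("table has no nonzero values")
    return float(nz.min() / 2.0)


def log2_abundance(values: np.ndarray, pc: float) -> np.ndarray:
    return np.log2(np.asarray(values, dtype=float) + pc)


def prevalence(table: AbundanceTable) -> pd.Series:
    """Fraction of samples in which each feature is nonzero."""
    return (table.data > 0).mean(axis=0)


def feature_screen(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    covariates: list[str] | None = None,
    min_prevalence: float = 0.1,
    score_col: str = SCORE_COL,
) -> FeatureScreenResult:
    """Abundance-as-outcome screen: per retained feature, OLS of
    log2(relative abundance + pseudocount) on score + covariates; BH q over
    retained features.  Features below the prevalence floor are dropped and
    counted.
    """
    covariates = list(covariates) if covariates is not None else []
    prev = prevalence(table)
    keep = prev[prev >= min_prevalence].index.tolist()
    dropped = [f for f in table.feature_ids if f not in set(keep)]
    if not keep:
        warnings.warn("no features pass the prevalence filter", stacklevel=2)
        empty = pd.DataFrame(columns=["beta", "se", "p", "q", "prevalence"])
        return FeatureScreenResult(empty, "log2(ra + pc)", min_prevalence,
                                   len(dropped), dropped)

    pc = pseudocount(table)
    md = metadata.loc[table.sample_ids] if set(table.sample_ids).issubset(
        set(metadata.index)) else metadata
    X = md[[score_col] + covariates].astype(float)
    rows = {}
    for f in keep:
        y = log2_abundance(table.data[f].values, pc)
        res = ols_table(y, X, model="log2(ra) ~ score + covariates")
        c = res.coef(score_col)
        rows[f] = {"beta": c.beta, "se": c.se, "p": c.p, "prevalence": prev[f]}
    out = pd.DataFrame(rows).T
    out["q"] = bh_fdr(out["p"].values)
    out = out[["beta", "se", "p", "q", "prevalence"]]
    return FeatureScreenResult(out, f"log2(ra + {pc:g})", min_prevalence,
                               len(dropped), dropped)


def reverse_regression(
    feature: pd.Series,
    metadata: pd.DataFrame,
    covariates: list[str] | None = None,
    pc: float | None = None,
    score_col: str = SCORE_COL,
) -> RegressionResult:
    """OLS of the score on log2(relative abundance + pseudocount) + covariates.

    The abundance coefficient is in score units per doubling of relative
    abundance.
    """
    covariates = list(covariates) if covariates is not None else []
    vals = feature.values.astype(float)
    if np.all(vals == vals[0]):
        raise ValueError("constant feature")
    if pc is None:
        nz = vals[vals > 0]
        pc = float(nz.min() / 2.0) if nz.size else 1e-9
    md = metadata.loc[feature.index] if set(feature.index).issubset(
        set(metadata.index)) else metadata
    X = pd.DataFrame({"log2_abundance": log2_abundance(vals, pc)})
    for c in covariates:
        X[c] = md[c].values
    return ols_table(md[score_col].values, X,
                     model="score ~ log2(ra) + covariates")


def interaction_model(
    feature: pd.Series,
    metadata: pd.DataFrame,
    covariates: list[str] | None = None,
    sex_col: str = "sex_male",
    pc: float | None = None,
    score_col: str = SCORE_COL,
) -> dict:
    """Sex-interaction test plus per-sex stratified fits.

    The full model adds a sex x log2-abundance product term; ``p_interaction``
    is the two-sided test of that coefficient.  Stratified models refit
    ``reverse_regression`` within each sex (sex dropped from the covariates).
    """
    covariates = [c for c in (covariates or []) if c != sex_col]
    md = metadata.loc[feature.index] if set(feature.index).issubset(
        set(metadata.index)) else metadata
    sex = md[sex_col].astype(float).values
    n_m, n_f = int((sex == 1).sum()), int((sex == 0).sum())
    if n_m < 10 or n_f < 10:
        raise ValueError(f"need >= 10 samples per sex (male={n_m}, female={n_f})")
    vals = feature.values.astype(float)
    if pc is None:
        nz = vals[vals > 0]
        pc = float(nz.min() / 2.0) if nz.size else 1e-9
    la = log2_abundance(vals, pc)
    X = pd.DataFrame({"log2_abundance": la, sex_col: sex,
                      "log2_abundance:sex": la * sex})
    for c in covariates:
        X[c] = md[c].values
    full = ols_table(md[score_col].values, X, model="score ~ log2(ra) * sex + covariates")
    p_int = float(full.coef("log2_abundance:sex").p)

    strat = {}
    for label, mask in (("male", sex == 1), ("female", sex == 0)):
        sub = pd.Series(vals[mask], index=feature.index[mask])
        strat[label] = reverse_regression(sub, md.loc[mask], covariates,
                                          pc=pc, score_col=score_col)
    return {"p_interaction": p_int, "full": full, "stratified": strat}


# ---------------------------------------------------------------------------
# chained-equation imputation (predictive-mean matching) + Rubin pooling


def _pmm_draw(pred_obs, y_obs, pred_mis, k, rng):
    """For each missing prediction, draw one of the k nearest observed donors."""
    order = np.argsort(pred_obs, kind="stable")
    po, yo = pred_obs[order], y_obs[order]
    out = np.empty(len(pred_mis))
    for i, pm in enumerate(pred_mis):
        j = np.searchsorted(po, pm)
        lo, hi = max(0, j - k), min(len(po), j + k)
        cand = np.argsort(np.abs(po[lo:hi] - pm), kind="stable")[:k]
        out[i] = yo[lo:hi][cand[rng.integers(len(cand))]]
    return out


def impute_covariates(
    metadata: pd.DataFrame,
    covariates: list[str] | None = None,
    m: int = 20,
    n_iterations: int = 10,
    k_donors: int = 5,
    seed: int = 0,
) -> ImputedSet:
    """Multiple imputation by chained equations.

    Continuous covariates are imputed by predictive mean matching against an
    OLS fit on all other covariates (donor pool ``k_donors``); binary
    covariates by matching on the logistic score, falling back to an
    observed-frequency draw when the logistic fit cannot converge.  Observed
    cells are identical across the ``m`` copies; only masked cells vary.
    """
    covariates = [c for c in (covariates or COVARIATES) if c in metadata.columns]
    base = metadata.copy()
    masks = {c: base[c].isna().values for c in covariates}
    need = [c for c in covariates if masks[c].any()]
    for c in covariates:
        if masks[c].all():
            raise ValueError(f"covariate {c!r} is 100% missing")
    binary = {c: set(base[c].dropna().unique()) <= {0, 1, 0.0, 1.0} for c in covariates}

    copies = []
    ss = np.random.SeedSequence([seed, 0x1A7])
    for child in ss.spawn(m):
        rng = np.random.default_rng(child)
        df = base.copy()
        # initial fill: random draws from the observed marginal
        for c in need:
            obs = df.loc[~masks[c], c].values
            df.loc[masks[c], c] = rng.choice(obs, size=masks[c].sum(), replace=True)
        for _ in range(n_iterations if need else 0):
            for c in need:
                others = [o for o in covariates if o != c]
                X = df[others].values.astype(float)
                X = np.column_stack([np.ones(len(X)), X])
                y = base[c].values.astype(float)
                obs, mis = ~masks[c], masks[c]
                if binary[c]:
                    yo = y[obs]
                    if len(np.unique(yo)) < 2:
                        df.loc[mis, c] = rng.choice(yo, size=mis.sum(), replace=True)
                        continue
                    try:
                        clf = LogisticRegression(max_iter=200, C=1e4)
                        clf.fit(X[obs], yo)
                        score_obs = clf.decision_function(X[obs])
                        score_mis = clf.decision_function(X[mis])
                        df.loc[mis, c] = _pmm_draw(score_obs, yo, score_mis,
                                                   k_donors, rng)
                    except Exception:  # non-convergence etc.
                        warnings.warn(
                            f"logistic fit failed for {c!r}; frequency draw",
                            stacklevel=2)
                        df.loc[mis, c] = rng.choice(yo, size=mis.sum(), replace=True)
                else:
                    coef, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
                    pred = X @ coef
                    df.loc[mis, c] = _pmm_draw(pred[obs], y[obs], pred[mis],
                                               k_donors, rng)
        copies.append(df)
    return ImputedSet(copies=copies, n_iterations=n_iterations, seed=seed)


def pool_rubin(estimates, variances) -> RegressionResult:
    """Rubin's rules across m imputed-data fits.

    pooled beta = mean of estimates; total variance = W + (1 + 1/m) B with W
    the mean within-imputation variance and B the between-imputation variance
    of the estimates.  CI by normal approximation.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    var = np.atleast_2d(np.asarray(variances, dtype=float))
    if est.shape != var.shape:
        raise ValueError("estimates and variances have mismatched shapes")
    m = est.shape[0]
    beta = est.mean(axis=0)
    w = var.mean(axis=0)
    b = est.var(axis=0, ddof=1) if m > 1 else np.zeros_like(beta)
    total = w + (1 + 1 / m) * b
    se = np.sqrt(total)
    from scipy.stats import norm

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2 * norm.sf(np.abs(z))
    terms = pd.DataFrame(
        {"beta": beta, "se": se, "ci_low": beta - 1.96 * se,
         "ci_high": beta + 1.96 * se, "p": p,
         "within_var": w, "between_var": b, "total_var": total},
    )
    return RegressionResult(terms=terms, n=m, model=f"rubin_pooled(m={m})")


def pooled_reverse_regression(
    feature: pd.Series,
    imputed: ImputedSet,
    covariates: list[str],
    pc: float | None = None,
    score_col: str = SCORE_COL,
) -> RegressionResult:
    """Reverse regression on each completed copy, pooled by Rubin's rules."""
    fits = [reverse_regression(feature, df, covariates, pc=pc, score_col=score_col)
            for df in imputed.copies]
    names = list(fits[0].terms.index)
    est = np.array([f.terms["beta"].values for f in fits])
    var = np.array([f.terms["se"].values ** 2 for f in fits])
    pooled = pool_rubin(est, var)
    pooled.terms.index = names
    pooled.n = fits[0].n
    pooled.model = f"rubin_pooled(m={imputed.m}): " + fits[0].model
    return pooled
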
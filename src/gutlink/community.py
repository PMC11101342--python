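"""Community-structure statistics: Bray-Curtis distances, alpha diversity,
marginal-SS PERMANOVA, and diversity-on-score regression.

The PERMANOVA follows the marginal (type-III-like) convention: each term's
sum of squares is what the full design explains beyond the design with that
term removed, computed on the Gower-centred inner-product matrix of squared
dissimilarities, with significance from free permutation of the metadata rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform

from .profiles import AbundanceTable


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def validate(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("nonzero diagonal")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("asymmetric distance matrix")


@dataclass
class PermanovaResult:
    terms: pd.DataFrame  # index: term; columns: df, SS, R2, F, p
    n_permutations: int
    seed: int
    n: int
    total_ss: float


@dataclass
class RegressionResult:
    """Coefficient table with normal-approximation 95% intervals."""

    terms: pd.DataFrame  # index: term; columns: beta, se, ci_low, ci_high, p
    n: int
    model: str = ""
    extra: dict = field(default_factory=dict)

    def coef(self, term: str) -> pd.Series:
        return self.terms.loc[term]


def _normal_ci(beta: np.ndarray, se: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return beta - 1.96 * se, beta + 1.96 * se


def ols_table(y: np.ndarray, X: pd.DataFrame, model: str = "", extra: dict | None = None,
              ) -> RegressionResult:
    """OLS with intercept prepended; coefficient table with +-1.96*SE intervals."""
    Xd = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(Xd.values) < Xd.shape[1]:
        raise ValueError(f"rank-deficient design; columns: {list(Xd.columns)}")
    fit = sm.OLS(np.asarray(y, dtype=float), Xd).fit()
    lo, hi = _normal_ci(fit.params.values, fit.bse.values)
    terms = pd.DataFrame(
        {"beta": fit.params.values, "se": fit.bse.values,
         "ci_low": lo, "ci_high": hi, "p": fit.pvalues.values},
        index=list(Xd.columns),
    )
    res = RegressionResult(terms=terms, n=int(fit.nobs), model=model, extra=extra or {})
    res.extra.setdefault("r_squared", float(fit.rsquared))
    res.extra.setdefault("resid", fit.resid)
    return res


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y).

    A pair of all-zero samples has an undefined quotient; it is reported as 0
    with a warning (the samples are identical in the trivial sense).
    """
    X = table.data.values.astype(float)
    if (X < 0).any():
        raise ValueError("negative abundance value")
    with np.errstate(invalid="ignore"):
        d = pdist(X, metric="braycurtis")
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair(s): distance set to 0", stacklevel=2)
        d = np.nan_to_num(d, nan=0.0)
    dm = DistanceMatrix(sample_ids=table.sample_ids, values=squareform(d))
    dm.validate()
    return dm


def alpha_diversity(sample: np.ndarray, index: str = "shannon") -> float:
    """Shannon entropy (natural log) or inverse Simpson of one profile.

    The vector is renormalised to proportions; zero entries contribute nothing
    to Shannon.  An all-zero vector has no defined diversity and returns NaN.
    """
    p = np.asarray(sample, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundance value")
    total = p.sum()
    if total == 0:
        warnings.warn("all-zero sample: diversity undefined", stacklevel=2)
        return float("nan")
    p = p / total
    nz = p[p > 0]
    if index == "shannon":
        return float(-(nz * np.log(nz)).sum())
    if index == "inverse_simpson":
        return float(1.0 / (nz**2).sum())
    raise ValueError(f"unknown diversity index {index!r}")


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    # projection onto col(X) via pseudoinverse; tolerant of dummy coding
    return x @ np.linalg.pinv(x)


def _design(metadata: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Numeric design matrix (with intercept) and per-term column indices."""
    cols: list[np.ndarray] = [np.ones(len(metadata))]
    owner: dict[str, list[int]] = {}
    for t in terms:
        v = metadata[t]
        if v.isna().any():
            raise ValueError(f"term {t!r} has missing values; impute or drop upstream")
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(v, drop_first=True).astype(float)
            idx = []
            for c in dummies.columns:
                idx.append(len(cols))
                cols.append(dummies[c].values)
            owner[t] = idx
        else:
            owner[t] = [len(cols)]
            cols.append(v.values.astype(float))
    return np.column_stack(cols), owner


def permanova_marginal(
    dist: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str],
    n_permutations: int = 9999,
    seed: int = 0,
) -> PermanovaResult:
    """Marginal-SS PERMANOVA of a distance matrix on a multi-term design.

    For each term, SS = tr(H_full G) - tr(H_reduced G) where G is the
    Gower-centred matrix of squared distances and H are hat matrices of the
    full design and the design with the term dropped.  R^2 = SS / tr(G);
    pseudo-F = (SS/df_term) / (SS_resid/df_resid).  p-values use the add-one
    permutation estimator under free row permutation.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    if set(dist.sample_ids).issubset(set(metadata.index)):
        md = metadata.loc[dist.sample_ids]
    else:
        md = metadata
    if len(md) != len(dist.sample_ids):
        raise ValueError("metadata and distance matrix sample counts differ")

    X, owner = _design(md, terms)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"fewer samples ({n}) than design parameters ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"rank-deficient design; collinear among terms {terms}")

    G = _gower_center(dist.values)
    total_ss = float(np.trace(G))
    H_full = _hat(X)
    df_resid = n - p
    R = np.eye(n) - H_full  # residual projector

    term_M: dict[str, np.ndarray] = {}
    term_df: dict[str, int] = {}
    for t in terms:
        keep = [j for j in range(p) if j not in owner[t]]
        H_red = _hat(X[:, keep])
        term_M[t] = H_full - H_red
        term_df[t] = len(owner[t])

    ss_obs = {t: float(np.sum(term_M[t] * G)) for t in terms}
    ss_resid = float(np.sum(R * G))
    f_obs = {
        t: (ss_obs[t] / term_df[t]) / (ss_resid / df_resid) for t in terms
    }

    rng = np.random.default_rng(seed)
    exceed = {t: 0 for t in terms}
    chunk = max(1, min(256, n_permutations))
    done = 0
    while done < n_permutations:
        k = min(chunk, n_permutations - done)
        perms = np.array([rng.permutation(n) for _ in range(k)])
        Gp = G[perms[:, :, None], perms[:, None, :]]  # (k, n, n)
        ssr_p = np.einsum("ij,kij->k", R, Gp)
        for t in terms:
            ss_p = np.einsum("ij,kij->k", term_M[t], Gp)
            f_p = (ss_p / term_df[t]) / (ssr_p / df_resid)
            exceed[t] += int(np.sum(f_p >= f_obs[t]))
        done += k

    rows = {
        t: {
            "df": term_df[t],
            "SS": ss_obs[t],
            "R2": ss_obs[t] / total_ss if total_ss > 0 else np.nan,
            "F": f_obs[t],
            "p": (1 + exceed[t]) / (1 + n_permutations),
        }
        for t in terms
    }
    rows["residual"] = {"df": df_resid, "SS": ss_resid,
                        "R2": ss_resid / total_ss if total_ss > 0 else np.nan,
                        "F": np.nan, "p": np.nan}
    return PermanovaResult(
        terms=pd.DataFrame(rows).T,
        n_permutations=n_permutations,
        seed=seed,
        n=n,
        total_ss=total_ss,
    )


def diversity_regression(
    diversity: pd.Series,
    metadata: pd.DataFrame,
    covariates: list[str] | None = None,
    score_col: str = "srs2_tscore",
) -> RegressionResult:
    """OLS of the behavioral score on z-standardised diversity plus covariates.

    The reported coefficient is the score difference per one-SD increase in
    diversity.
    """
    covariates = covariates or []
    div = diversity.astype(float)
    sd = div.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("zero-variance diversity")
    X = pd.DataFrame({"diversity_sd": (div - div.mean()) / sd})
    for c in covariates:
        X[c] = metadata[c].values
    y = metadata[score_col].values
    return ols_table(y, X, model="score ~ z(diversity) + covariates")
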
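"""Cross-cohort transfer prediction and fecal-metabolite regressions.

A score model fit on one cohort (log2-transformed shared species plus
covariates) is applied unchanged to the other cohort, and predictions are
scored by Pearson correlation, RMSE and MAE against the observed scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.linear_model import RidgeCV
from sklearn.model_selection import KFold

from .assoc import SCORE_COL, log2_abundance
from .community import RegressionResult, ols_table
from .profiles import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class TransferModel:
    features: list[str]
    covariates: list[str]
    coef: pd.Series  # index: const + log2 features + covariates
    pseudocount: float
    train_cohort: str
    transform: str = "log2(ra + pc)"
    method: str = "ols"


@dataclass
class PredictionEval:
    pearson_r: float
    rmse: float
    mae: float
    n: int


def shared_features(
    train_table: AbundanceTable,
    test_table: AbundanceTable | None,
    min_shared_prevalence: float = 0.1,
) -> tuple[list[str], pd.DataFrame]:
    """Features above the prevalence floor in the training table and, when a
    test table is supplied, in both cohorts.  Also returns the per-cohort
    prevalence table for reporting non-shared features."""
    prev_train = (train_table.data > 0).mean(axis=0)
    report = pd.DataFrame({"prevalence_train": prev_train})
    keep = prev_train >= min_shared_prevalence
    if test_table is not None:
        prev_test = (test_table.data > 0).mean(axis=0)
        report["prevalence_test"] = prev_test.reindex(prev_train.index).fillna(0.0)
        keep = keep & (report["prevalence_test"] >= min_shared_prevalence)
    return list(prev_train.index[keep]), report


def fit_transfer_model(
    train_table: AbundanceTable,
    train_metadata: pd.DataFrame,
    covariates: list[str],
    test_table: AbundanceTable | None = None,
    min_shared_prevalence: float = 0.1,
    train_cohort: str = "train",
    seed: int = 0,
    score_col: str = SCORE_COL,
) -> TransferModel:
    """OLS of the score on log2 shared features + covariates.

    When the feature count reaches the sample count, a ridge fit with the
    penalty chosen by seeded 5-fold cross-validation replaces plain OLS.
    """
    feats, report = shared_features(train_table, test_table, min_shared_prevalence)
    if not feats:
        raise ValueError(
            "no shared features above prevalence "
            f"{min_shared_prevalence}; per-cohort prevalences:\n{report}"
        )
    md = train_metadata.loc[train_table.sample_ids] if set(
        train_table.sample_ids).issubset(set(train_metadata.index)) else train_metadata
    vals = train_table.data[feats].values
    nz = vals[vals > 0]
    pc = float(nz.min() / 2.0) if nz.size else 1e-9
    X = pd.DataFrame(log2_abundance(vals, pc), index=train_table.sample_ids,
                     columns=feats)
    for c in covariates:
        X[c] = md[c].values
    y = md[score_col].values.astype(float)

    if X.shape[1] + 1 >= len(y):
        logger.info("p >= n (%d features, %d samples): ridge fallback",
                    X.shape[1], len(y))
        cv = KFold(n_splits=5, shuffle=True, random_state=seed)
        ridge = RidgeCV(alphas=np.logspace(-2, 4, 13), cv=cv)
        ridge.fit(X.values, y)
        coef = pd.Series(np.concatenate([[ridge.intercept_], ridge.coef_]),
                         index=["const"] + list(X.columns))
        method = f"ridge(alpha={ridge.alpha_:g})"
    else:
        res = ols_table(y, X, model="score ~ log2(shared features) + covariates")
        coef = res.terms["beta"]
        method = "ols"
    return TransferModel(features=feats, covariates=list(covariates), coef=coef,
                         pseudocount=pc, train_cohort=train_cohort, method=method)


def predict_scores(
    model: TransferModel,
    test_table: AbundanceTable,
    test_metadata: pd.DataFrame,
) -> pd.Series:
    """Deterministic linear prediction on the model's transform.

    Model features absent from the test table are imputed as zero abundance
    (counted and warned); covariates must be present and complete.
    """
    md = test_metadata.loc[test_table.sample_ids] if set(
        test_table.sample_ids).issubset(set(test_metadata.index)) else test_metadata
    missing_feats = [f for f in model.features if f not in test_table.data.columns]
    if missing_feats:
        warnings.warn(
            f"{len(missing_feats)} model feature(s) absent from the test table; "
            "imputed as zero abundance", stacklevel=2)
    for c in model.covariates:
        if c not in md.columns or md[c].isna().any():
            raise ValueError(f"covariate {c!r} missing or incomplete in test metadata")
    X = pd.DataFrame(index=test_table.sample_ids)
    for f in model.features:
        vals = (test_table.data[f].values if f in test_table.data.columns
                else np.zeros(test_table.n_samples))
        X[f] = log2_abundance(vals, model.pseudocount)
    for c in model.covariates:
        X[c] = md[c].values.astype(float)
    pred = model.coef["const"] + X.values @ model.coef[list(X.columns)].values
    return pd.Series(pred, index=test_table.sample_ids, name="predicted_score")


def evaluate_predictions(pred: pd.Series, observed: pd.Series) -> PredictionEval:
    """Pearson r, RMSE and MAE between predicted and observed scores."""
    obs = observed.reindex(pred.index)
    if obs.isna().any():
        raise ValueError("observed scores missing for some predictions")
    p, o = pred.values.astype(float), obs.values.astype(float)
    if len(p) < 3:
        raise ValueError("need at least 3 observations")
    err = p - o
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.std(p) == 0 or np.std(o) == 0:
        warnings.warn("constant predictions or observations: r undefined",
                      stacklevel=2)
        r = float("nan")
    else:
        r = float(pearsonr(p, o).statistic)
    return PredictionEval(pearson_r=r, rmse=rmse, mae=mae, n=len(p))


def metabolite_regression(
    concentrations: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: list[str] | None = None,
    adjusted: bool = False,
    score_col: str = SCORE_COL,
) -> dict[str, RegressionResult]:
    """Per-metabolite OLS of the score on log2 relative concentration.

    Relative concentrations must be strictly positive (no pseudocount).  The
    adjusted model adds the full covariate set; coefficients are in score
    units per doubling of concentration.
    """
    if (concentrations.values <= 0).any():
        raise ValueError("non-positive relative concentration")
    covs = list(covariates or []) if adjusted else []
    md = metadata.loc[concentrations.index] if set(concentrations.index).issubset(
        set(metadata.index)) else metadata
    out = {}
    for m in concentrations.columns:
        X = pd.DataFrame({"log2_concentration": np.log2(concentrations[m].values)})
        for c in covs:
            X[c] = md[c].values
        out[m] = ols_table(
            md[score_col].values, X,
            model=f"score ~ log2({m})" + (" + covariates" if adjusted else ""))
    return out
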
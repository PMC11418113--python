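"""LASSO-Cox prognostic modelling and survival comparison.

The overall survival score (OSS) of a sample is a linear combination of gene
expressions with coefficients selected by L1-penalized Cox regression; higher
OSS means higher risk. The published ten-gene ovarian-cancer model is shipped
verbatim; ``fit_lasso_cox`` refits the same construction on new data, picking
the penalty by cross-validated partial-likelihood deviance with the 1-SE
rule. Stratification at the training-median OSS defines high/low risk groups
compared by the log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .matrix import ExpressionMatrix, ValidationError

#: the published ten-gene OSS model (three risk genes, seven protective)
PUBLISHED_COEFFICIENTS: Dict[str, float] = {
    "MFAP4": 0.0166,
    "FBLN2": 0.1858,
    "IGF2": 0.0227,
    "NME5": -0.0034,
    "MGLL": -0.1435,
    "COLEC11": -0.0101,
    "AGR2": -0.0415,
    "TFF3": -0.0453,
    "PAEP": -0.0199,
    "DEFB1": -0.0275,
}


@dataclass
class RiskModel:
    genes: List[str]
    coefficients: np.ndarray
    cutpoint: float = 0.0
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.genes) != len(self.coefficients):
            raise ValidationError("genes and coefficients differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene names in model")
        if (self.coefficients == 0).any():
            raise ValidationError("zero coefficients must not be stored")

    def as_series(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.genes)


def published_model() -> RiskModel:
    """The published ten-gene OSS model with its printed coefficients."""
    genes = list(PUBLISHED_COEFFICIENTS)
    coefs = np.array([PUBLISHED_COEFFICIENTS[g] for g in genes])
    return RiskModel(genes=genes, coefficients=coefs, cutpoint=0.0,
                     provenance="published")


def validate_survival(survival: pd.DataFrame) -> pd.DataFrame:
    """Check a survival table (index: sample; columns: time, event)."""
    if not {"time", "event"} <= set(survival.columns):
        raise ValidationError("survival table needs 'time' and 'event' columns")
    if (survival["time"] <= 0).any():
        raise ValidationError("survival times must be positive")
    if not survival["event"].isin([0, 1]).all():
        raise ValidationError("event indicator must be 0 or 1")
    return survival


def oss_score(model: RiskModel, matrix: ExpressionMatrix | pd.DataFrame) -> pd.Series:
    """OSS per sample: sum over model genes of coefficient x expression."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    missing = [g for g in model.genes if g not in values.index]
    if missing:
        raise ValidationError(f"model genes absent from matrix: {missing}")
    X = values.loc[model.genes].to_numpy()
    return pd.Series(model.coefficients @ X, index=values.columns, name="OSS")


def stratify(scores: pd.Series, cutpoint: float) -> pd.Series:
    """High/low risk labels: high iff OSS > cutpoint."""
    labels = pd.Series(
        np.where(scores > cutpoint, "high", "low"), index=scores.index
    )
    if labels.nunique() == 1:
        warnings.warn(
            f"all samples fall in the {labels.iloc[0]!r} group at cutpoint {cutpoint}",
            stacklevel=2,
        )
    return labels


def logrank_test(groups: pd.Series, survival: pd.DataFrame) -> Tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square statistic, p-value)."""
    validate_survival(survival)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValidationError(f"exactly two nonempty groups required, got {levels}")
    a = groups.index[groups == levels[0]]
    b = groups.index[groups == levels[1]]
    res = _lifelines_logrank(
        survival.loc[a, "time"], survival.loc[b, "time"],
        event_observed_A=survival.loc[a, "event"],
        event_observed_B=survival.loc[b, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


def _cv_deviance(X, y, alphas, cv_folds, seed) -> Tuple[np.ndarray, np.ndarray]:
    """Mean and SE over folds of the CV partial-likelihood deviance path."""
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_dev = []
    for train_idx, test_idx in kf.split(X):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=alphas, fit_baseline_model=False,
            normalize=False, max_iter=100000,
        )
        model.fit(X[train_idx], y[train_idx])
        # the solver may truncate the path; align fitted alphas to the grid
        devs = np.full(len(alphas), np.nan)
        fitted = {float(a): i for i, a in enumerate(model.alphas_)}
        for j, a in enumerate(alphas):
            i = fitted.get(float(a))
            if i is not None:
                devs[j] = -2 * _log_partial_likelihood(
                    X[test_idx], y[test_idx], model.coef_[:, i]
                )
        fold_dev.append(devs)
    fold_dev = np.asarray(fold_dev)
    # only compare alphas evaluated in every fold
    complete = np.isfinite(fold_dev).all(axis=0)
    mean = np.full(fold_dev.shape[1], np.inf)
    se = np.zeros(fold_dev.shape[1])
    mean[complete] = fold_dev[:, complete].mean(axis=0)
    se[complete] = fold_dev[:, complete].std(axis=0, ddof=1) / np.sqrt(cv_folds)
    return mean, se


def _log_partial_likelihood(X, y, coef) -> float:
    """Breslow log partial likelihood of a linear predictor."""
    eta = X @ coef
    time = np.asarray(y["time"], dtype=float)
    event = np.asarray(y["event"], dtype=bool)
    order = np.argsort(time, kind="stable")
    eta, time, event = eta[order], time[order], event[order]
    shift = eta.max()
    rev_cumsum = np.cumsum(np.exp(eta - shift)[::-1])[::-1]
    ll = 0.0
    i, n = 0, len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d = int(event[i:j].sum())
        if d > 0:
            # log-sum-exp over the risk set {i..n-1}, shift cancels per event
            ll += eta[i:j][event[i:j]].sum() - d * (np.log(rev_cumsum[i]) + shift)
        i = j
    return ll


def fit_lasso_cox(
    matrix: ExpressionMatrix,
    survival: pd.DataFrame,
    candidate_genes: Sequence[str],
    cv_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    alpha: float | None = None,
    rule: str = "1se",
) -> RiskModel:
    """L1-penalized Cox model over candidate genes.

    The penalty path comes from a full-data fit; the penalty is chosen by
    ``cv_folds``-fold cross-validated partial-likelihood deviance with the
    1-SE rule (largest penalty within one SE of the minimum; ``rule="min"``
    takes the minimum-deviance penalty instead), overridable via ``alpha``. Expression is z-scaled per gene inside the fit by default and
    coefficients are reported back on the original scale. The training
    cutpoint is the median OSS over training samples.
    """
    validate_survival(survival)
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    missing = [g for g in candidate_genes if g not in values.index]
    if missing:
        raise ValidationError(f"candidate genes absent: {missing[:5]}")
    common = survival.index.intersection(values.columns)
    if len(common) < 30 or survival.loc[common, "event"].sum() < 10:
        raise ValidationError(
            "need >= 30 samples with >= 10 events for a stable LASSO-Cox fit"
        )
    X = values.loc[list(candidate_genes), common].to_numpy().T
    if survival.loc[common, "event"].sum() == 0:
        raise ValidationError("no events in survival data")
    sd = X.std(axis=0, ddof=1)
    mu = X.mean(axis=0)
    if standardize:
        safe_sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - mu) / safe_sd
    else:
        safe_sd = np.ones_like(sd)
        Xs = X
    y = Surv.from_arrays(
        event=survival.loc[common, "event"].astype(bool).to_numpy(),
        time=survival.loc[common, "time"].to_numpy(),
    )

    path_model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=50, fit_baseline_model=False, normalize=False,
        max_iter=100000,
    )
    path_model.fit(Xs, y)
    alphas = np.asarray(path_model.alphas_)

    if alpha is None:
        mean_dev, se_dev = _cv_deviance(Xs, y, alphas, cv_folds, seed)
        best = int(np.nanargmin(mean_dev))
        if rule == "min":
            chosen = best
        else:
            limit = mean_dev[best] + se_dev[best]
            # alphas are decreasing: the largest alpha within 1 SE is the
            # earliest index meeting the limit
            chosen = next(i for i in range(len(alphas)) if mean_dev[i] <= limit)
        alpha = float(alphas[chosen])

    final = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=[alpha], fit_baseline_model=False, normalize=False,
        max_iter=100000,
    )
    final.fit(Xs, y)
    coef_std = final.coef_[:, 0]
    nz = coef_std != 0
    if not nz.any():
        raise ValidationError(
            "all coefficients zero at the chosen penalty; use a smaller alpha"
        )
    coef_orig = coef_std / safe_sd  # back to the original expression scale
    genes = [g for g, keep in zip(candidate_genes, nz) if keep]
    model = RiskModel(genes=genes, coefficients=coef_orig[nz], provenance="fitted")
    scores = oss_score(model, values.loc[:, common])
    model.cutpoint = float(scores.median())
    return model
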
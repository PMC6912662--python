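"""Logistic AF classifier: fit, ROC threshold selection, K-fold validation.

The model is a plain maximum-likelihood logistic regression of the window
label (AF = 1) on the covariate vector, with Wald standard errors and
p-values from the observed information matrix — no regularisation.

The decision threshold tau is chosen on a 1001-point grid (0 to 1 in steps
of 0.001) as the point of the empirical ROC curve closest to the ideal
corner (FPR, Se) = (0, 1):

    tau = argmin_tau { FPR_tau^2 + (1 - Se_tau)^2 }

with the classification rule "AF iff predicted probability > tau" (strict).
Robustness is assessed by stratified K-fold cross-validation (K = 10 by
default): the model is fit and tau selected on the training folds only, then
Se, Sp and ACC are measured on the held-out fold, and the quartiles
(P25 / median / P75) of the per-fold metrics are reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import GroupKFold, StratifiedKFold

from . import __version__ as _pkg_version
from .features import AF, FEATURE_COLUMNS

__all__ = [
    "FittedModel",
    "RocResult",
    "EvalReport",
    "CVSummary",
    "fit_logistic",
    "predict_proba",
    "roc_threshold",
    "evaluate",
    "kfold_cv",
    "save_model",
    "load_model",
]

TAU_GRID = np.arange(1001) / 1000.0


def _labels01(labels: np.ndarray | pd.Series) -> np.ndarray:
    return (np.asarray(labels) == AF).astype(float)


@dataclass
class FittedModel:
    """Logistic coefficients with Wald inference."""

    covariate_names: list[str]
    coefficients: np.ndarray  # intercept first
    standard_errors: np.ndarray
    wald_p_values: np.ndarray
    converged: bool
    n_obs: int
    dropped_covariates: list[str] = field(default_factory=list)

    def significance_stars(self) -> list[str]:
        """'**' at 1%, '*' at 5%, '' otherwise, per coefficient."""
        return [
            "**" if p < 0.01 else "*" if p < 0.05 else "" for p in self.wald_p_values
        ]


@dataclass
class RocResult:
    grid_tau: np.ndarray
    grid_fpr: np.ndarray
    grid_se: np.ndarray
    chosen_tau: float


@dataclass
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    tau: float

    @property
    def se(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def sp(self) -> float:
        return 1.0 - (self.fp / (self.tn + self.fp)) if self.tn + self.fp else 0.0

    @property
    def acc(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else 0.0


@dataclass
class CVSummary:
    k: int
    per_fold: list[EvalReport]
    quartiles: pd.DataFrame  # index: tau/se/sp/acc; columns: p25/median/p75

    @property
    def median_acc(self) -> float:
        return float(self.quartiles.loc["acc", "median"])


def fit_logistic(
    features: pd.DataFrame, covariates: list[str] | None = None
) -> FittedModel:
    """Maximum-likelihood logistic fit of label ~ covariates.

    Newton scoring (tolerance 1e-8, at most 100 iterations); zero-variance
    covariates are dropped with a warning.  Under perfect separation the
    Newton step breaks down, so the fit falls back to L-BFGS and the model
    is flagged non-converged, keeping the last-iterate coefficients.
    """
    covariates = list(covariates or FEATURE_COLUMNS)
    y = _labels01(features["label"].to_numpy())
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the model")
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 rows per class")
    X = features[covariates].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    dropped = [c for c, k in zip(covariates, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance covariates: {dropped}")
        covariates = [c for c, k in zip(covariates, keep) if k]
        X = X[:, keep]
    # Standardize for the optimizer (covariate scales span ms to unit
    # fractions); this is an exact affine reparametrization, undone below.
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Z = sm.add_constant((X - mu) / sd, has_constant="add")
    model = sm.Logit(y, Z)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
            converged = bool(res.mle_retvals.get("converged", False))
        except np.linalg.LinAlgError:
            # Newton's step is undefined once the Hessian is singular (the
            # typical symptom of perfect separation); BFGS still yields a
            # usable separating iterate.
            res = model.fit(method="bfgs", maxiter=200, disp=0)
            converged = False
        separation = any("erfect separation" in str(w.message) for w in caught)
    if separation:
        warnings.warn(
            "perfect separation detected; coefficients are not identified "
            "(model flagged non-converged)"
        )
        converged = False
    # Undo the standardization: beta_i = a_i/sd_i, beta_0 = a_0 - sum a_i mu_i/sd_i.
    p = len(covariates)
    T = np.zeros((p + 1, p + 1))
    T[0, 0] = 1.0
    T[0, 1:] = -mu / sd
    T[np.arange(1, p + 1), np.arange(1, p + 1)] = 1.0 / sd
    coefficients = T @ np.asarray(res.params, dtype=float)
    try:
        cov = T @ np.asarray(res.cov_params(), dtype=float) @ T.T
        with np.errstate(invalid="ignore"):
            bse = np.sqrt(np.diag(cov))
    except (np.linalg.LinAlgError, ValueError):
        bse = np.full(p + 1, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = coefficients / bse
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    return FittedModel(
        covariate_names=covariates,
        coefficients=coefficients,
        standard_errors=bse,
        wald_p_values=pvals,
        converged=converged,
        n_obs=int(len(y)),
        dropped_covariates=dropped,
    )


def predict_proba(model: FittedModel, features: pd.DataFrame) -> np.ndarray:
    """P(AF) = logistic(beta0 + sum_i beta_i x_i) per row."""
    missing = [c for c in model.covariate_names if c not in features.columns]
    if missing:
        raise ValueError(f"features missing model covariates: {missing}")
    X = features[model.covariate_names].to_numpy(dtype=float)
    eta = model.coefficients[0] + X @ model.coefficients[1:]
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def roc_threshold(
    probs: np.ndarray, labels: np.ndarray | pd.Series
) -> RocResult:
    """ROC grid over tau in {0, 0.001, ..., 1} and the corner-closest tau.

    The chosen tau minimises FPR^2 + (1 - Se)^2; ties resolve to the
    smallest grid value.
    """
    probs = np.asarray(probs, dtype=float)
    y = _labels01(labels)
    pos, neg = y.sum(), (1 - y).sum()
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    pred = probs[None, :] > TAU_GRID[:, None]  # (1001, n)
    se = (pred & (y == 1)).sum(axis=1) / pos
    fpr = (pred & (y == 0)).sum(axis=1) / neg
    dist2 = fpr**2 + (1.0 - se) ** 2
    best = int(np.argmin(dist2))  # argmin returns the first (smallest tau)
    return RocResult(
        grid_tau=TAU_GRID.copy(),
        grid_fpr=fpr,
        grid_se=se,
        chosen_tau=float(TAU_GRID[best]),
    )


def evaluate(
    probs: np.ndarray, labels: np.ndarray | pd.Series, tau: float
) -> EvalReport:
    """Confusion counts and Se/Sp/ACC at threshold tau (rule p > tau)."""
    probs = np.asarray(probs, dtype=float)
    y = _labels01(labels).astype(bool)
    pred = probs > tau
    return EvalReport(
        tp=int((pred & y).sum()),
        tn=int((~pred & ~y).sum()),
        fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()),
        tau=float(tau),
    )


def _quartiles(per_fold: list[EvalReport]) -> pd.DataFrame:
    rows = {
        "tau": [r.tau for r in per_fold],
        "se": [r.se for r in per_fold],
        "sp": [r.sp for r in per_fold],
        "acc": [r.acc for r in per_fold],
    }
    return pd.DataFrame(
        {
            "p25": {k: np.percentile(v, 25) for k, v in rows.items()},
            "median": {k: np.percentile(v, 50) for k, v in rows.items()},
            "p75": {k: np.percentile(v, 75) for k, v in rows.items()},
        }
    )


def kfold_cv(
    features: pd.DataFrame,
    k: int = 10,
    seed: int | None = 0,
    covariates: list[str] | None = None,
    group_by_record: bool = False,
) -> CVSummary:
    """Stratified K-fold cross-validation of the full fit/threshold/evaluate
    pipeline.

    For each fold the model is fit and tau chosen on the other k-1 folds;
    Se, Sp and ACC are then measured on the held-out fold.  Set
    ``group_by_record=True`` to keep all windows of a record in the same
    fold (grouped rather than stratified splitting).
    """
    y = _labels01(features["label"].to_numpy())
    counts = [int((1 - y).sum()), int(y.sum())]
    if min(counts) < k:
        raise ValueError(
            f"each class needs at least k={k} rows; class counts are {counts}"
        )
    if group_by_record:
        splitter = GroupKFold(n_splits=k)
        splits = splitter.split(features, y, groups=features["record_id"])
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(features, y)
    per_fold = []
    for train_idx, test_idx in splits:
        train = features.iloc[train_idx]
        test = features.iloc[test_idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_logistic(train, covariates=covariates)
        tau = roc_threshold(
            predict_proba(model, train), train["label"].to_numpy()
        ).chosen_tau
        per_fold.append(
            evaluate(predict_proba(model, test), test["label"].to_numpy(), tau)
        )
    return CVSummary(k=k, per_fold=per_fold, quartiles=_quartiles(per_fold))


def save_model(model: FittedModel, tau: float | None, spec: dict, path: str | Path) -> None:
    """Serialize a fitted model (plus chosen threshold and window spec) to JSON."""
    doc = {
        "library_version": _pkg_version,
        "covariate_names": model.covariate_names,
        "coefficients": model.coefficients.tolist(),
        "standard_errors": model.standard_errors.tolist(),
        "wald_p_values": model.wald_p_values.tolist(),
        "converged": model.converged,
        "n_obs": model.n_obs,
        "dropped_covariates": model.dropped_covariates,
        "tau": tau,
        "spec": spec,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_model(path: str | Path) -> tuple[FittedModel, float | None, dict]:
    doc = json.loads(Path(path).read_text())
    model = FittedModel(
        covariate_names=list(doc["covariate_names"]),
        coefficients=np.asarray(doc["coefficients"], dtype=float),
        standard_errors=np.asarray(doc["standard_errors"], dtype=float),
        wald_p_values=np.asarray(doc["wald_p_values"], dtype=float),
        converged=bool(doc["converged"]),
        n_obs=int(doc["n_obs"]),
        dropped_covariates=list(doc.get("dropped_covariates", [])),
    )
    return model, doc.get("tau"), doc.get("spec", {})
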
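"""Feature-selecting models for the impairment outcomes.

Numeric outcomes (strength, sensation) use the LASSO fit by least-angle
regression (LARS): the full regularization path is computed, the penalty is
chosen by 10-fold block cross-validation (participants shuffled once, then
split into contiguous blocks), and the final model is a penalized refit at
the chosen penalty on all samples (an unpenalized least-squares refit on the
selected columns is also reported). The categorical outcome (spasticity)
uses multinomial (softmax) logistic regression with an L1 penalty, with the
penalty chosen by cross-validated accuracy (ties resolved toward the
stronger penalty); per-class selected features are the nonzero entries of
that class's coefficient vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoLars, LinearRegression, LogisticRegression, lars_path

from .errors import ConfigurationError, ValidationError

FEATURE_SET_LABELS = ("la_only", "covariates_only", "covariates_plus_la")


def block_cv_folds(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold assignment: shuffle once by seed, split into k contiguous blocks.

    Returns an integer array of length ``n`` with fold labels 0..k-1; block
    sizes differ by at most one.
    """
    if n < k:
        raise ConfigurationError(f"need at least k={k} samples, got n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    folds = np.empty(n, dtype=int)
    start = 0
    for fold, size in enumerate(sizes):
        folds[order[start : start + size]] = fold
        start += size
    return folds


@dataclass
class SelectionResult:
    """Outcome of penalty selection + final fit for one model."""

    outcome: str
    feature_set: str
    model_kind: str  # "lasso_lars" or "l1_multinomial"
    feature_names: list
    alpha: float
    folds: np.ndarray
    coefficients: np.ndarray  # (p,) regression; (k, p) classification
    intercept: np.ndarray
    selected: list  # flat list (regression) or dict class -> list
    cv_score: float
    classes: list = field(default_factory=list)
    ols_refit_coefficients: np.ndarray | None = None
    ols_refit_intercept: float | None = None

    @property
    def n_selected(self):
        if isinstance(self.selected, dict):
            return {c: len(v) for c, v in self.selected.items()}
        return len(self.selected)

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self.model_kind == "lasso_lars":
            return X @ self.coefficients + self.intercept[0]
        scores = X @ self.coefficients.T + self.intercept
        return np.asarray(self.classes)[np.argmax(scores, axis=1)]

    def to_dict(self) -> dict:
        d = {
            "outcome": self.outcome,
            "feature_set": self.feature_set,
            "model_kind": self.model_kind,
            "alpha": self.alpha,
            "cv_score": self.cv_score,
            "folds": self.folds.tolist(),
            "feature_names": list(self.feature_names),
            "coefficients": np.asarray(self.coefficients).tolist(),
            "intercept": np.asarray(self.intercept).tolist(),
            "selected": self.selected if isinstance(self.selected, dict) else list(self.selected),
        }
        if self.classes:
            d["classes"] = list(self.classes)
        return d


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def select_features_lasso_lars(
    X, y, folds: np.ndarray, outcome: str = "y", feature_set: str = "la_only"
) -> SelectionResult:
    """LASSO-LARS with block-CV penalty choice and all-sample final fit."""
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if np.any(np.isnan(Xm)) or np.any(np.isnan(y)):
        raise ValidationError("modeling inputs must be imputed (no NaN)")
    n, p = Xm.shape

    if np.ptp(y) == 0:
        return SelectionResult(
            outcome=outcome,
            feature_set=feature_set,
            model_kind="lasso_lars",
            feature_names=names,
            alpha=np.inf,
            folds=folds,
            coefficients=np.zeros(p),
            intercept=np.array([float(y[0])]),
            selected=[],
            cv_score=0.0,
        )

    alphas_path, _, _ = lars_path(Xm, y - y.mean(), method="lasso")
    candidates = np.unique(np.concatenate([alphas_path, [0.0]]))[::-1]
    candidates = np.clip(candidates, 1e-12, None)
    if len(candidates) > 30:  # cap the CV grid on long paths
        keep = np.unique(np.linspace(0, len(candidates) - 1, 30).astype(int))
        candidates = candidates[keep]

    mse = np.zeros(len(candidates))
    for fold in np.unique(folds):
        train, test = folds != fold, folds == fold
        for i, a in enumerate(candidates):
            model = LassoLars(alpha=float(a), fit_intercept=True)
            model.fit(Xm[train], y[train])
            resid = y[test] - model.predict(Xm[test])
            mse[i] += float(np.mean(resid**2))
    mse /= len(np.unique(folds))
    # minimal CV error; ties toward the stronger penalty
    best = np.flatnonzero(mse <= mse.min() + 1e-12)
    alpha = float(candidates[best[0]])

    final = LassoLars(alpha=alpha, fit_intercept=True)
    final.fit(Xm, y)
    coef = np.asarray(final.coef_, dtype=float)
    selected = [names[i] for i in np.flatnonzero(coef != 0)]

    ols_coef, ols_intercept = None, None
    if selected:
        idx = np.flatnonzero(coef != 0)
        ols = LinearRegression().fit(Xm[:, idx], y)
        ols_coef = np.zeros(p)
        ols_coef[idx] = ols.coef_
        ols_intercept = float(ols.intercept_)

    return SelectionResult(
        outcome=outcome,
        feature_set=feature_set,
        model_kind="lasso_lars",
        feature_names=names,
        alpha=alpha,
        folds=folds,
        coefficients=coef,
        intercept=np.array([float(final.intercept_)]),
        selected=selected,
        cv_score=float(mse[best[0]]),
        ols_refit_coefficients=ols_coef,
        ols_refit_intercept=ols_intercept,
    )


def select_features_l1_logistic(
    X,
    y,
    folds: np.ndarray,
    outcome: str = "spasticity",
    feature_set: str = "la_only",
    Cs: np.ndarray | None = None,
    max_iter: int = 5000,
) -> SelectionResult:
    """L1-penalized multinomial logistic regression with block-CV penalty choice."""
    Xm, names = _as_matrix(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("classification outcome has a single class")
    if np.any(counts < 2):
        raise ValidationError("each class needs at least 2 members")
    if np.any(np.isnan(Xm)):
        raise ValidationError("modeling inputs must be imputed (no NaN)")

    Cs = Cs if Cs is not None else np.logspace(-2, 2, 9)
    Cs = np.sort(np.asarray(Cs, dtype=float))  # ascending: strongest penalty first

    def fit(C, Xf, yf):
        return LogisticRegression(
            l1_ratio=1.0, C=float(C), solver="saga", max_iter=max_iter, tol=1e-4,
            random_state=0,
        ).fit(Xf, yf)

    acc = np.zeros(len(Cs))
    n_folds = len(np.unique(folds))
    for fold in np.unique(folds):
        train, test = folds != fold, folds == fold
        if len(np.unique(y[train])) < len(classes):
            n_folds -= 1
            continue
        for i, C in enumerate(Cs):
            model = fit(C, Xm[train], y[train])
            acc[i] += float(np.mean(model.predict(Xm[test]) == y[test]))
    if n_folds == 0:
        raise ValidationError("every CV fold lost a class; use fewer folds")
    acc /= n_folds
    best = np.flatnonzero(acc >= acc.max() - 1e-12)
    C = float(Cs[best[0]])  # ties -> stronger penalty (smaller C)

    final = fit(C, Xm, y)
    coef = np.asarray(final.coef_, dtype=float)
    selected = {
        str(c): [names[j] for j in np.flatnonzero(coef[i] != 0)]
        for i, c in enumerate(final.classes_)
    }
    return SelectionResult(
        outcome=outcome,
        feature_set=feature_set,
        model_kind="l1_multinomial",
        feature_names=names,
        alpha=1.0 / C,
        folds=folds,
        coefficients=coef,
        intercept=np.asarray(final.intercept_, dtype=float),
        selected=selected,
        cv_score=float(acc[best[0]]),
        classes=[str(c) for c in final.classes_],
    )


def compose_feature_sets(la: pd.DataFrame, covariates: pd.DataFrame | None) -> dict:
    """Column-bind LA and covariate matrices for the three feature-set labels.

    Covariate columns are prefixed ``cov.`` and LA columns ``la.`` so the
    provenance of every column survives into reports. Covariates must already
    be scaled to the same 0-1 range as the LA features.
    """
    la_mat = la.add_prefix("la.")
    if covariates is None or covariates.shape[1] == 0:
        return {"la_only": la_mat, "covariates_only": None, "covariates_plus_la": la_mat}
    if not la.index.equals(covariates.index):
        if set(la.index) != set(covariates.index):
            raise ValidationError("LA and covariate tables index different participants")
        covariates = covariates.loc[la.index]
    cov_mat = covariates.add_prefix("cov.")
    return {
        "la_only": la_mat,
        "covariates_only": cov_mat,
        "covariates_plus_la": pd.concat([cov_mat, la_mat], axis=1),
    }
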
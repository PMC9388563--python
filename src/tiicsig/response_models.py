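"""Responder classification: screening, repeated CV harness, importances.

Four classifier families (extremely-randomised trees, gradient boosting,
adaptive boosting, multi-layer perceptron) are run through a repeated
stratified 3-fold cross-validation harness. Each repetition reshuffles
the folds with a repetition-specific seed derived from one master seed,
optionally grid-searches hyper-parameters within the training folds, and
scores the pooled out-of-fold predictions by ROC AUC. The report carries
the full AUC distribution, its mean, a 2.5/97.5-percentile interval, and
averaged per-feature importances (impurity-based for the tree families,
permutation-based for the perceptron — the latter is an extension, the
originating analysis only shows tree importances).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
)
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .errors import DegenerateDataError

FAMILIES = ("etc", "gbc", "abc", "mlp")
FAMILY_LABELS = {
    "etc": "extremely-randomised-trees",
    "gbc": "gradient-boosting",
    "abc": "adaptive-boosting",
    "mlp": "multi-layer-perceptron",
}

#: Small published-style grids; the harness, not the grid, is the method.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "etc": {"n_estimators": [100, 200], "max_depth": [3, 5, None]},
    "gbc": {"n_estimators": [100, 200], "learning_rate": [0.01, 0.1], "max_depth": [2, 3]},
    "abc": {"n_estimators": [50, 100, 200], "learning_rate": [0.01, 0.1, 1.0]},
    "mlp": {"hidden_layer_sizes": [(8,), (16,), (16, 8)], "alpha": [1e-4, 1e-2]},
}

DEFAULT_REPETITIONS = 5000
FAST_REPETITIONS = 200
N_FOLDS = 3


@dataclass
class ModelReport:
    family: str
    auc_per_repetition: np.ndarray
    chosen_params: dict
    importances: dict[str, float] = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_per_repetition))

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.auc_per_repetition, [2.5, 97.5])
        return float(lo), float(hi)

    def to_dict(self) -> dict:
        return {
            "family": FAMILY_LABELS[self.family],
            "mean_auc": self.mean_auc,
            "ci95": list(self.ci95),
            "n_repetitions": int(len(self.auc_per_repetition)),
            "auc_per_repetition": [float(a) for a in self.auc_per_repetition],
            "chosen_params": self.chosen_params,
            "importances": self.importances,
        }


def screen_features(features: pd.DataFrame, responder: np.ndarray) -> pd.DataFrame:
    """Univariate logistic association of each feature with response.

    Returns odds ratio, Wald CI95, p and direction per feature. Complete
    separation (or any failed maximum-likelihood fit) falls back to a
    ridge-penalised estimate and is flagged — its p-value is NaN.
    """
    y = np.asarray(responder, dtype=float)
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise DegenerateDataError("screening needs >= 2 responders and >= 2 non-responders")
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"feature": col, "or": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                         "p": np.nan, "direction": "none", "flag": "degenerate"})
            continue
        X = sm.add_constant(x)
        beta, se, flag = np.nan, np.nan, ""
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta, se = fit.params[1], fit.bse[1]
            if not (np.isfinite(beta) and np.isfinite(se) and se < 1e3):
                raise ValueError("unstable estimate")
        except Exception:
            lr = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
            lr.fit(x.reshape(-1, 1), y)
            beta, se, flag = float(lr.coef_[0, 0]), np.nan, "separation_penalised"
        p = np.nan
        ci = (np.nan, np.nan)
        if np.isfinite(se):
            from scipy.stats import norm

            p = 2 * norm.sf(abs(beta / se))
            ci = (np.exp(beta - 1.959963984540054 * se), np.exp(beta + 1.959963984540054 * se))
        rows.append({
            "feature": col, "or": float(np.exp(beta)),
            "ci_lo": ci[0], "ci_hi": ci[1], "p": p,
            "direction": "positive" if beta > 0 else "negative",
            "flag": flag,
        })
    return pd.DataFrame(rows).set_index("feature")


def make_estimator(family: str, seed: int, params: dict | None = None):
    params = dict(params or {})
    if family == "etc":
        return ExtraTreesClassifier(n_estimators=100, random_state=seed, **params)
    if family == "gbc":
        return GradientBoostingClassifier(random_state=seed, **params)
    if family == "abc":
        return AdaBoostClassifier(random_state=seed, **params)
    if family == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=params.pop("hidden_layer_sizes", (16,)),
            max_iter=params.pop("max_iter", 500),
            random_state=seed,
            **params,
        )
    raise ValueError(f"unknown family '{family}' (choose from {FAMILIES})")


def _fold_importances(family, est, X_test, y_test, rng_seed: int) -> np.ndarray:
    if family in ("etc", "gbc", "abc"):
        imp = np.asarray(est.feature_importances_, dtype=float)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = permutation_importance(
                est, X_test, y_test, scoring="roc_auc",
                n_repeats=3, random_state=rng_seed,
            )
        imp = np.clip(res.importances_mean, 0.0, None)
    total = imp.sum()
    return imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))


def fit_predict_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    family: str,
    param_grid: dict | None = None,
    repetitions: int = FAST_REPETITIONS,
    seed: int = 0,
    default_params: bool = True,
    compute_importances: bool = True,
    n_folds: int = N_FOLDS,
) -> ModelReport:
    """Repeated stratified k-fold CV harness for one classifier family.

    Per repetition the folds are reshuffled with a repetition-specific
    seed; with ``default_params=False`` a grid search (inner stratified
    3-fold, AUC-scored) runs within the training folds. The repetition's
    AUC is the pooled out-of-fold AUC. Patients with missing features
    must be dropped upstream; stratified folding requires >= ``n_folds``
    members per class.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family '{family}' (choose from {FAMILIES})")
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"f{i}" for i in range(Xv.shape[1])
    ]
    if np.isnan(Xv).any():
        raise DegenerateDataError("feature matrix contains missing values; drop incomplete patients")
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise DegenerateDataError(
            f"cannot stratify {n_folds} folds with class counts {counts.tolist()}"
        )
    grid = param_grid if param_grid is not None else DEFAULT_GRIDS[family]

    children = np.random.SeedSequence(seed).spawn(repetitions)
    aucs = np.empty(repetitions)
    imp_acc = np.zeros(len(feature_names))
    imp_n = 0
    param_votes: Counter = Counter()

    for rep, child in enumerate(children):
        rs = int(child.generate_state(1)[0] % (2**31 - 1))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        oof = np.empty(len(y))
        for fold, (tr, te) in enumerate(skf.split(Xv, y)):
            est_seed = (rs + fold) % (2**31 - 1)
            if default_params:
                est = make_estimator(family, est_seed)
            else:
                inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=est_seed)
                gs = GridSearchCV(
                    make_estimator(family, est_seed), grid,
                    scoring="roc_auc", cv=inner, n_jobs=1,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gs.fit(Xv[tr], y[tr])
                est = gs.best_estimator_
                param_votes[tuple(sorted(gs.best_params_.items()))] += 1
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Xv[tr], y[tr])
                oof[te] = est.predict_proba(Xv[te])[:, 1]
            if compute_importances:
                imp_acc += _fold_importances(family, est, Xv[te], y[te], est_seed)
                imp_n += 1
        aucs[rep] = roc_auc_score(y, oof)

    chosen: dict = {}
    if param_votes:
        chosen = dict(param_votes.most_common(1)[0][0])
    importances = {}
    if compute_importances and imp_n:
        mean_imp = imp_acc / imp_n
        importances = {n: float(v) for n, v in zip(feature_names, mean_imp)}
    return ModelReport(
        family=family,
        auc_per_repetition=aucs,
        chosen_params=chosen,
        importances=importances,
    )


def fit_train_validate(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_val: pd.DataFrame,
    y_val: np.ndarray,
    family: str,
    param_grid: dict | None = None,
    repetitions: int = FAST_REPETITIONS,
    seed: int = 0,
    default_params: bool = True,
) -> ModelReport:
    """Train-cohort fit (optionally grid-searched) scored on a held-out cohort.

    Mirrors the originating design: classifiers built on the training
    cohort are applied to the validation cohort, repeated with fresh
    seeds, and the average validation AUC is reported.
    """
    Xt = X_train.to_numpy(dtype=float)
    Xv = X_val.to_numpy(dtype=float)
    yt = np.asarray(y_train, dtype=int)
    yv = np.asarray(y_val, dtype=int)
    grid = param_grid if param_grid is not None else DEFAULT_GRIDS[family]
    children = np.random.SeedSequence(seed).spawn(repetitions)
    aucs = np.empty(repetitions)
    param_votes: Counter = Counter()
    for rep, child in enumerate(children):
        rs = int(child.generate_state(1)[0] % (2**31 - 1))
        if default_params:
            est = make_estimator(family, rs)
        else:
            inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=rs)
            gs = GridSearchCV(make_estimator(family, rs), grid, scoring="roc_auc", cv=inner, n_jobs=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gs.fit(Xt, yt)
            est = gs.best_estimator_
            param_votes[tuple(sorted(gs.best_params_.items()))] += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xt, yt)
            aucs[rep] = roc_auc_score(yv, est.predict_proba(Xv)[:, 1])
    chosen = dict(param_votes.most_common(1)[0][0]) if param_votes else {}
    return ModelReport(family=family, auc_per_repetition=aucs, chosen_params=chosen)
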
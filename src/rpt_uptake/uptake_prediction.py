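"""Repeated cross-validated prediction of vaccine uptake.

Three classifiers are compared under repeated stratified 10-fold
cross-validation: a balanced random forest (BRF), a plain random forest, and
L2 logistic regression.  The BRF grows each tree on a bootstrap in which the
majority class is randomly downsampled to the minority-class count, so
recall and specificity stay balanced at the study's ~72/28 class imbalance;
test folds are never resampled.  Reported metrics are fold-level accuracy,
recall, specificity, precision, NPV and AUROC (positive class = fully
vaccinated), averaged over all folds, plus normalized mean-decrease-in-Gini
feature importances with group sums for the three headline demographics
(age, income, education), the 15 judgment variables, and the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from rpt_uptake.rpt_features import JUDGMENT_VARIABLES

TOP3_DEMOGRAPHICS: tuple[str, ...] = ("age", "income", "education")
METRIC_NAMES: tuple[str, ...] = (
    "accuracy",
    "recall",
    "specificity",
    "precision",
    "npv",
    "auroc",
)


@dataclass(frozen=True)
class ModelSpec:
    """One model configuration (classifier x hyperparameters x CV plan)."""

    model: str = "brf"  # "brf" | "rf" | "logistic"
    n_estimators: int = 100
    max_depth: int = 10
    feature_set: str = "judgment+demo"
    cv_folds: int = 10
    cv_repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("brf", "rf", "logistic"):
            raise ValueError(f"unknown model {self.model!r}")


class BalancedRandomForest:
    """Random forest with per-tree majority-class downsampling.

    Each of the ``n_estimators`` trees is grown (Gini criterion, depth
    capped at ``max_depth``) on a bootstrap containing ``n_min`` cases drawn
    with replacement from each class, ``n_min`` being the minority-class
    count, so every tree sees a balanced sample while the ensemble still
    averages over the majority class.
    """

    def __init__(self, n_estimators: int = 100, max_depth: int = 10, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training data must contain both classes")
        rng = np.random.default_rng(self.random_state)
        idx_by_class = [np.flatnonzero(y == c) for c in self.classes_]
        n_min = min(len(ix) for ix in idx_by_class)
        self.estimators_: list[DecisionTreeClassifier] = []
        self.bootstrap_indices_: list[np.ndarray] = []
        for _ in range(self.n_estimators):
            boot = np.concatenate(
                [rng.choice(ix, size=n_min, replace=True) for ix in idx_by_class]
            )
            tree = DecisionTreeClassifier(
                criterion="gini",
                max_depth=self.max_depth,
                max_features="sqrt",
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(X[boot], y[boot])
            self.estimators_.append(tree)
            self.bootstrap_indices_.append(boot)
        imp = np.mean([t.feature_importances_ for t in self.estimators_], axis=0)
        total = imp.sum()
        self.feature_importances_ = imp / total if total > 0 else imp
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros((X.shape[0], self.classes_.size))
        for tree in self.estimators_:
            proba = tree.predict_proba(X)
            for j, c in enumerate(tree.classes_):
                out[:, np.searchsorted(self.classes_, c)] += proba[:, j]
        return out / self.n_estimators

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_balanced_forest(
    X: np.ndarray, y: np.ndarray, n_estimators: int, max_depth: int, seed: int
) -> BalancedRandomForest:
    """Fit a balanced random forest on a training set."""
    return BalancedRandomForest(n_estimators, max_depth, random_state=seed).fit(X, y)


def auroc_rank(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUROC as the Mann-Whitney rank statistic (midranks give tied scores
    half credit).  NaN when only one class is present."""
    y = np.asarray(y_true, dtype=int)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def compute_metrics(
    labels: np.ndarray, predicted: np.ndarray, probabilities: np.ndarray
) -> dict[str, float]:
    """Confusion-matrix metrics with class 1 (fully vaccinated) positive.

    Ratios with a zero denominator are NaN (flagged missing), never coerced
    to 0.
    """
    y = np.asarray(labels, dtype=int)
    yhat = np.asarray(predicted, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if not (y.size == yhat.size == p.size):
        raise ValueError("label, prediction and probability vectors must align")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    tp = int(((y == 1) & (yhat == 1)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "accuracy": ratio(tp + tn, y.size),
        "recall": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "auroc": auroc_rank(y, p),
    }


@dataclass
class GiniSummary:
    """Normalized mean-decrease-in-Gini importances with group sums."""

    importances: pd.Series  # indexed by feature name, sums to 1
    group_sums: dict[str, float]


def summarize_gini(
    importance_rows: Sequence[np.ndarray], feature_names: Sequence[str]
) -> GiniSummary:
    """Average per-fold impurity importances and normalize to sum 1.

    Group sums partition the total into the three headline demographics
    (age, income, education), the 15 judgment variables, and everything
    else.
    """
    if len(importance_rows) == 0:
        raise ValueError("no importances to summarize (tree-based models only)")
    mean_imp = np.mean(np.asarray(importance_rows, dtype=float), axis=0)
    total = mean_imp.sum()
    if total > 0:
        mean_imp = mean_imp / total
    imp = pd.Series(mean_imp, index=list(feature_names)).sort_values(ascending=False)
    in_top3 = imp.index.isin(TOP3_DEMOGRAPHICS)
    in_judgment = imp.index.isin(JUDGMENT_VARIABLES)
    group_sums = {
        "top3_demographics": float(imp[in_top3].sum()),
        "judgment": float(imp[in_judgment].sum()),
        "remaining": float(imp[~(in_top3 | in_judgment)].sum()),
    }
    return GiniSummary(importances=imp, group_sums=group_sums)


@dataclass
class CVMetricsReport:
    spec: ModelSpec
    means: dict[str, float]  # percent scale
    per_fold: pd.DataFrame  # raw fold-level fractions
    n_folds: int
    undefined_counts: dict[str, int]
    gini: GiniSummary | None = None


def _make_model(spec: ModelSpec, seed: int):
    if spec.model == "brf":
        return BalancedRandomForest(spec.n_estimators, spec.max_depth, random_state=seed)
    if spec.model == "rf":
        return RandomForestClassifier(
            n_estimators=spec.n_estimators,
            max_depth=spec.max_depth,
            criterion="gini",
            random_state=seed,
        )
    return LogisticRegression(max_iter=100, solver="lbfgs")


def run_repeated_cv(X: pd.DataFrame, y: np.ndarray, spec: ModelSpec) -> CVMetricsReport:
    """Repeated stratified k-fold evaluation of one model spec.

    Each repeat draws a fresh stratified partition; the model is trained on
    k-1 folds and scored on the untouched held-out fold (no resampling of
    test data).  Means are taken per metric over all fold evaluations,
    skipping folds where a metric is undefined (logged in
    ``undefined_counts``).  Logistic regression standardizes features with
    training-fold statistics.
    """
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("need both classes present")
    feature_names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    cv = RepeatedStratifiedKFold(
        n_splits=spec.cv_folds, n_repeats=spec.cv_repeats, random_state=spec.seed
    )
    rng = np.random.default_rng(spec.seed)
    fold_metrics: list[dict[str, float]] = []
    importances: list[np.ndarray] = []
    for train_idx, test_idx in cv.split(Xv, y):
        X_tr, X_te = Xv[train_idx], Xv[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]
        model = _make_model(spec, seed=int(rng.integers(2**31)))
        if spec.model == "logistic":
            mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
            sd[sd == 0] = 1.0
            X_tr = (X_tr - mu) / sd
            X_te = (X_te - mu) / sd
        model.fit(X_tr, y_tr)
        proba = model.predict_proba(X_te)
        pos_col = int(np.searchsorted(model.classes_, 1))
        fold_metrics.append(compute_metrics(y_te, model.predict(X_te), proba[:, pos_col]))
        if hasattr(model, "feature_importances_"):
            importances.append(np.asarray(model.feature_importances_))
    per_fold = pd.DataFrame(fold_metrics)
    means = {m: float(np.nanmean(per_fold[m])) * 100.0 for m in METRIC_NAMES}
    undefined = {m: int(per_fold[m].isna().sum()) for m in METRIC_NAMES}
    gini = summarize_gini(importances, feature_names) if importances else None
    return CVMetricsReport(
        spec=spec,
        means=means,
        per_fold=per_fold,
        n_folds=len(fold_metrics),
        undefined_counts=undefined,
        gini=gini,
    )


@dataclass
class LogisticReport:
    table: pd.DataFrame  # coef, se, z, p, ci_low, ci_high per variable
    llf: float
    llnull: float
    pseudo_r2: float
    converged: bool


def fit_logistic_report(X: pd.DataFrame, y: np.ndarray, maxiter: int = 100) -> LogisticReport:
    """Maximum-likelihood logistic fit with Wald inference.

    The null model is intercept-only; McFadden pseudo-R^2 = 1 - LL/LL0.
    Confidence bounds are coefficient +/- 1.96 SE.  Non-convergence (e.g.
    perfect separation) is reported through ``converged``.
    """
    y = np.asarray(y, dtype=int)
    design = sm.add_constant(X.astype(float), has_constant="add")
    fit = sm.Logit(y, design).fit(maxiter=maxiter, disp=0, warn_convergence=False)
    null = sm.Logit(y, np.ones((y.size, 1))).fit(disp=0)
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "z": fit.tvalues,
            "p": fit.pvalues,
            "ci_low": fit.params - 1.96 * fit.bse,
            "ci_high": fit.params + 1.96 * fit.bse,
        }
    )
    llf, llnull = float(fit.llf), float(null.llf)
    return LogisticReport(
        table=table,
        llf=llf,
        llnull=llnull,
        pseudo_r2=1.0 - llf / llnull,
        converged=bool(fit.mle_retvals.get("converged", True)),
    )
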
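"""Nested cross-validation for imbalanced clinical prediction.

The evaluation engine: an outer loop (leave-one-out by default; stratified
k-fold for the expensive tree ensembles) assesses the model, while an inner
stratified 4-fold grid search on each outer-training fold picks the
hyperparameters.  Imputation, scaling and class weights are all fitted on
the training rows of the fold at hand, so no held-out information leaks
into any statistic.  The held-out probabilities are pooled over outer folds
into one prediction per woman — the object every downstream metric (ROC,
Brier, cut-point scan, decision curve) consumes.

The sparse logistic model is L1-penalized, class-weighted maximum
likelihood; the L1 path performs feature selection, and the per-fold
nonzero-coefficient sets are recorded for stability accounting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    BaggingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, roc_auc_score, roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .cohort import ANTENATAL_FEATURES, DELIVERY_FEATURES, CohortTable, one_hot_encode
from .preprocess import ChainedImputer, apply_scaler, class_weights, fit_scaler

logger = logging.getLogger(__name__)

FAMILIES = ("sparse_logistic", "decision_tree", "bagged_trees",
            "random_forest", "gradient_boosted_trees")

#: default hyperparameter grids (regularization C log-spaced 1e-3..1e3)
DEFAULT_GRIDS: Mapping[str, Mapping[str, list]] = {
    "sparse_logistic": {"C": list(np.logspace(-3, 3, 10))},
    "decision_tree": {"max_leaf_nodes": [4, 8, 16, 32],
                      "min_samples_leaf": [1, 5, 10]},
    "bagged_trees": {"n_estimators": [25, 50, 100]},
    "random_forest": {"n_estimators": [100, 300], "max_depth": [None, 4, 8]},
    "gradient_boosted_trees": {"max_depth": [2, 3],
                               "learning_rate": [0.05, 0.1],
                               "l2_regularization": [0.0, 1.0]},
}


@dataclass
class ModelSpec:
    family: str = "sparse_logistic"
    hyper_grid: Mapping[str, list] | None = None
    class_weighting: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.hyper_grid is None:
            self.hyper_grid = {k: list(v)
                               for k, v in DEFAULT_GRIDS[self.family].items()}
        if any(len(v) == 0 for v in self.hyper_grid.values()):
            raise ValueError("every hyper_grid entry needs >= 1 candidate")

    def candidates(self) -> list[dict]:
        """Grid expanded in declared order (ties in search resolve to the
        first candidate)."""
        keys = list(self.hyper_grid)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.hyper_grid[k] for k in keys))]


@dataclass
class CVConfig:
    outer: str | int = "leave_one_out"  # or k for stratified k-fold
    inner_folds: int = 4
    #: balanced accuracy is the proper-accuracy analogue of the
    #: class-weighted training loss: with inverse-frequency weights, plain
    #: accuracy rewards the all-shrunk majority classifier on an imbalanced
    #: cohort, which would defeat both tuning and feature selection.
    inner_metric: str = "balanced_accuracy"  # or "accuracy" / "auc"
    mice_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if isinstance(self.outer, int) and self.outer < 2:
            raise ValueError("outer stratified k must be >= 2")
        if self.inner_metric not in ("balanced_accuracy", "accuracy", "auc"):
            raise ValueError(f"unknown inner_metric {self.inner_metric!r}")


@dataclass
class AggregatedPredictions:
    """Pooled held-out predictions: exactly one probability per sample."""

    frame: pd.DataFrame  # columns: id, fold, prob, label
    chosen_params: list[dict] = field(default_factory=list)
    selected_features: list[frozenset] | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.frame["prob"].to_numpy()).all():
            raise ValueError("non-finite held-out probability")

    @property
    def probs(self) -> np.ndarray:
        return self.frame["prob"].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_arrays(cls, probs, labels, folds=None, ids=None,
                    **kw) -> "AggregatedPredictions":
        probs = np.asarray(probs, dtype=float)
        labels = np.asarray(labels, dtype=int)
        n = len(probs)
        frame = pd.DataFrame({
            "id": ids if ids is not None else np.arange(n),
            "fold": folds if folds is not None else np.zeros(n, int),
            "prob": probs, "label": labels})
        return cls(frame, **kw)


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


# ---------------------------------------------------------------------------
# internals

def _fold_seed(seed: int, *key: int) -> int:
    """Documented fan-out: one global seed spawns per-fold seeds through a
    SeedSequence keyed by fold indices; results stay below 2^31."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] >> 1)


def _make_estimator(family: str, params: Mapping, weights, seed: int):
    if family == "sparse_logistic":
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=params["C"],
            class_weight=weights, tol=1e-6, max_iter=5000, random_state=seed)
    if family == "decision_tree":
        return DecisionTreeClassifier(class_weight=weights, random_state=seed,
                                      **params)
    if family == "bagged_trees":
        # bootstrap-aggregated trees with probability averaging
        p = dict(params)
        b = p.pop("n_estimators", 50)
        base = DecisionTreeClassifier(class_weight=weights, **p)
        return BaggingClassifier(estimator=base, n_estimators=b,
                                 random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(class_weight=weights, random_state=seed,
                                      **params)
    if family == "gradient_boosted_trees":
        return HistGradientBoostingClassifier(class_weight=weights,
                                              random_state=seed, **params)
    raise ValueError(family)


def _complete_and_scale(X_tr: pd.DataFrame, X_te: pd.DataFrame | None,
                        mice_iterations: int, seed: int):
    """Impute (only if anything is missing) then z-score, train-fitted."""
    if X_tr.isna().to_numpy().any() or (
            X_te is not None and X_te.isna().to_numpy().any()):
        imp = ChainedImputer(iterations=mice_iterations, seed=seed).fit(X_tr)
        X_tr = imp.completed_train()
        X_te = imp.transform(X_te) if X_te is not None else None
    scaler = fit_scaler(X_tr)
    X_tr = apply_scaler(scaler, X_tr)
    X_te = apply_scaler(scaler, X_te) if X_te is not None else None
    return X_tr, X_te, scaler


def _inner_grid_search(X: pd.DataFrame, y: np.ndarray, model: ModelSpec,
                       cv: CVConfig, seed: int) -> dict:
    """Mean inner-CV score per grid candidate; best (first on ties) wins.

    Preprocessing is fitted once per inner fold and shared across the grid
    — candidates differ only in the estimator, so this is exact, not an
    approximation.
    """
    counts = np.bincount(y, minlength=2)
    if counts.min() < cv.inner_folds:
        raise ValueError(
            f"minority class ({counts.min()} samples) cannot populate "
            f"{cv.inner_folds} stratified inner folds")
    candidates = model.candidates()
    if len(candidates) == 1:
        return candidates[0]
    skf = StratifiedKFold(cv.inner_folds, shuffle=True,
                          random_state=seed % (2**31))
    scores = np.zeros(len(candidates))
    for k, (tr, va) in enumerate(skf.split(X, y)):
        X_tr, X_va, _ = _complete_and_scale(
            X.iloc[tr], X.iloc[va], cv.mice_iterations, _fold_seed(seed, k))
        w = class_weights(y[tr]) if model.class_weighting else None
        for i, params in enumerate(candidates):
            est = _make_estimator(model.family, params, w, _fold_seed(seed, k, i))
            est.fit(X_tr, y[tr])
            if cv.inner_metric == "accuracy":
                scores[i] += est.score(X_va, y[va])
            elif cv.inner_metric == "balanced_accuracy":
                scores[i] += balanced_accuracy_score(y[va], est.predict(X_va))
            else:
                scores[i] += roc_auc_score(y[va], est.predict_proba(X_va)[:, 1])
    return candidates[int(np.argmax(scores))]  # argmax: first on ties


def _outer_splits(y: np.ndarray, cv: CVConfig):
    if cv.outer == "leave_one_out":
        return list(LeaveOneOut().split(np.zeros_like(y), y))
    return list(StratifiedKFold(int(cv.outer), shuffle=True,
                                random_state=cv.seed % (2**31)).split(
                                    np.zeros_like(y), y))


def default_features(table: CohortTable) -> list[str]:
    """All antenatal + delivery covariates present in the table."""
    return [f for f in ANTENATAL_FEATURES + DELIVERY_FEATURES
            if f in table.data.columns]


# ---------------------------------------------------------------------------
# public API

def nested_cv_evaluate(
    table: CohortTable,
    model: ModelSpec | None = None,
    cv: CVConfig | None = None,
    features: Sequence[str] | None = None,
) -> AggregatedPredictions:
    """Run the full nested evaluation and pool held-out predictions.

    For each outer split: hyperparameters are tuned by inner stratified
    k-fold on the outer-training rows, the winner is refitted on the whole
    outer-training fold (imputation and scaling refitted likewise), and the
    held-out probability is recorded.  For the sparse logistic model the
    refit's nonzero coefficients give the fold's selected-feature set.
    """
    model = model or ModelSpec()
    cv = cv or CVConfig()
    df, y_series = table.modelling_view()
    y = y_series.to_numpy()
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need >= 2 samples in each class")
    feats = list(features) if features is not None else default_features(table)
    X = one_hot_encode(df, feats)
    ids = df["id"].to_numpy() if "id" in df.columns else np.arange(len(df))

    probs = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1, int)
    chosen: list[dict] = []
    selected: list[frozenset] = []
    for f, (tr, te) in enumerate(_outer_splits(y, cv)):
        seed_f = _fold_seed(cv.seed, f)
        best = _inner_grid_search(X.iloc[tr], y[tr], model, cv, seed_f)
        X_tr, X_te, _ = _complete_and_scale(
            X.iloc[tr], X.iloc[te], cv.mice_iterations, seed_f)
        w = class_weights(y[tr]) if model.class_weighting else None
        est = _make_estimator(model.family, best, w, seed_f)
        est.fit(X_tr, y[tr])
        probs[te] = est.predict_proba(X_te)[:, 1]
        fold_of[te] = f
        chosen.append(best)
        if model.family == "sparse_logistic":
            nz = np.flatnonzero(np.abs(est.coef_[0]) > 0)
            selected.append(frozenset(X.columns[i] for i in nz))
        logger.debug("outer fold %d: params=%s", f, best)

    frame = pd.DataFrame({"id": ids, "fold": fold_of, "prob": probs,
                          "label": y})
    return AggregatedPredictions(
        frame, chosen_params=chosen,
        selected_features=selected if selected else None,
        feature_names=list(X.columns))


def roc_auc(preds: AggregatedPredictions) -> RocCurve:
    """ROC at every distinct predicted probability; AUC by the trapezoid
    rule, which equals the Mann-Whitney concordance probability with ties
    counted one half."""
    y, p = preds.labels, preds.probs
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, thr = roc_curve(y, p)
    return RocCurve(thr, fpr, tpr, float(np.trapezoid(tpr, fpr)))


def brier(preds: AggregatedPredictions) -> float:
    """Mean squared difference between probability and 0/1 outcome."""
    return float(np.mean((preds.probs - preds.labels) ** 2))


def feature_stability(preds: AggregatedPredictions) -> pd.DataFrame:
    """How often each feature carried a nonzero coefficient across outer
    folds — count and fraction, sorted most-stable first."""
    if preds.selected_features is None:
        raise ValueError("no selected-feature sets recorded "
                         "(only the sparse logistic family records them)")
    n_folds = len(preds.selected_features)
    counts = {f: 0 for f in preds.feature_names}
    for s in preds.selected_features:
        for f in s:
            counts[f] += 1
    out = pd.DataFrame({
        "feature": list(counts),
        "count": list(counts.values())})
    out["fraction"] = out["count"] / n_folds
    return out.sort_values(["fraction", "feature"],
                           ascending=[False, True]).reset_index(drop=True)
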
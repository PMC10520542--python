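"""Fold-local preprocessing: chained-equations imputation, z-scoring, and
the class-weight formula.

These are the leakage-sensitive steps of the evaluation pipeline: every
statistic (imputation regressions, scaler means/sds, class weights) is
learned on the training rows of the current fold only and then applied
unchanged to held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Chained-equations imputation

class ChainedImputer:
    """Deterministic multiple-imputation-by-chained-equations completion.

    Missing cells start at the training-column means; the imputer then
    cycles the incomplete features in column order, regressing each (OLS on
    all other features, fitted on the training rows observed for that
    feature) and replacing its missing cells with the predictions, for a
    fixed number of sweeps.  Regressions are fitted on training rows only;
    :meth:`transform` replays the stored per-sweep models on new rows, so
    held-out data never influences any model.  No posterior noise is drawn
    — one completed dataset per fold — making the scheme fully
    deterministic (the ``seed`` argument is accepted for interface
    stability and recorded, nothing more).

    Columns whose observed values are all 0/1 (one-hot dummies, flags) have
    their imputations clipped to [0, 1].
    """

    def __init__(self, iterations: int = 10, seed: int = 0):
        if iterations < 1:
            raise ValueError("iterations must be >= 1")
        self.iterations = int(iterations)
        self.seed = int(seed)

    def fit(self, train: pd.DataFrame) -> "ChainedImputer":
        X = train.to_numpy(dtype=float, copy=True)
        obs = ~np.isnan(X)
        self.columns_ = list(train.columns)
        n, p = X.shape
        none_observed = [c for c, k in zip(self.columns_, obs.sum(axis=0))
                         if k == 0]
        if none_observed:
            raise ValueError(
                f"feature(s) with zero observed values: {', '.join(none_observed)}")
        self.means_ = np.nanmean(np.where(obs, X, np.nan), axis=0)
        self.binary_ = np.array([
            np.isin(X[obs[:, j], j], (0.0, 1.0)).all() for j in range(p)])
        self.incomplete_ = np.flatnonzero(~obs.all(axis=0))

        # mean-initialize, then sweep; store each sweep's models for transform
        X[~obs] = np.take(self.means_, np.nonzero(~obs)[1])
        self.models_: list[dict[int, np.ndarray]] = []
        for _ in range(self.iterations):
            sweep: dict[int, np.ndarray] = {}
            for j in self.incomplete_:
                rows = obs[:, j]
                others = np.delete(np.arange(p), j)
                yj = X[rows, j]
                if np.ptp(yj) == 0.0:  # constant target: degenerate regression
                    beta = np.zeros(len(others) + 1)
                    beta[0] = yj[0]
                else:
                    A = np.column_stack([np.ones(rows.sum()), X[rows][:, others]])
                    beta, *_ = np.linalg.lstsq(A, yj, rcond=None)
                sweep[j] = beta
                miss = ~rows
                if miss.any():
                    A_miss = np.column_stack([np.ones(miss.sum()),
                                              X[miss][:, others]])
                    pred = A_miss @ beta
                    if self.binary_[j]:
                        pred = np.clip(pred, 0.0, 1.0)
                    X[miss, j] = pred
            self.models_.append(sweep)
        # features complete in train can still be missing in held-out rows;
        # fit one regression each on the completed training data
        self.final_models_: dict[int, np.ndarray] = {}
        for j in range(p):
            if j in self.incomplete_:
                continue
            others = np.delete(np.arange(p), j)
            yj = X[:, j]
            if np.ptp(yj) == 0.0:
                beta = np.zeros(len(others) + 1)
                beta[0] = yj[0]
            else:
                A = np.column_stack([np.ones(n), X[:, others]])
                beta, *_ = np.linalg.lstsq(A, yj, rcond=None)
            self.final_models_[j] = beta
        self.completed_train_ = X
        return self

    def transform(self, m: pd.DataFrame) -> pd.DataFrame:
        """Complete new rows with the training-fitted chained models."""
        if list(m.columns) != self.columns_:
            raise ValueError("column mismatch with the fitted imputer")
        X = m.to_numpy(dtype=float, copy=True)
        obs = ~np.isnan(X)
        p = X.shape[1]
        X[~obs] = np.take(self.means_, np.nonzero(~obs)[1])
        def _apply(j: int, beta: np.ndarray) -> None:
            miss = ~obs[:, j]
            if not miss.any():
                return
            others = np.delete(np.arange(p), j)
            A = np.column_stack([np.ones(miss.sum()), X[miss][:, others]])
            pred = A @ beta
            if self.binary_[j]:
                pred = np.clip(pred, 0.0, 1.0)
            X[miss, j] = pred

        for sweep in self.models_:
            for j, beta in sweep.items():
                _apply(j, beta)
        for j, beta in self.final_models_.items():
            _apply(j, beta)
        return pd.DataFrame(X, columns=self.columns_, index=m.index)

    def completed_train(self) -> pd.DataFrame:
        return pd.DataFrame(self.completed_train_, columns=self.columns_)


def mice_impute(
    train: pd.DataFrame,
    apply_to: pd.DataFrame | None = None,
    iterations: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Functional wrapper: complete ``train`` and optionally ``apply_to``
    with chained-equations models fitted on ``train`` alone."""
    imp = ChainedImputer(iterations=iterations, seed=seed).fit(train)
    completed = imp.completed_train()
    completed.index = train.index
    out = imp.transform(apply_to) if apply_to is not None else None
    return completed, out


# ---------------------------------------------------------------------------
# Standardization

@dataclass
class ScalerParams:
    """Per-feature z-score parameters learned on training rows only.

    Constant features keep scale 1 (so they map to all zeros) and are
    flagged in ``constant``.
    """

    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    constant: np.ndarray = field(default_factory=lambda: np.array([], bool))


def fit_scaler(train: pd.DataFrame) -> ScalerParams:
    if len(train) < 2:
        raise ValueError("need >= 2 training rows to fit a scaler")
    X = train.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd, the usual standardizer convention
    constant = sd == 0.0
    sd = np.where(constant, 1.0, sd)
    return ScalerParams(list(train.columns), mean, sd, constant)


def apply_scaler(params: ScalerParams, m: pd.DataFrame) -> pd.DataFrame:
    if list(m.columns) != params.feature_names:
        raise ValueError("column mismatch with the fitted scaler")
    X = (m.to_numpy(dtype=float) - params.mean) / params.scale
    return pd.DataFrame(X, columns=params.feature_names, index=m.index)


# ---------------------------------------------------------------------------
# Class weights

def class_weights(labels) -> dict[int, float]:
    """Inverse-frequency weights: w_k = 1 / (2 x fraction of class k).

    Equalizes the total loss mass of the two classes
    (n_k * w_k = n / 2 for each k), the 'balanced' weighting convention.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("class_weights requires both classes present")
    n = y.size
    return {int(c): n / (2.0 * k) for c, k in zip(classes, counts)}
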
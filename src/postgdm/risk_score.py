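"""The deployable composite risk score.

The final model is a class-weighted L1-logistic fit on the full cohort
(hyperparameters tuned by the same inner stratified 4-fold search used in
evaluation).  Training runs on standardized features; the coefficients are
then back-transformed to raw predictor units

    b_raw_m = b_std_m / sd_m,
    b0_raw  = b0_std - sum_m b_std_m * mean_m / sd_m,

so the published-style score P(prediabetes) = 1 / (1 + e^(-(b0 + sum b_m x_m)))
applies directly to raw antenatal inputs (fasting glucose in mmol/L, HbA1c
in mmol/mol).  The default deployment predictors are the two stability-
selected ones: antenatal fasting glucose and antenatal HbA1c.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, one_hot_encode
from .info_diagnostics import ThresholdMetricsRow, threshold_metrics
from .nested_cv import (
    AggregatedPredictions,
    CVConfig,
    ModelSpec,
    _complete_and_scale,
    _fold_seed,
    _inner_grid_search,
    _make_estimator,
)
from .preprocess import class_weights

#: deployment predictors: the two antenatal measures the stability analysis
#: singles out
DEFAULT_SCORE_FEATURES = ("a_fg", "a_hba1c")

#: five predetermined target sensitivities (percent) for operating points
DEFAULT_SENSITIVITIES = (60.0, 70.0, 75.0, 80.0, 90.0)


@dataclass
class FittedRiskModel:
    """Intercept and raw-scale coefficients of the composite risk score."""

    intercept: float
    coefficients: Mapping[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.coefficients)
        if len(names) != len(set(names)):
            raise ValueError("duplicate predictor names")

    def linear_predictor(self, values: Mapping[str, float] | pd.DataFrame):
        b = self.intercept
        for name, coef in self.coefficients.items():
            if isinstance(values, pd.DataFrame):
                if name not in values.columns:
                    raise KeyError(f"unknown predictor {name!r}")
                b = b + coef * values[name].to_numpy(dtype=float)
            else:
                if name not in values:
                    raise KeyError(f"unknown predictor {name!r}")
                b = b + coef * float(values[name])
        return b

    def predict_risk(self, values: Mapping[str, float] | pd.DataFrame):
        b = self.linear_predictor(values)
        return 1.0 / (1.0 + np.exp(-b))

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"intercept": self.intercept,
             "coefficients": dict(self.coefficients),
             "provenance": self.provenance}, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, src: str | Path) -> "FittedRiskModel":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        obj = json.loads(text)
        return cls(obj["intercept"], obj["coefficients"],
                   obj.get("provenance", {}))


def published_risk_model() -> FittedRiskModel:
    """The reported two-variable score: logit = -8.36 + 0.58*A-FG + 0.10*A-HbA1c."""
    return FittedRiskModel(
        intercept=-8.36, coefficients={"a_fg": 0.58, "a_hba1c": 0.10},
        provenance={"source": "published composite score"})


def composite_risk(model: FittedRiskModel, a_fg, a_hba1c):
    """Risk of postpartum prediabetes from the two raw antenatal inputs."""
    a_fg = np.asarray(a_fg, dtype=float)
    a_hba1c = np.asarray(a_hba1c, dtype=float)
    frame = pd.DataFrame({"a_fg": np.atleast_1d(a_fg),
                          "a_hba1c": np.atleast_1d(a_hba1c)})
    risk = model.predict_risk(frame)
    return float(risk[0]) if a_fg.ndim == 0 and a_hba1c.ndim == 0 else risk


def fit_final_model(
    table: CohortTable,
    model: ModelSpec | None = None,
    cv: CVConfig | None = None,
    features: Sequence[str] | None = None,
) -> FittedRiskModel:
    """Tune on the full data (inner stratified k-fold), refit on all rows,
    and return raw-scale coefficients."""
    model = model or ModelSpec()
    if model.family != "sparse_logistic":
        raise ValueError("the composite risk score is a logistic model; "
                         f"got family {model.family!r}")
    cv = cv or CVConfig()
    feats = list(features) if features is not None else list(DEFAULT_SCORE_FEATURES)
    df, y_series = table.modelling_view()
    y = y_series.to_numpy()
    if np.bincount(y, minlength=2).min() < cv.inner_folds:
        raise ValueError("too few samples in a class to tune the final model")
    X = one_hot_encode(df, feats)

    seed = _fold_seed(cv.seed, 0xF1)
    best = _inner_grid_search(X, y, model, cv, seed)
    X_std, _, scaler = _complete_and_scale(X, None, cv.mice_iterations, seed)
    w = class_weights(y) if model.class_weighting else None
    est = _make_estimator(model.family, best, w, seed)
    est.fit(X_std, y)

    b_std = est.coef_[0]
    b0_std = float(est.intercept_[0])
    b_raw = b_std / scaler.scale
    b0_raw = b0_std - float(np.sum(b_std * scaler.mean / scaler.scale))
    return FittedRiskModel(
        intercept=b0_raw,
        coefficients={name: float(b) for name, b in zip(X.columns, b_raw)},
        provenance={"hyperparameters": {k: (v if not isinstance(v, np.floating)
                                            else float(v))
                                        for k, v in best.items()},
                    "seed": int(cv.seed), "n": int(len(y)),
                    "standardized_intercept": b0_std,
                    "standardized_coefficients": [float(b) for b in b_std],
                    "scaler_mean": [float(m) for m in scaler.mean],
                    "scaler_scale": [float(s) for s in scaler.scale]})


def standardized_view(model: FittedRiskModel) -> FittedRiskModel | None:
    """Rebuild the standardized-scale model from provenance (if recorded);
    used to verify the back-transformation leaves probabilities unchanged."""
    prov = model.provenance
    if "standardized_coefficients" not in prov:
        return None
    names = list(model.coefficients)
    return FittedRiskModel(
        intercept=prov["standardized_intercept"],
        coefficients=dict(zip(names, prov["standardized_coefficients"])),
        provenance={"scale": "standardized"})


def operating_points(
    preds: AggregatedPredictions,
    sensitivities: Sequence[float] = DEFAULT_SENSITIVITIES,
) -> list[ThresholdMetricsRow]:
    """Full metric rows at predetermined target sensitivities (percent).

    Achievable sensitivities are discrete, so for each target the largest
    cut-point whose achieved sensitivity is >= target is chosen (candidates
    are the observed positive scores; classification is score >= c).
    """
    y, p = preds.labels, preds.probs
    pos = np.sort(p[y == 1])[::-1]
    if len(pos) == 0 or len(p[y == 0]) == 0:
        raise ValueError("both classes required")
    rows = []
    for s in sensitivities:
        if not 0.0 <= s <= 100.0:
            raise ValueError(f"target sensitivity {s} outside [0, 100]")
        k = int(np.ceil(s / 100.0 * len(pos)))
        c = float(pos[k - 1]) if k >= 1 else float(pos[0] + 1e-9)
        rows.append(threshold_metrics(preds, min(max(c, 0.0), 1.0)))
    return rows
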
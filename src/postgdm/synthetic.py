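"""Seeded synthetic cohorts with the statistical structure of a
gestational-diabetes postpartum-screening study.

Two generative views of the same population are provided:

* ``latent_logistic`` (default): antenatal fasting glucose and HbA1c are
  drawn from the cohort-wide marginals (correlated), and the prediabetes
  outcome is Bernoulli with logit ``b0 + b1*a_fg + b2*a_hba1c``.  This is
  the causal direction assumed by the composite risk score, and is the
  mode used for parameter-recovery checks.
* ``class_conditional``: the outcome is drawn first at the target
  prevalence and class-varying features are sampled from class-specific
  Gaussians — the mode used for moment-matching checks.

Default location/scale parameters are the observed cohort summary moments
(prediabetes n=92 vs normal glucose tolerance n=302, prevalence 23.35%).
Postpartum measures are generated consistently with the assigned outcome, so
re-deriving the label from the glycaemic thresholds recovers it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import (
    ANTENATAL_FEATURES,
    CRITERIA,
    CohortTable,
    POSTPARTUM_COLUMNS,
)

# ---------------------------------------------------------------------------
# Cohort summary moments (mean, sd) used as generator defaults

#: cohort-wide marginals
OVERALL_MOMENTS: Mapping[str, tuple[float, float]] = {
    "age": (32.21, 5.40),
    "height": (1.64, 0.07),
    "bmi": (29.76, 6.81),
    "sbp": (115.71, 13.62),
    "dbp": (69.98, 9.40),
    "ga_ogtt": (28.16, 4.21),
    "a_fg": (4.95, 0.87),
    "a_pg": (8.55, 1.75),
    "a_hba1c": (35.52, 4.69),
    "ga_birth": (37.91, 1.27),
    "birth_weight": (3211.95, 467.75),
}

#: class-conditional antenatal moments, keyed 0=NGT, 1=prediabetes
CLASS_MOMENTS: Mapping[str, dict[int, tuple[float, float]]] = {
    "age": {1: (32.38, 5.46), 0: (32.16, 5.39)},
    "bmi": {1: (31.21, 7.40), 0: (29.30, 6.56)},
    "a_fg": {1: (5.38, 0.91), 0: (4.82, 0.81)},
    "a_pg": {1: (8.90, 1.75), 0: (8.44, 1.74)},
    "a_hba1c": {1: (38.13, 4.61), 0: (34.72, 4.42)},
}

#: class-conditional postpartum moments
POSTPARTUM_MOMENTS: Mapping[str, dict[int, tuple[float, float]]] = {
    "p_fg": {1: (5.64, 0.79), 0: (4.78, 0.38)},
    "p_pg": {1: (7.10, 2.08), 0: (5.12, 1.07)},
    "p_hba1c": {1: (42.22, 4.56), 0: (34.99, 2.55)},
}

#: categorical level probabilities (cohort-wide)
CATEGORICAL_PROBS: Mapping[str, Mapping[str, float]] = {
    "ethnicity": {"WhiteEuropean": 0.769, "SouthAsian": 0.117, "Other": 0.114},
    "parity": {"1": 0.49, "2+": 0.51},
    "smoking": {"never": 0.51, "ex": 0.394, "current": 0.096},
    "delivery_mode": {"spontaneous": 0.504, "instrumental": 0.082,
                      "caesarean": 0.414},
}

FLAG_PROBS: Mapping[str, float] = {
    "married": 0.943, "employed": 0.974,
    "male_baby": 0.468, "breastfeeding": 0.583,
}

#: physiologic floors applied after Gaussian sampling
FLOORS: Mapping[str, float] = {
    "a_fg": 2.0, "a_pg": 2.0, "p_fg": 2.0, "p_pg": 2.0,
    "a_hba1c": 15.0, "p_hba1c": 15.0,
    "height": 1.30, "age": 15.0, "bmi": 13.0,
    "sbp": 70.0, "dbp": 40.0, "ga_ogtt": 12.0, "ga_birth": 24.0,
    "birth_weight": 500.0,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic cohort generator.

    ``coefficients`` are the latent-logistic (intercept, a_fg slope,
    a_hba1c slope) on raw units (mmol/L, mmol/mol).  When
    ``calibrate_intercept`` is true the intercept receives an additive
    offset solved so the expected outcome rate equals ``prevalence``; the
    slopes — the quantities the pipeline must recover — are never touched.
    """

    n: int = 394
    prevalence: float = 0.2335
    outcome_model: str = "latent_logistic"  # or "class_conditional"
    coefficients: tuple[float, float, float] = (-8.36, 0.58, 0.10)
    calibrate_intercept: bool = True
    rho_fg_hba1c: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0
    class_means: Mapping[str, dict[int, float]] = field(
        default_factory=lambda: {f: {k: m for k, (m, _) in v.items()}
                                 for f, v in CLASS_MOMENTS.items()})
    class_sds: Mapping[str, dict[int, float]] = field(
        default_factory=lambda: {f: {k: s for k, (_, s) in v.items()}
                                 for f, v in CLASS_MOMENTS.items()})

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.outcome_model not in ("latent_logistic", "class_conditional"):
            raise ValueError(f"unknown outcome_model {self.outcome_model!r}")
        if not -1.0 < self.rho_fg_hba1c < 1.0:
            raise ValueError("rho_fg_hba1c must be in (-1, 1)")
        for f, sds in self.class_sds.items():
            if any(s <= 0 for s in sds.values()):
                raise ValueError(f"non-positive sd for feature {f!r}")


def _truncated_normal(rng: np.random.Generator, mean, sd, size,
                      floor: float | None) -> np.ndarray:
    """Gaussian draw with resampling below the floor (deterministic in rng)."""
    x = rng.normal(mean, sd, size)
    if floor is not None:
        for _ in range(200):
            bad = x <= floor
            if not bad.any():
                break
            x[bad] = rng.normal(
                mean if np.isscalar(mean) else np.asarray(mean)[bad],
                sd if np.isscalar(sd) else np.asarray(sd)[bad],
                int(bad.sum()))
        np.clip(x, floor + 1e-9, None, out=x)
    return x


def _correlated_pair(rng, m1, s1, m2, s2, rho, size):
    """Bivariate normal with the given marginals and correlation."""
    z1 = rng.standard_normal(size)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(size)
    return m1 + s1 * z1, m2 + s2 * z2


def _categorical(rng, probs: Mapping[str, float], size: int) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[v] for v in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=size, p=p)


def _postpartum_for_label(rng: np.random.Generator, y: np.ndarray,
                          criteria_name: str = "NICE") -> dict[str, np.ndarray]:
    """Draw postpartum measures from class moments, constrained so the
    glycaemic labelling rules recover the assigned class exactly."""
    crit = CRITERIA[criteria_name]
    n = len(y)
    out = {}
    for col in POSTPARTUM_COLUMNS:
        mom = POSTPARTUM_MOMENTS[col]
        mean = np.where(y == 1, mom[1][0], mom[0][0]).astype(float)
        sd = np.where(y == 1, mom[1][1], mom[0][1]).astype(float)
        out[col] = _truncated_normal(rng, mean, sd, n, FLOORS[col])

    pre_thr = {"p_fg": crit.prediabetes.get("fasting", np.inf),
               "p_pg": crit.prediabetes.get("postprandial", np.inf),
               "p_hba1c": crit.prediabetes.get("hba1c", np.inf)}
    dm_thr = {"p_fg": crit.diabetes.get("fasting", np.inf),
              "p_pg": crit.diabetes.get("postprandial", np.inf),
              "p_hba1c": crit.diabetes.get("hba1c", np.inf)}

    def consistent() -> np.ndarray:
        any_pre = np.zeros(n, bool)
        any_dm = np.zeros(n, bool)
        for col in POSTPARTUM_COLUMNS:
            any_pre |= out[col] >= pre_thr[col]
            any_dm |= out[col] >= dm_thr[col]
        return np.where(y == 1, any_pre & ~any_dm, ~any_pre)

    for _ in range(200):
        ok = consistent()
        if ok.all():
            break
        bad = ~ok
        nb = int(bad.sum())
        for col in POSTPARTUM_COLUMNS:
            mom = POSTPARTUM_MOMENTS[col]
            mean = np.where(y[bad] == 1, mom[1][0], mom[0][0]).astype(float)
            sd = np.where(y[bad] == 1, mom[1][1], mom[0][1]).astype(float)
            out[col][bad] = _truncated_normal(rng, mean, sd, nb, FLOORS[col])
    else:  # deterministic repair for any stragglers
        bad = ~consistent()
        for col in POSTPARTUM_COLUMNS:
            out[col][bad & (y == 0)] = np.minimum(
                out[col][bad & (y == 0)], pre_thr[col] - 1e-6)
            out[col][bad & (y == 1)] = np.minimum(
                out[col][bad & (y == 1)], dm_thr[col] - 1e-6)
        fire = np.zeros(n, bool)
        for col in POSTPARTUM_COLUMNS:
            fire |= out[col] >= pre_thr[col]
        force = bad & (y == 1) & ~fire
        out["p_fg"][force] = pre_thr["p_fg"] + 0.05
    return out


def generate_cohort(spec: GeneratorSpec) -> CohortTable:
    """Generate a labelled synthetic cohort.  Deterministic given the seed."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n

    if spec.outcome_model == "latent_logistic":
        m_fg, s_fg = OVERALL_MOMENTS["a_fg"]
        m_hb, s_hb = OVERALL_MOMENTS["a_hba1c"]
        a_fg, a_hba1c = _correlated_pair(
            rng, m_fg, s_fg, m_hb, s_hb, spec.rho_fg_hba1c, n)
        a_fg = np.maximum(a_fg, FLOORS["a_fg"] + 1e-9)
        a_hba1c = np.maximum(a_hba1c, FLOORS["a_hba1c"] + 1e-9)
        b0, b1, b2 = spec.coefficients
        lp = b0 + b1 * a_fg + b2 * a_hba1c
        if spec.calibrate_intercept:
            delta = brentq(
                lambda d: expit(lp + d).mean() - spec.prevalence, -20.0, 20.0)
            lp = lp + delta
        y = (rng.random(n) < expit(lp)).astype(int)
        age = _truncated_normal(rng, *OVERALL_MOMENTS["age"], n, FLOORS["age"])
        bmi = _truncated_normal(rng, *OVERALL_MOMENTS["bmi"], n, FLOORS["bmi"])
        a_pg = _truncated_normal(rng, *OVERALL_MOMENTS["a_pg"], n, FLOORS["a_pg"])
    else:
        y = (rng.random(n) < spec.prevalence).astype(int)
        means = spec.class_means
        sds = spec.class_sds
        pick = lambda f: (np.where(y == 1, means[f][1], means[f][0]).astype(float),
                          np.where(y == 1, sds[f][1], sds[f][0]).astype(float))
        (mf, sf), (mh, sh) = pick("a_fg"), pick("a_hba1c")
        a_fg, a_hba1c = _correlated_pair(rng, mf, sf, mh, sh,
                                         spec.rho_fg_hba1c, n)
        a_fg = np.maximum(a_fg, FLOORS["a_fg"] + 1e-9)
        a_hba1c = np.maximum(a_hba1c, FLOORS["a_hba1c"] + 1e-9)
        age = _truncated_normal(rng, *pick("age"), n, FLOORS["age"])
        bmi = _truncated_normal(rng, *pick("bmi"), n, FLOORS["bmi"])
        a_pg = _truncated_normal(rng, *pick("a_pg"), n, FLOORS["a_pg"])

    height = _truncated_normal(rng, *OVERALL_MOMENTS["height"], n,
                               FLOORS["height"])
    weight = bmi * height**2  # keeps the bmi = weight/height^2 audit exact
    cols: dict[str, np.ndarray] = {
        "id": np.array([f"S{i:05d}" for i in range(n)]),
        "age": age, "height": height, "weight": weight, "bmi": bmi,
        "sbp": _truncated_normal(rng, *OVERALL_MOMENTS["sbp"], n, FLOORS["sbp"]),
        "dbp": _truncated_normal(rng, *OVERALL_MOMENTS["dbp"], n, FLOORS["dbp"]),
        "ga_ogtt": _truncated_normal(rng, *OVERALL_MOMENTS["ga_ogtt"], n,
                                     FLOORS["ga_ogtt"]),
        "a_fg": a_fg, "a_pg": a_pg, "a_hba1c": a_hba1c,
        "ga_birth": _truncated_normal(rng, *OVERALL_MOMENTS["ga_birth"], n,
                                      FLOORS["ga_birth"]),
        "birth_weight": _truncated_normal(
            rng, *OVERALL_MOMENTS["birth_weight"], n, FLOORS["birth_weight"]),
    }
    for col, probs in CATEGORICAL_PROBS.items():
        cols[col] = _categorical(rng, probs, n)
    parity_num = np.where(cols["parity"] == "1", 1, 2)
    cols["gravida"] = (parity_num + rng.poisson(0.8, n)).astype(float)
    for col, p in FLAG_PROBS.items():
        cols[col] = (rng.random(n) < p).astype(float)
    cols.update(_postpartum_for_label(rng, y))

    table = CohortTable(pd.DataFrame(cols))
    recovered = table.binary_outcome().to_numpy()
    if not np.array_equal(recovered, y.astype(float)):
        raise AssertionError("generated postpartum measures do not recover "
                             "the assigned outcome")  # internal contract
    if spec.missing_rate > 0:
        table = inject_missingness(table, spec.missing_rate,
                                   seed=int(rng.integers(2**31)))
    return table


def inject_missingness(
    table: CohortTable,
    rate: float,
    seed: int,
    columns: Sequence[str] = ANTENATAL_FEATURES,
) -> CohortTable:
    """Mask antenatal cells missing-completely-at-random at the given rate.

    Outcome-defining postpartum measures are never masked.  Returns a new
    table; the input is untouched.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return CohortTable(table.data.copy(), criteria=table.criteria)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    df = table.data.copy()
    maskable = [c for c in columns
                if c in df.columns and c not in POSTPARTUM_COLUMNS]
    mask = rng.random((len(df), len(maskable))) < rate
    for j, col in enumerate(maskable):
        if df[col].dtype == object:
            df.loc[mask[:, j], col] = None
        else:
            df.loc[mask[:, j], col] = np.nan
    return CohortTable(df, criteria=table.criteria)
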
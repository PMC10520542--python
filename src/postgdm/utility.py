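"""Decision curve analysis and statistical power for the two-group design.

Net benefit at threshold probability ``pt`` values a true positive at 1 and
a false positive at the odds ``pt/(1-pt)``:

    NB(pt) = (TP - FP * pt/(1-pt)) / N

compared against treat-all (NB = pi - (1-pi) pt/(1-pt), prevalence pi) and
treat-none (NB = 0).

Power calculations use the two-sided two-sample t-test with unequal group
sizes (allocation ratio r = n2/n1) and Cohen's d with the pooled standard
deviation; the power function is the noncentral t, via the standard
`statsmodels` solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.power import TTestIndPower

from .nested_cv import AggregatedPredictions


@dataclass(frozen=True)
class NetBenefitPoint:
    pt: float
    nb_model: float
    nb_all: float
    nb_none: float = 0.0


def net_benefit(
    preds: AggregatedPredictions,
    pt_grid: Sequence[float] | None = None,
    n_total: int | None = None,
) -> pd.DataFrame:
    """Decision curve: model vs treat-all vs treat-none net benefit.

    ``n_total`` overrides the denominator N (e.g. to express benefit per
    member of a wider cohort than the prediction set); prevalence for the
    treat-all comparator uses the same denominator.
    """
    pts = (np.round(np.arange(0.01, 1.0, 0.01), 2) if pt_grid is None
           else np.asarray(pt_grid, dtype=float))
    if np.any((pts <= 0.0) | (pts >= 1.0)):
        raise ValueError("threshold probabilities must lie in (0, 1)")
    y, p = preds.labels, preds.probs
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    n = int(n_total) if n_total is not None else len(y)
    odds = pts / (1.0 - pts)
    tp = (p[None, y == 1] >= pts[:, None]).sum(axis=1)
    fp = (p[None, y == 0] >= pts[:, None]).sum(axis=1)
    n_pos = int((y == 1).sum())
    nb_model = (tp - fp * odds) / n
    nb_all = (n_pos - (n - n_pos) * odds) / n
    return pd.DataFrame({"pt": pts, "nb_model": nb_model, "nb_all": nb_all,
                         "nb_none": np.zeros_like(pts)})


# ---------------------------------------------------------------------------
# Power analysis

@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for the two-sample t-test power calculation."""

    d: float                 # Cohen's effect size
    alpha: float = 0.05      # two-sided significance level
    power: float = 0.90      # target probability of rejecting a false null
    ratio: float = 1.0       # allocation n2/n1

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must be in (0, 1)")
        if self.d <= 0.0:
            raise ValueError("effect size must be > 0")
        if self.ratio <= 0.0:
            raise ValueError("allocation ratio must be > 0")


def cohens_d(mu1: float, sd1: float, n1: int,
             mu2: float, sd2: float, n2: int) -> float:
    """Standardized mean difference with the pooled standard deviation.

    s_pooled^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2); the sign
    follows mu1 - mu2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be > 0")
    s2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    return (mu1 - mu2) / math.sqrt(s2)


def solve_sample_size(spec: PowerSpec) -> tuple[int, int]:
    """Smallest (n1, n2 = ratio*n1) reaching the target power.

    Solves the noncentral-t power equation on the real line, then rounds
    each group up independently.
    """
    spec.validate()
    n1 = TTestIndPower().solve_power(
        effect_size=spec.d, alpha=spec.alpha, power=spec.power,
        ratio=spec.ratio, alternative="two-sided")
    if not np.isfinite(n1) or n1 <= 1:
        raise ValueError("power target unattainable for this design")
    return math.ceil(n1), math.ceil(spec.ratio * n1)


def power_at(spec: PowerSpec, n1: float) -> float:
    """Achieved power of the two-sided test at group sizes (n1, ratio*n1)."""
    return float(TTestIndPower().power(
        effect_size=spec.d, nobs1=n1, alpha=spec.alpha, ratio=spec.ratio,
        alternative="two-sided"))


def power_curve(
    n1_grid: Sequence[float],
    d_grid: Sequence[float],
    alpha: float = 0.05,
    ratio: float = 1.0,
) -> pd.DataFrame:
    """Power over a grid of group-1 sizes and effect sizes (long format)."""
    rows = []
    for d in d_grid:
        spec = PowerSpec(d=d, alpha=alpha, ratio=ratio)
        for n1 in n1_grid:
            rows.append({"n1": float(n1), "d": float(d), "alpha": alpha,
                         "ratio": ratio, "power": power_at(spec, n1)})
    return pd.DataFrame(rows)
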
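"""Kullback-Leibler evaluation of a dichotomized risk score.

At a probability cut-point ``c`` the score induces two Bernoulli response
distributions: sensitivity ``g1(c)`` among the diseased and specificity
``g2(c)`` among the non-diseased.  The relative entropies

    D(g1||g2) = g1 ln(g1/(1-g2)) + (1-g1) ln((1-g1)/g2)   (rule-in)
    D(g2||g1) = (1-g2) ln((1-g2)/g1) + g2 ln(g2/(1-g1))   (rule-out)

measure the information a positive (resp. negative) result carries.  Their
exponentials P_in = e^D and P_out are pre-to-post-test odds multipliers;
ID = 1 - e^(-D) rescales divergence to [0, 1).  Scanning a cut-point grid
and maximizing D(g1||g2), D(g2||g1), or their sum TKL yields the rule-in
test T_in, the rule-out test T_out, and the combined test T_in-out.

Information graphs plot the diagnostic information of a positive/negative
result (posterior-vs-prior relative entropy) against the pre-test
probability; their expectation is the mutual information between disease
status and test result.  TKL also equals a discrete Bregman divergence of
the negative Shannon entropy h(p) = p ln p + (1-p) ln(1-p): the summed
vertical gaps between h and its tangents at p = g1 and p = 1 - g2.

All logarithms are natural (nats).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .nested_cv import AggregatedPredictions

#: probabilities entering a log are clamped to [EPS, 1-EPS]; degenerate
#: rows (sensitivity or specificity exactly 0 or 1) are therefore reported
#: as large finite divergences and flagged, never +/-inf.
EPS = 1e-12

__all__ = [
    "kl_in", "kl_out", "pin_pout", "info_distinguishability",
    "youden", "threshold_metrics", "scan_cutpoints",
    "information_graph", "bregman_total_kl",
    "ThresholdMetricsRow", "CutpointSelection", "DEFAULT_GRID",
]

#: the canonical scan grid: 1000 cut-points 0.000, 0.001, ..., 0.999
DEFAULT_GRID = np.round(np.arange(1000) * 0.001, 3)


def _clamp(p):
    return np.clip(p, EPS, 1.0 - EPS)


def _check_unit(name, *vals):
    for v in vals:
        v = np.asarray(v, dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")


def kl_in(g1, g2):
    """Rule-in divergence D(g1||g2) in nats (vectorized)."""
    _check_unit("g1/g2", g1, g2)
    g1, g2 = _clamp(np.asarray(g1, float)), _clamp(np.asarray(g2, float))
    d = g1 * np.log(g1 / (1 - g2)) + (1 - g1) * np.log((1 - g1) / g2)
    return d if d.ndim else float(d)


def kl_out(g1, g2):
    """Rule-out divergence D(g2||g1) in nats (vectorized)."""
    _check_unit("g1/g2", g1, g2)
    g1, g2 = _clamp(np.asarray(g1, float)), _clamp(np.asarray(g2, float))
    d = (1 - g2) * np.log((1 - g2) / g1) + g2 * np.log(g2 / (1 - g1))
    return d if d.ndim else float(d)


def pin_pout(d):
    """Odds-ratio multiplier e^D for a divergence of d nats."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("divergence must be >= 0")
    out = np.exp(d)
    return out if out.ndim else float(out)


def info_distinguishability(d):
    """Information distinguishability ID = 1 - e^(-D), in [0, 1)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("divergence must be >= 0")
    out = 1.0 - np.exp(-d)
    return out if out.ndim else float(out)


def youden(g1, g2):
    """Youden index J = sensitivity + specificity - 1."""
    _check_unit("g1/g2", g1, g2)
    j = np.asarray(g1, float) + np.asarray(g2, float) - 1.0
    return j if j.ndim else float(j)


# ---------------------------------------------------------------------------
# Threshold metric rows

@dataclass
class ThresholdMetricsRow:
    """Every reported column of the per-cut-point diagnostic table."""

    c: float
    g1: float          # sensitivity
    g2: float          # specificity
    ppv: float         # nan when nothing is predicted positive
    npv: float
    f1: float
    accuracy: float
    j: float
    kl_in: float
    kl_out: float
    tkl: float
    p_in: float
    p_out: float
    id_in: float
    id_out: float
    ta: int            # percent of cohort scoring strictly below c
    degenerate: bool = False  # g1 or g2 hit 0/1; divergences are clamped

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _metrics_from_counts(c, tp, fn, tn, fp, n_below, n) -> ThresholdMetricsRow:
    pos, neg = tp + fn, tn + fp
    g1, g2 = tp / pos, tn / neg
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    f1 = (2 * ppv * g1 / (ppv + g1)
          if np.isfinite(ppv) and (ppv + g1) > 0 else float("nan"))
    acc = (tp + tn) / n
    din, dout = kl_in(g1, g2), kl_out(g1, g2)
    return ThresholdMetricsRow(
        c=float(c), g1=float(g1), g2=float(g2), ppv=float(ppv),
        npv=float(npv), f1=float(f1), accuracy=float(acc),
        j=float(g1 + g2 - 1.0), kl_in=float(din), kl_out=float(dout),
        tkl=float(din + dout), p_in=float(np.exp(din)),
        p_out=float(np.exp(dout)), id_in=float(1 - np.exp(-din)),
        id_out=float(1 - np.exp(-dout)),
        ta=int(round(100.0 * n_below / n)),
        degenerate=bool(g1 in (0.0, 1.0) or g2 in (0.0, 1.0)))


def threshold_metrics(preds: AggregatedPredictions,
                      c: float) -> ThresholdMetricsRow:
    """Classify positive iff score >= c and report the full metric row."""
    if not 0.0 <= c <= 1.0:
        raise ValueError("cut-point must lie in [0, 1]")
    y, p = preds.labels, preds.probs
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    pred_pos = p >= c
    tp = int(np.sum(pred_pos & (y == 1)))
    fn = int(np.sum(~pred_pos & (y == 1)))
    tn = int(np.sum(~pred_pos & (y == 0)))
    fp = int(np.sum(pred_pos & (y == 0)))
    return _metrics_from_counts(c, tp, fn, tn, fp, int(np.sum(p < c)), len(y))


@dataclass
class CutpointSelection:
    """The three information-optimal tests found by a grid scan."""

    c_in: float
    d_in: float        # max D(g1||g2)
    c_out: float
    d_out: float       # max D(g2||g1)
    c_in_out: float
    tkl_max: float     # max of the symmetric sum


def scan_cutpoints(
    preds: AggregatedPredictions,
    grid: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, CutpointSelection]:
    """Metric rows at every grid cut-point plus the three argmax tests.

    The default grid is 1000 points at 0.001 spacing from 0.000 to 0.999.
    Ties break toward the smaller cut-point.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    y, p = preds.labels, preds.probs
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    pos, neg = p[y == 1], p[y == 0]
    n = len(y)
    # vectorized confusion counts over the whole grid
    tp = (pos[None, :] >= grid[:, None]).sum(axis=1)
    fp = (neg[None, :] >= grid[:, None]).sum(axis=1)
    fn = len(pos) - tp
    tn = len(neg) - fp
    n_below = (p[None, :] < grid[:, None]).sum(axis=1)
    rows = [_metrics_from_counts(grid[i], tp[i], fn[i], tn[i], fp[i],
                                 n_below[i], n)
            for i in range(len(grid))]
    table = pd.DataFrame([r.as_dict() for r in rows])
    i_in = int(np.argmax(table["kl_in"].to_numpy()))
    i_out = int(np.argmax(table["kl_out"].to_numpy()))
    i_both = int(np.argmax(table["tkl"].to_numpy()))
    sel = CutpointSelection(
        c_in=float(grid[i_in]), d_in=float(table["kl_in"].iloc[i_in]),
        c_out=float(grid[i_out]), d_out=float(table["kl_out"].iloc[i_out]),
        c_in_out=float(grid[i_both]), tkl_max=float(table["tkl"].iloc[i_both]))
    return table, sel


# ---------------------------------------------------------------------------
# Information graphs

def information_graph(g1: float, g2: float,
                      x_grid: Sequence[float] | None = None) -> pd.DataFrame:
    """Diagnostic information vs pre-test probability for a fixed test.

    At pre-test probability ``x`` the probability of a positive result is
    ``Pr(T1) = x g1 + (1-x)(1-g2)``.  ``i_plus`` / ``i_minus`` are the
    relative entropies of the posterior disease distribution (given a
    positive / negative result) from the prior, and ``i_expected`` is the
    mutual information between status and result, so the decomposition
    ``i_expected = Pr(T1) i_plus + (1-Pr(T1)) i_minus`` holds identically.
    """
    _check_unit("g1/g2", g1, g2)
    x = (np.linspace(0.001, 0.999, 999) if x_grid is None
         else _clamp(np.asarray(x_grid, dtype=float)))
    g1c, g2c = float(_clamp(g1)), float(_clamp(g2))
    pr_t1 = _clamp(x * g1c + (1 - x) * (1 - g2c))
    post_pos = _clamp(x * g1c / pr_t1)           # Pr(D1 | T1)
    post_neg = _clamp(x * (1 - g1c) / (1 - pr_t1))  # Pr(D1 | T0)

    def kl_bern(a, b):
        return a * np.log(a / b) + (1 - a) * np.log((1 - a) / (1 - b))

    i_plus = kl_bern(post_pos, x)
    i_minus = kl_bern(post_neg, x)
    # mutual information of the 2x2 joint, computed independently of the
    # posterior decomposition above
    joint = np.stack([x * g1c, x * (1 - g1c),
                      (1 - x) * (1 - g2c), (1 - x) * g2c])
    marg_t = np.stack([pr_t1, 1 - pr_t1, pr_t1, 1 - pr_t1])
    marg_d = np.stack([x, x, 1 - x, 1 - x])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / _clamp(marg_t * marg_d))
    i_expected = np.where(joint > EPS, terms, 0.0).sum(axis=0)
    return pd.DataFrame({"x": x, "pr_t1": pr_t1, "i_plus": i_plus,
                         "i_minus": i_minus,
                         "i_expected": np.maximum(i_expected, 0.0)})


def bregman_total_kl(g1: float, g2: float) -> float:
    """Total K-L divergence as a discrete Bregman divergence.

    Sum of the vertical distances between the negative Shannon entropy
    h(p) = p ln p + (1-p) ln(1-p) and its tangents, evaluated crosswise at
    p = g1 and p = 1 - g2; algebraically equal to kl_in + kl_out.
    """
    _check_unit("g1/g2", g1, g2)
    a = float(_clamp(g1))        # p = g1(c)
    b = float(_clamp(1.0 - g2))  # p = 1 - g2(c)

    def h(p):
        return p * np.log(p) + (1 - p) * np.log(1 - p)

    def h_prime(p):
        return np.log(p / (1 - p))

    def tangent(at, x):
        return h(at) + h_prime(at) * (x - at)

    return float((h(a) - tangent(b, a)) + (h(b) - tangent(a, b)))
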
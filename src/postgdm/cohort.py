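"""Cohort data model, CSV I/O and postpartum glucose-tolerance labelling.

The cohort is one row per woman with antenatal covariates measured around
the gestational-diabetes OGTT, delivery/neonatal covariates, and (optionally)
the postpartum screening measures that define the outcome: fasting glucose
(``p_fg``, mmol/L), 2-h postprandial glucose (``p_pg``, mmol/L) and HbA1c
(``p_hba1c``, mmol/mol IFCC).

The outcome label is derived from fixed glycaemic thresholds.  Three named
rule-sets are supported (NICE is the default; WHO and ADA differ only in
which measures count towards prediabetes and where the fasting cut lies).
Incident type-2 diabetes takes precedence over prediabetes when both
rule-sets fire; a woman with no postpartum measure at all is ``unlabelled``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Column schema

#: numeric columns, canonical units: years, m, kg, kg/m^2, mmHg, weeks,
#: mmol/L (glucose), mmol/mol (HbA1c), grams
NUMERIC_COLUMNS = (
    "age", "height", "weight", "bmi", "sbp", "dbp", "gravida",
    "ga_ogtt", "a_fg", "a_pg", "a_hba1c",
    "ga_birth", "birth_weight",
    "p_fg", "p_pg", "p_hba1c",
)

#: categorical columns with their level sets (first level = modelling reference)
CATEGORICAL_LEVELS: Mapping[str, tuple[str, ...]] = {
    "ethnicity": ("WhiteEuropean", "SouthAsian", "Other"),
    "parity": ("1", "2+"),
    "smoking": ("never", "ex", "current"),
    "delivery_mode": ("spontaneous", "instrumental", "caesarean"),
}

#: 0/1 flag columns
FLAG_COLUMNS = ("married", "employed", "male_baby", "breastfeeding")

#: covariates known antenatally (candidates for prediction)
ANTENATAL_FEATURES = (
    "age", "height", "weight", "bmi", "sbp", "dbp", "gravida",
    "ethnicity", "parity", "smoking", "married", "employed",
    "ga_ogtt", "a_fg", "a_pg", "a_hba1c",
)

#: covariates known at/after delivery
DELIVERY_FEATURES = (
    "ga_birth", "delivery_mode", "birth_weight", "male_baby", "breastfeeding",
)

#: outcome-defining postpartum measures — never imputed, never masked
POSTPARTUM_COLUMNS = ("p_fg", "p_pg", "p_hba1c")

#: columns that must exist in any ingested file
MANDATORY_COLUMNS = ("a_fg", "a_hba1c")

ALL_COLUMNS = ("id",) + NUMERIC_COLUMNS[:13] + tuple(CATEGORICAL_LEVELS) \
    + FLAG_COLUMNS + POSTPARTUM_COLUMNS
# note: ALL_COLUMNS is a convenience superset; tables may carry any subset
# beyond MANDATORY_COLUMNS.

MISSING_MARKERS = ("", "NA", "NaN")


# ---------------------------------------------------------------------------
# Outcome criteria

@dataclass(frozen=True)
class DiagnosticCriteria:
    """Glycaemic thresholds (inclusive, >=) for one named rule-set.

    ``prediabetes`` and ``diabetes`` map measure name -> threshold; a measure
    absent from the map does not contribute to that category.
    """

    name: str
    prediabetes: Mapping[str, float]
    diabetes: Mapping[str, float]


#: fasting / 2-h postprandial in mmol/L, HbA1c in mmol/mol
CRITERIA: Mapping[str, DiagnosticCriteria] = {
    "NICE": DiagnosticCriteria(
        "NICE",
        prediabetes={"fasting": 5.6, "postprandial": 7.8, "hba1c": 40.0},
        diabetes={"fasting": 7.0, "postprandial": 11.1, "hba1c": 48.0},
    ),
    "WHO": DiagnosticCriteria(
        "WHO",
        prediabetes={"fasting": 6.1, "postprandial": 7.8},
        diabetes={"fasting": 7.0, "postprandial": 11.1, "hba1c": 48.0},
    ),
    "ADA": DiagnosticCriteria(
        "ADA",
        prediabetes={"fasting": 5.6, "postprandial": 7.8, "hba1c": 39.0},
        diabetes={"fasting": 7.0, "postprandial": 11.1, "hba1c": 48.0},
    ),
}

_MEASURE_COLUMN = {"fasting": "p_fg", "postprandial": "p_pg", "hba1c": "p_hba1c"}

#: ordered from least to most severe, for monotonicity reasoning
SEVERITY_ORDER = ("NGT", "prediabetes", "T2DM")


@dataclass(frozen=True)
class OutcomeLabel:
    """Postpartum glucose-tolerance status and the measures that fired."""

    status: str  # "NGT" | "prediabetes" | "T2DM" | "unlabelled"
    triggering_measures: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.status not in SEVERITY_ORDER + ("unlabelled",):
            raise ValueError(f"unknown status {self.status!r}")


def label_outcome(
    p_fg: float | None,
    p_pg: float | None,
    p_hba1c: float | None,
    criteria: str | DiagnosticCriteria = "NICE",
) -> OutcomeLabel:
    """Label one woman's postpartum status from her screening measures.

    Thresholds are inclusive (``>=``).  Diabetes takes precedence over
    prediabetes; with all three measures absent the status is ``unlabelled``.
    ``triggering_measures`` names the comparisons that fired for the returned
    status (empty exactly when the status is NGT or unlabelled).
    """
    if isinstance(criteria, str):
        try:
            criteria = CRITERIA[criteria]
        except KeyError:
            raise ValueError(
                f"unknown criteria {criteria!r}; choose from {sorted(CRITERIA)}"
            ) from None

    values = {"fasting": p_fg, "postprandial": p_pg, "hba1c": p_hba1c}
    values = {k: v for k, v in values.items() if v is not None and pd.notna(v)}
    if not values:
        return OutcomeLabel("unlabelled")

    dm = {m for m, thr in criteria.diabetes.items()
          if m in values and values[m] >= thr}
    if dm:
        return OutcomeLabel("T2DM", frozenset(dm))
    pre = {m for m, thr in criteria.prediabetes.items()
           if m in values and values[m] >= thr}
    if pre:
        return OutcomeLabel("prediabetes", frozenset(pre))
    return OutcomeLabel("NGT")


# ---------------------------------------------------------------------------
# Table container

@dataclass
class CohortTable:
    """An ordered cohort: a DataFrame of records plus parallel outcome labels.

    ``data`` holds one row per woman in canonical column names/units; missing
    values are NaN.  ``labels`` is recomputed from the postpartum columns on
    construction (and by :meth:`relabel`) so the two can never fall out of
    sync.
    """

    data: pd.DataFrame
    criteria: str = "NICE"
    labels: list[OutcomeLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.relabel(self.criteria)

    def relabel(self, criteria: str = "NICE") -> None:
        self.criteria = criteria
        get = lambda col: (self.data[col] if col in self.data
                           else pd.Series(float("nan"), index=self.data.index))
        self.labels = [
            label_outcome(fg, pg, hba1c, criteria)
            for fg, pg, hba1c in zip(get("p_fg"), get("p_pg"), get("p_hba1c"))
        ]
        self.data["status"] = [lab.status for lab in self.labels]

    def __len__(self) -> int:
        return len(self.data)

    @property
    def status(self) -> pd.Series:
        return pd.Series([lab.status for lab in self.labels], name="status")

    def binary_outcome(self) -> pd.Series:
        """Prediabetes=1 vs NGT=0; T2DM and unlabelled rows are NaN.

        The prediction task contrasts prediabetes with normal glucose
        tolerance; incident diabetes and women without postpartum screening
        fall outside the two-class problem and are dropped by the modelling
        layers (with a logged count).
        """
        mapping = {"prediabetes": 1.0, "NGT": 0.0}
        return self.status.map(mapping)

    def modelling_view(self) -> tuple[pd.DataFrame, pd.Series]:
        """Rows with a binary outcome, plus the 0/1 outcome vector."""
        y = self.binary_outcome()
        keep = y.notna()
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d rows without a binary outcome", n_drop)
        return self.data.loc[keep].reset_index(drop=True), \
            y.loc[keep].astype(int).reset_index(drop=True)


# ---------------------------------------------------------------------------
# CSV I/O

def read_cohort(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    criteria: str = "NICE",
) -> CohortTable:
    """Read a delimited cohort file into a :class:`CohortTable`.

    ``dialect`` maps file column headers to canonical names, so arbitrary
    CSV layouts can be adapted without code changes.  Empty cells, ``NA``
    and ``NaN`` are missing; any other unparseable numeric cell also becomes
    missing, with a warning counting the coercions.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False,
                         na_values=list(MISSING_MARKERS), skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file (no header row)") from None
    if dialect:
        df = df.rename(columns=dict(dialect))

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s) {', '.join(missing)}"
        )

    n_bad = 0
    for col in df.columns:
        if col in NUMERIC_COLUMNS or col in FLAG_COLUMNS:
            raw_present = df[col].notna()
            df[col] = pd.to_numeric(df[col], errors="coerce")
            n_bad += int((raw_present & df[col].isna()).sum())
    if n_bad:
        logger.warning("%s: %d unparseable numeric cell(s) set to missing",
                       path, n_bad)
    return CohortTable(df, criteria=criteria)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write the cohort back to CSV (UTF-8, '.' decimal, empty cell = missing)."""
    table.data.to_csv(path, index=False)


def audit_bmi(table: CohortTable, tol: float = 0.05) -> pd.Series:
    """Flag rows where recorded BMI disagrees with weight/height^2 by > tol.

    Returns a boolean Series (True = inconsistent); rows with any of the
    three fields missing are False.  Audit-grade data check only — nothing
    is modified.
    """
    d = table.data
    needed = {"bmi", "height", "weight"}
    if not needed.issubset(d.columns):
        return pd.Series(False, index=d.index)
    derived = d["weight"] / d["height"] ** 2
    ok = d[list(needed)].notna().all(axis=1)
    rel = (d["bmi"] - derived).abs() / derived
    return (rel > tol) & ok


def one_hot_encode(
    df: pd.DataFrame, features: Iterable[str]
) -> pd.DataFrame:
    """Design matrix for the given features: numerics as floats, flags as
    0/1, categoricals one-hot with the first level as reference."""
    cols: list[pd.Series] = []
    for f in features:
        if f not in df.columns:
            raise KeyError(f"feature {f!r} not in table")
        if f in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[f]
            cat = pd.Categorical(df[f], categories=levels)
            for level in levels[1:]:  # first level = reference
                s = pd.Series((cat == level).astype(float), index=df.index,
                              name=f"{f}_{level}")
                s[pd.isna(cat)] = float("nan")
                cols.append(s)
        else:
            cols.append(pd.to_numeric(df[f], errors="coerce").rename(f))
    return pd.concat(cols, axis=1)
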
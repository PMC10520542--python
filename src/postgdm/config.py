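"""Run configuration: a YAML-serializable bundle of every knob the
pipeline exposes, and the seeded end-to-end driver."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import info_diagnostics, nested_cv, risk_score, utility
from .cohort import CohortTable, read_cohort, write_cohort
from .nested_cv import CVConfig, ModelSpec
from .synthetic import GeneratorSpec, generate_cohort
from .utility import PowerSpec

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run bit-for-bit."""

    seed: int = 0
    input: str | None = None              # CSV path, or None to simulate
    dialect: Mapping[str, str] | None = None
    generator: Mapping[str, Any] = field(default_factory=dict)
    criteria: str = "NICE"
    features: Sequence[str] | None = None
    model: Mapping[str, Any] = field(default_factory=dict)
    cv: Mapping[str, Any] = field(default_factory=dict)
    score_features: Sequence[str] = ("a_fg", "a_hba1c")
    sensitivities: Sequence[float] = risk_score.DEFAULT_SENSITIVITIES
    dca_n_total: int | None = None
    power: Mapping[str, float] = field(default_factory=lambda: {
        "d": 0.681, "alpha": 0.05, "power": 0.90, "ratio": 0.305})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    # -- derived objects ----------------------------------------------------
    def generator_spec(self) -> GeneratorSpec:
        kw = dict(self.generator)
        kw.setdefault("seed", self.seed)
        if "coefficients" in kw:
            kw["coefficients"] = tuple(kw["coefficients"])
        return GeneratorSpec(**kw)

    def model_spec(self) -> ModelSpec:
        return ModelSpec(**dict(self.model))

    def cv_config(self) -> CVConfig:
        kw = dict(self.cv)
        kw.setdefault("seed", self.seed)
        return CVConfig(**kw)

    def power_spec(self) -> PowerSpec:
        return PowerSpec(**dict(self.power))

    def load_table(self) -> CohortTable:
        # exactly one of input / generator; an absent generator means
        # "simulate with defaults" only when input is also absent
        if self.input is not None and self.generator:
            raise ValueError("config must give exactly one of input/generator")
        if self.input is not None:
            return read_cohort(self.input, dialect=self.dialect,
                               criteria=self.criteria)
        table = generate_cohort(self.generator_spec())
        if self.criteria != "NICE":
            table.relabel(self.criteria)
        return table


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute every stage and write the report bundle.

    Stages: ingest/simulate -> label -> nested CV -> final model ->
    cut-point scan -> decision curve -> power, each stage's failure
    reported with its name.  Re-running with the same config is
    bit-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    @stage("ingest")
    def table() -> CohortTable:
        t = config.load_table()
        write_cohort(t, outdir / "cohort.csv")
        artifacts["cohort"] = outdir / "cohort.csv"
        return t

    @stage("label")
    def _check_labels():
        statuses = set(table.status)
        if statuses == {"unlabelled"}:
            raise ValueError("no postpartum measures: every row unlabelled "
                             "(need p_fg / p_pg / p_hba1c)")

    @stage("evaluate")
    def preds():
        p = nested_cv.nested_cv_evaluate(
            table, config.model_spec(), config.cv_config(), config.features)
        p.frame.to_csv(outdir / "predictions.csv", index=False)
        artifacts["predictions"] = outdir / "predictions.csv"
        roc = nested_cv.roc_auc(p)
        pd.DataFrame({"threshold": roc.thresholds, "fpr": roc.fpr,
                      "tpr": roc.tpr}).to_csv(outdir / "roc.csv", index=False)
        artifacts["roc"] = outdir / "roc.csv"
        metrics = {"auc": roc.auc, "brier": nested_cv.brier(p),
                   "n": len(p), "prevalence": float(p.labels.mean())}
        if p.selected_features is not None:
            stab = nested_cv.feature_stability(p)
            metrics["feature_stability"] = {
                r.feature: {"count": int(r.count), "fraction": float(r.fraction)}
                for r in stab.itertuples()}
        (outdir / "metrics.json").write_text(
            json.dumps(metrics, indent=2, sort_keys=True) + "\n")
        artifacts["metrics"] = outdir / "metrics.json"
        return p

    @stage("final_model")
    def model():
        m = risk_score.fit_final_model(
            table, config.model_spec(), config.cv_config(),
            config.score_features)
        m.to_json(outdir / "model.json")
        artifacts["model"] = outdir / "model.json"
        return m

    @stage("cutpoints")
    def _cutpoints():
        rows, sel = info_diagnostics.scan_cutpoints(preds)
        rows.to_csv(outdir / "cutpoint_table.csv", index=False)
        artifacts["cutpoint_table"] = outdir / "cutpoint_table.csv"
        ops = risk_score.operating_points(preds, config.sensitivities)
        payload = {
            "c_in": sel.c_in, "d_in": sel.d_in,
            "c_out": sel.c_out, "d_out": sel.d_out,
            "c_in_out": sel.c_in_out, "tkl_max": sel.tkl_max,
            "operating_points": [r.as_dict() for r in ops]}
        (outdir / "cutpoints.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")
        artifacts["cutpoints"] = outdir / "cutpoints.json"

    @stage("dca")
    def _dca():
        utility.net_benefit(preds, n_total=config.dca_n_total).to_csv(
            outdir / "dca.csv", index=False)
        artifacts["dca"] = outdir / "dca.csv"

    @stage("power")
    def _power():
        spec = config.power_spec()
        n1, n2 = utility.solve_sample_size(spec)
        payload = {"d": spec.d, "alpha": spec.alpha, "target_power": spec.power,
                   "ratio": spec.ratio, "n1": n1, "n2": n2,
                   "total": n1 + n2,
                   "achieved_power": utility.power_at(spec, n1)}
        (outdir / "power.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
        artifacts["power"] = outdir / "power.json"

    @stage("run_log")
    def _log():
        log = {"config": dataclasses.asdict(config),
               "chosen_hyperparameters": [
                   {k: float(v) if isinstance(v, (int, float, np.floating))
                    else v for k, v in p.items()}
                   for p in preds.chosen_params],
               "artifact_digests": {k: _digest(v)
                                    for k, v in sorted(artifacts.items())}}
        (outdir / "run_log.json").write_text(
            json.dumps(log, indent=2, sort_keys=True, default=str) + "\n")
        artifacts["run_log"] = outdir / "run_log.json"

    return artifacts
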
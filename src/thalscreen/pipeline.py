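"""End-to-end orchestration: data -> indices -> approximations -> reducts
-> rules -> predictions -> metrics, with every artifact written to disk
under deterministic names.

A :class:`PipelineConfig` is a single YAML-serializable document; every
run logs the resolved config and a content digest of its input, so two
runs with the same config and data produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .classifier import DominanceRuleClassifier, classify_batch
from .dominance import approximation_report
from .evaluation import confusion_and_metrics, roc_pr, split
from .indices import add_index_columns
from .ingest import build_decision_table, clean, read_cbc_csv
from .reducts import find_reducts
from .rules import serialize_rules
from .simulate import SimulationConfig, generate_dataset

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("thalscreen")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serializable to one YAML document."""

    output_dir: str = "pipeline_out"
    input_csv: Optional[str] = None         # mutually exclusive with simulation
    simulation: Optional[dict] = None       # SimulationConfig fields
    criteria: Optional[list[str]] = None    # None: all available columns
    directions: dict | str = "gain"
    with_indices: bool = True
    reduct_strategy: Optional[str] = None   # None | greedy | exhaustive
    consistency: float = 1.0
    train_fraction: float = 0.8
    seed: int = 0
    verbosity: str = "INFO"

    def validate(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise ValueError("exactly one of input_csv / simulation must be set")
        if not 0 < self.consistency <= 1:
            raise ValueError("consistency must lie in (0, 1]")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.reduct_strategy not in (None, "greedy", "exhaustive"):
            raise ValueError(f"unknown reduct strategy {self.reduct_strategy!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**(yaml.safe_load(text) or {}))


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return run

    return wrap


@_stage("load")
def _load(config: PipelineConfig) -> pd.DataFrame:
    if config.input_csv is not None:
        raw = read_cbc_csv(config.input_csv)
        table, report = clean(raw)
        log.info("cleaning: %s", report.to_dict())
        return table
    sim = SimulationConfig(**config.simulation)
    return generate_dataset(sim)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full screening pipeline; returns artifact paths/objects.

    Stages: load (ingest or simulate) -> index computation -> dominance
    approximations -> optional reduct search -> rule induction on the
    training split -> classification of the test split -> metrics.
    On a stage failure the partial artifacts are kept and a failure
    marker file names the failed stage.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out)
    except PipelineError as exc:
        (out / "FAILED").write_text(f"{exc.stage}: {exc.cause}\n")
        raise


def _run(config: PipelineConfig, out: Path) -> dict:
    table = _load(config)
    digest = hashlib.sha256(table.to_csv().encode()).hexdigest()
    log.info("input digest sha256=%s rows=%d", digest, len(table))
    (out / "config.yaml").write_text(config.to_yaml())

    @_stage("indices")
    def stage_indices():
        frame = add_index_columns(table.drop(columns=["decision"]))
        frame["decision"] = table["decision"]
        frame.to_csv(out / "indices.csv")
        return frame

    frame = stage_indices() if config.with_indices else table.copy()

    feature_cols = (
        list(config.criteria)
        if config.criteria is not None
        else [c for c in frame.columns if c != "decision"]
    )
    if isinstance(config.directions, str):
        directions = {c: config.directions for c in feature_cols}
    else:
        directions = dict(config.directions)

    @_stage("approximations")
    def stage_approx():
        dt = build_decision_table(frame, directions, criteria=feature_cols)
        report = approximation_report(dt)
        (out / "approximations.json").write_text(json.dumps(report.to_dict(), indent=2))
        return dt, report

    dt, approx = stage_approx()

    reduct_cols = feature_cols
    reducts = None
    if config.reduct_strategy is not None:

        @_stage("reducts")
        def stage_reducts():
            found = find_reducts(dt, strategy=config.reduct_strategy)
            (out / "reducts.json").write_text(
                json.dumps(
                    [r.to_dict(strategy=config.reduct_strategy) for r in found],
                    indent=2,
                )
            )
            return found

        reducts = stage_reducts()
        if reducts:
            reduct_cols = list(reducts[0].criteria)

    @_stage("rules")
    def stage_rules():
        train, test = split(frame, config.train_fraction, seed=config.seed)
        clf = DominanceRuleClassifier(
            directions={c: directions[c] for c in reduct_cols},
            consistency=config.consistency,
            criteria=reduct_cols,
        )
        clf.fit(train[reduct_cols], train["decision"].to_numpy())
        (out / "rules.txt").write_text(serialize_rules(clf.ruleset_))
        return train, test, clf

    train, test, clf = stage_rules()

    @_stage("classification")
    def stage_classify():
        predictions, summary = classify_batch(clf.ruleset_, test[reduct_cols])
        rows = [
            {
                "patient_id": p.object_id,
                "predicted_class": p.predicted_class,
                "score": p.score,
                "fired_rules": ";".join(map(str, p.fired_rules)),
            }
            for p in predictions
        ]
        pd.DataFrame(rows).to_csv(out / "predictions.csv", index=False)
        return predictions, summary

    predictions, summary = stage_classify()

    @_stage("evaluation")
    def stage_evaluate():
        y_true = test["decision"].to_numpy()
        y_pred = np.array([p.predicted_class for p in predictions])
        scores = np.array([p.score for p in predictions])
        metrics = confusion_and_metrics(y_true, y_pred)
        if len(np.unique(y_true)) == 2:
            metrics.auc = roc_pr(y_true, scores)["roc_auc"]
        (out / "metrics.json").write_text(json.dumps(metrics.to_dict(), indent=2))
        return metrics

    metrics = stage_evaluate()

    summary_doc = {
        "input_digest": digest,
        "n_rows": len(table),
        "gamma": approx.gamma,
        "n_rules": len(clf.ruleset_.rules),
        "criteria_used": reduct_cols,
        "test_accuracy": metrics.accuracy,
        "test_auc": metrics.auc,
    }
    (out / "run_summary.json").write_text(json.dumps(summary_doc, indent=2))
    return {
        "output_dir": str(out),
        "table": table,
        "frame": frame,
        "decision_table": dt,
        "approximations": approx,
        "reducts": reducts,
        "classifier": clf,
        "predictions": predictions,
        "metrics": metrics,
        "summary": summary_doc,
    }
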
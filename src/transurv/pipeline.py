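"""End-to-end experiment pipeline: early-endpoint training, dual validation.

Reproduces the study design around the transduction wrapper: fit an
early-endpoint model (Cox and/or SVRc, with and without transduction) on a
training cohort, freeze the stratification threshold on training scores,
then evaluate concordance, sensitivity, specificity and the combined
criterion on (a) the training set, (b) an early-endpoint validation cohort
and (c) a late-endpoint validation cohort — always against original
observed times.  Also reports per-feature weights, normalized by the
largest-magnitude weight so features are comparable across models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cox import CoxPH
from .data import SurvivalData
from .model import SurvivalResults
from .svrc import SVRc, SvrcParams
from .transduction import (
    TransductionConfig,
    TransductiveModel,
    report_evaluation,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "normalize_weights", "make_learner"]


def make_learner(name: str, svrc_params: SvrcParams | None = None):
    """Learner factory by name ('cox' or 'svrc') with fixed hyperparameters."""
    if name == "cox":
        return lambda d: CoxPH(d).fit()
    if name == "svrc":
        return lambda d: SVRc(d, params=svrc_params).fit()
    raise ValueError(f"unknown learner {name!r} (expected 'cox' or 'svrc')")


def normalize_weights(weights, rule: str = "max_abs") -> pd.Series:
    """Divide weights by the highest-weighted feature, preserving sign.

    ``rule='max_abs'`` (default) divides by the maximum absolute weight, so
    the largest-magnitude feature maps to ±1.  ``rule='max_positive'``
    divides by the largest positive weight (normalized magnitudes can then
    exceed 1); kept for comparability with reports using that convention.
    """
    w = pd.Series(weights, dtype=float)
    if w.empty:
        raise ValueError("empty weight vector")
    if rule == "max_abs":
        denom = w.abs().max()
        if denom == 0:
            raise ValueError("all-zero weight vector cannot be normalized")
    elif rule == "max_positive":
        if not (w > 0).any():
            raise ValueError("no positive weight to normalize by under 'max_positive'")
        denom = w[w > 0].max()
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return w / denom


@dataclass
class ExperimentConfig:
    """One training/validation experiment over learner x transduction variants.

    ``train``/``valid_early``/``valid_late`` may be SurvivalData instances
    or CSV paths (loaded with the given column names).  Validation cohorts
    must share the training feature schema; the early and late validation
    endpoints are typically two outcome columns over the same patients.
    """

    train: SurvivalData | str
    valid_early: SurvivalData | str | None = None
    valid_late: SurvivalData | str | None = None
    learners: tuple = ("svrc", "cox")
    transduction: tuple = (False, True)
    time_point: float = 60.0
    grid_size: int = 10
    svrc_params: SvrcParams | None = None
    time_column: str = "time"
    event_column: str = "event"
    late_time_column: str = "time"
    late_event_column: str = "event"
    weight_rule: str = "max_abs"
    seed: int = 0
    outdir: str | None = None


@dataclass
class ExperimentResult:
    """Metrics table, weight report and fitted models for every variant."""

    metrics: pd.DataFrame     # rows (block, metric), one column per variant
    weights: pd.DataFrame     # rows features, columns (variant, original|normalized)
    models: dict = field(repr=False, default_factory=dict)
    config: ExperimentConfig | None = field(repr=False, default=None)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv")
        payload = {
            variant: {
                block: self.metrics[variant].loc[block].to_dict()
                for block in self.metrics.index.get_level_values("block").unique()
            }
            for variant in self.metrics.columns
        }
        with open(out / "metrics.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
        self.weights.to_csv(out / "weights.csv")
        for name, model in self.models.items():
            res = model.results if hasattr(model, "results") else model
            if hasattr(res, "to_json"):
                (out / f"model_{name.replace(' ', '_')}.json").write_text(res.to_json())


def _as_data(obj, time_column, event_column) -> SurvivalData | None:
    if obj is None or isinstance(obj, SurvivalData):
        return obj
    return SurvivalData.from_csv(obj, time_column=time_column, event_column=event_column)


def _variant_name(learner: str, transduce: bool) -> str:
    return f"{learner}+transduction" if transduce else learner


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run every requested (learner, transduction) variant and collect reports.

    Training and validation stay strictly separate: models and thresholds
    are frozen on training data before any validation metric is computed,
    and validation metrics never depend on transduced times.
    """
    train = _as_data(cfg.train, cfg.time_column, cfg.event_column)
    valid_early = _as_data(cfg.valid_early, cfg.time_column, cfg.event_column)
    valid_late = _as_data(cfg.valid_late, cfg.late_time_column, cfg.late_event_column)
    train.require_events()

    metric_cols: dict[str, pd.Series] = {}
    weight_cols: dict[tuple, pd.Series] = {}
    models: dict[str, SurvivalResults] = {}
    for learner_name in cfg.learners:
        factory = make_learner(learner_name, cfg.svrc_params)
        for transduce in cfg.transduction:
            name = _variant_name(learner_name, transduce)
            if transduce:
                tcfg = TransductionConfig(
                    learner=factory,
                    time_point=cfg.time_point,
                    grid_size=cfg.grid_size,
                    seed=cfg.seed,
                )
                fitted: SurvivalResults = TransductiveModel(train, tcfg).fit()
            else:
                fitted = factory(train)
            models[name] = fitted
            table = report_evaluation(train, valid_early, valid_late, fitted, cfg.time_point)
            metric_cols[name] = table.unstack().reorder_levels([0, 1])
            w = fitted.weights
            weight_cols[(name, "original")] = w
            weight_cols[(name, "normalized")] = normalize_weights(w, cfg.weight_rule)

    metrics = pd.DataFrame(metric_cols)
    metrics.index.names = ["block", "metric"]
    weights = pd.DataFrame(weight_cols)
    weights.columns = pd.MultiIndex.from_tuples(weights.columns, names=["variant", "weight"])
    result = ExperimentResult(metrics=metrics, weights=weights, models=models, config=cfg)
    if cfg.outdir is not None:
        result.save(cfg.outdir)
    return result
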
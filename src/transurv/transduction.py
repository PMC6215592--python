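"""Singular transduction of censored survival targets.

A censored time is a lower bound on the unobserved true event time.  The
transduction wrapper treats each censored target as a semi-supervised
regression label: for every censored record it scans candidate target times
on an arithmetic grid from the observed censoring time U_i up to the dataset
maximum T_max, refits the base learner with ONLY that record's target
replaced, and keeps the candidate that maximizes the combined criterion
``CI + sensitivity * specificity`` — always evaluated against the ORIGINAL
observed times and indicators, never against the candidate targets (scoring
on the transduced targets would reward exactly the change being searched and
inflate performance).

Each censored record is transduced independently of the others ("singular"
transduction, linear in the number of censored cases, as opposed to the
exponential joint search over all grid assignments); a final model is then
fit once on the assembled transduced targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .data import SurvivalData
from .exceptions import FitError, TransurvError
from .metrics import evaluate, select_threshold
from .model import SurvivalModel, SurvivalResults

__all__ = [
    "TransductionConfig",
    "TransducedDataset",
    "candidate_grid",
    "transduce_instance",
    "transduce_dataset",
    "report_evaluation",
    "TransductiveModel",
    "TransductionResults",
]

LearnerFactory = Callable[[SurvivalData], SurvivalResults]


@dataclass
class TransductionConfig:
    """Settings of the singular transduction search.

    Parameters
    ----------
    learner : callable SurvivalData -> fitted results
        Base learner factory with fixed hyperparameters, e.g.
        ``lambda d: CoxPH(d).fit()``.
    time_point : float
        Evaluation time point for the sensitivity/specificity term of the
        criterion (thresholds are re-selected on training data per fit).
    grid_size : int, default 10
        Number of increments m; each censored record is offered m + 1
        equally spaced candidates from U_i to T_max inclusive.
    seed : int, optional
        Seed forwarded to stochastic learner internals (none of the built-in
        learners are stochastic; kept for user-supplied learners).
    """

    learner: LearnerFactory
    time_point: float
    grid_size: int = 10
    seed: int | None = None

    def __post_init__(self):
        if self.grid_size < 1:
            raise ValueError(f"grid_size must be >= 1, got {self.grid_size}")
        if not self.time_point > 0:
            raise ValueError(f"time_point must be positive, got {self.time_point}")


@dataclass
class TransducedDataset:
    """Original dataset plus transduced targets and the search provenance.

    Invariants (validated on construction): events keep their observed time
    exactly; every censored target satisfies ``U_i <= U_hat_i <= T_max``.
    """

    base: SurvivalData
    transduced_times: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        t_hat = np.asarray(self.transduced_times, dtype=float)
        if t_hat.shape[0] != self.base.n:
            raise ValueError("transduced_times length mismatch")
        ev = self.base.event == 1
        if not np.array_equal(t_hat[ev], self.base.time[ev]):
            raise TransurvError("transduction altered an event time")
        cens = ~ev
        if np.any(t_hat[cens] < self.base.time[cens]) or np.any(
            t_hat[cens] > self.base.t_max + 1e-12
        ):
            raise TransurvError("transduced time outside [U_i, T_max]")
        self.transduced_times = t_hat

    @property
    def data(self) -> SurvivalData:
        """Dataset with transduced times (original indicators retained)."""
        return self.base.with_times(self.transduced_times)

    def trace_frame(self) -> pd.DataFrame:
        """Long-format (record, candidate, criterion) table of the search."""
        rows = [
            {"record": p["index"], "candidate": c, "criterion": crit, "chosen": c == p["chosen"]}
            for p in self.provenance
            for c, crit in zip(p["candidates"], p["criteria"])
        ]
        return pd.DataFrame(rows, columns=["record", "candidate", "criterion", "chosen"])


def candidate_grid(u: float, t_max: float, m: int) -> np.ndarray:
    """m + 1 equally spaced candidate times from ``u`` to ``t_max`` inclusive.

    The first candidate is always the unmodified observed time, so the
    search can never do worse than keeping the censored time.  When
    ``u == t_max`` the grid collapses to the single candidate ``u``.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if u > t_max:
        raise ValueError(f"censored time {u} exceeds t_max {t_max}")
    if u == t_max:
        return np.array([u])
    return np.linspace(u, t_max, m + 1)


def _training_criterion(
    original: SurvivalData, scores: np.ndarray, time_point: float
) -> float:
    thr = select_threshold(original, scores, time_point)
    return evaluate(original, scores, time_point, thr).criterion


def transduce_instance(
    data: SurvivalData, i: int, cfg: TransductionConfig
) -> tuple[float, float, dict]:
    """Best transduced target for censored record ``i``.

    For every candidate u on the grid, a training copy with only record i's
    target set to u is fit and the criterion is computed on the ORIGINAL
    times; ties break toward the smallest candidate (minimal departure from
    the observed censoring time).  Candidates whose fit fails are skipped
    with a warning.

    Returns ``(best_time, best_criterion, trace)``.
    """
    if data.event[i] != 0:
        raise ValueError(f"record {i} is an event; only censored targets are transduced")
    grid = candidate_grid(float(data.time[i]), data.t_max, cfg.grid_size)
    criteria = np.full(grid.shape, np.nan)
    for k, u in enumerate(grid):
        try:
            results = cfg.learner(data.with_time(i, u))
            scores = results.predict(data)
            criteria[k] = _training_criterion(data, scores, cfg.time_point)
        except (FitError, np.linalg.LinAlgError) as exc:
            warnings.warn(
                f"candidate {u:g} for record {i} skipped (fit failed: {exc})",
                UserWarning,
            )
    if np.all(np.isnan(criteria)):
        raise FitError(f"every candidate fit failed for censored record {i}")
    best_k = int(np.nanargmax(criteria))  # first max -> smallest candidate on ties
    trace = {
        "index": i,
        "candidates": grid.tolist(),
        "criteria": criteria.tolist(),
        "chosen": float(grid[best_k]),
    }
    return float(grid[best_k]), float(criteria[best_k]), trace


def transduce_dataset(
    data: SurvivalData, cfg: TransductionConfig
) -> tuple[TransducedDataset, SurvivalResults]:
    """Singular transduction of every censored record, plus the final fit.

    Each censored record is searched against the original dataset — the
    selections never see each other, which is what keeps the cost linear in
    the number of censored cases.  The final learner is fit once on the
    assembled transduced targets (original indicators retained, so learners
    that use censoring status, like SVRc, still see it).
    """
    data.require_events()
    t_hat = data.time.astype(float).copy()
    provenance = []
    for i in np.where(data.event == 0)[0]:
        best_time, _, trace = transduce_instance(data, int(i), cfg)
        t_hat[i] = best_time
        provenance.append(trace)
    transduced = TransducedDataset(base=data, transduced_times=t_hat, provenance=provenance)
    final = cfg.learner(transduced.data)
    return transduced, final


def report_evaluation(
    d_train: SurvivalData,
    d_valid_early: SurvivalData | None,
    d_valid_late: SurvivalData | None,
    results: SurvivalResults,
    time_point: float,
) -> pd.DataFrame:
    """CI / sensitivity / specificity / criterion on train and validation sets.

    The stratification threshold is selected on the training scores and
    frozen for both validation blocks; all metrics use original observed
    times (transduced targets never enter an accuracy assessment).
    """
    blocks: dict[str, SurvivalData] = {"training": d_train}
    if d_valid_early is not None:
        blocks["validation_early"] = d_valid_early
    if d_valid_late is not None:
        blocks["validation_late"] = d_valid_late
    for name, ds in blocks.items():
        if ds.n_features != d_train.n_features or ds.feature_names != d_train.feature_names:
            raise ValueError(f"{name} feature schema differs from training schema")
    train_scores = results.predict(d_train)
    threshold = select_threshold(d_train, train_scores, time_point)
    table = {}
    for name, ds in blocks.items():
        scores = train_scores if ds is d_train else results.predict(ds)
        ev = evaluate(ds, scores, time_point, threshold)
        table[name] = {
            "ci": ev.ci,
            "sensitivity": ev.sensitivity,
            "specificity": ev.specificity,
            "criterion": ev.criterion,
        }
    return pd.DataFrame(table)


class TransductiveModel(SurvivalModel):
    """Transduction wrapper presented as a model over a training dataset.

    ``fit()`` runs the singular transduction search and the final refit,
    returning :class:`TransductionResults`.
    """

    def __init__(self, data: SurvivalData, config: TransductionConfig):
        super().__init__(data)
        self.config = config

    def fit(self) -> "TransductionResults":
        cfg = self.config
        baseline_results = cfg.learner(self.data)
        baseline_criterion = _training_criterion(
            self.data, baseline_results.predict(self.data), cfg.time_point
        )
        transduced, final = transduce_dataset(self.data, cfg)
        final_criterion = _training_criterion(
            self.data, final.predict(self.data), cfg.time_point
        )
        return TransductionResults(
            model=self,
            transduced=transduced,
            results=final,
            baseline_criterion=baseline_criterion,
            criterion=final_criterion,
        )


@dataclass
class TransductionResults(SurvivalResults):
    """Transduced dataset plus the final learner fit on it.

    ``baseline_criterion`` is the training criterion of the un-transduced
    fit and ``criterion`` that of the combined refit, both on original
    times.  The combined refit is not guaranteed to beat the baseline (each
    target was optimized in isolation); both are reported so the comparison
    is visible.
    """

    model: TransductiveModel
    transduced: TransducedDataset
    results: SurvivalResults
    baseline_criterion: float
    criterion: float

    def predict(self, data: SurvivalData) -> np.ndarray:
        return self.results.predict(data)

    @property
    def weights(self) -> pd.Series:
        return self.results.weights

    def summary(self) -> pd.DataFrame:
        return self.results.summary()
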
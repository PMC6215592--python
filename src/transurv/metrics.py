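"""Evaluation metrics for censored survival predictions.

All scores are *survival-time-oriented*: a larger score means a longer
predicted survival.  Three quantities are computed:

* the concordance index (CI) over Harrell-comparable pairs,
* sensitivity/specificity of a high-risk / low-risk stratification at a
  fixed time point (censored records with earlier times are excluded),
* the combined criterion ``CI + sensitivity * specificity`` used to rank
  models and to drive the transduction search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .data import SurvivalData
from .exceptions import MetricUndefinedError, StratificationUndefinedError

__all__ = [
    "concordance_index",
    "stratify",
    "select_threshold",
    "criterion",
    "evaluate",
    "StratificationResult",
    "EvaluationResult",
]

POSITIVE, NEGATIVE, EXCLUDED = "positive", "negative", "excluded"


def _check_scores(data: SurvivalData, scores) -> np.ndarray:
    s = np.asarray(scores, dtype=float).ravel()
    if s.shape[0] != data.n:
        raise ValueError(f"{s.shape[0]} scores for {data.n} records")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores contain non-finite values")
    return s


def concordance_index(data: SurvivalData, scores) -> float:
    """Harrell's concordance index of survival-oriented scores.

    Comparable pairs are (i, j) with ``U_i < U_j`` and ``delta_i = 1``, plus
    tied-time pairs ``U_i = U_j`` where i is an event and j is censored.  A
    pair is concordant when the shorter-lived record has the smaller score
    (``s_i < s_j``); tied scores receive credit 0.5.  Tied event times are
    not comparable to each other.

    Returns a value in [0, 1]; 0.5 means no rank association.
    """
    s = _check_scores(data, scores)
    t, e = data.time, data.event
    ev = e[:, None] == 1
    comparable = ((t[:, None] < t[None, :]) & ev) | (
        (t[:, None] == t[None, :]) & ev & (e[None, :] == 0)
    )
    n_comp = comparable.sum()
    if n_comp == 0:
        raise MetricUndefinedError("no comparable pairs; concordance index undefined")
    concordant = comparable & (s[:, None] < s[None, :])
    tied = comparable & (s[:, None] == s[None, :])
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


@dataclass(frozen=True)
class StratificationResult:
    """High/low-risk stratification of a cohort at a fixed time point.

    ``labels[i]`` is 'positive' (event at or before the time point),
    'negative' (observed beyond the time point) or 'excluded' (censored at
    or before it — outcome status unknowable).  A record is *predicted*
    positive (high risk) when its survival-oriented score falls below the
    threshold.
    """

    time_point: float
    threshold: float
    labels: tuple
    sensitivity: float
    specificity: float

    @property
    def n_positive(self) -> int:
        return self.labels.count(POSITIVE)

    @property
    def n_negative(self) -> int:
        return self.labels.count(NEGATIVE)

    @property
    def n_excluded(self) -> int:
        return self.labels.count(EXCLUDED)


def _strata_masks(data: SurvivalData, time_point: float):
    if not time_point > 0:
        raise ValueError(f"time_point must be positive, got {time_point}")
    t, e = data.time, data.event
    pos = (e == 1) & (t <= time_point)
    neg = t > time_point
    excl = (e == 0) & (t <= time_point)
    return pos, neg, excl


def stratify(
    data: SurvivalData, scores, time_point: float, threshold: float
) -> StratificationResult:
    """Stratify records at ``time_point`` and score the dichotomized model.

    Sensitivity = TP/(TP+FN) over actual positives, specificity =
    TN/(TN+FP) over actual negatives; excluded records enter neither.
    Raises :class:`StratificationUndefinedError` when either actual class
    is empty rather than silently returning 0.
    """
    s = _check_scores(data, scores)
    pos, neg, excl = _strata_masks(data, time_point)
    if not pos.any():
        raise StratificationUndefinedError(
            f"no events at or before time point {time_point}; sensitivity undefined"
        )
    if not neg.any():
        raise StratificationUndefinedError(
            f"no records observed beyond time point {time_point}; specificity undefined"
        )
    pred_pos = s < threshold
    sens = float(pred_pos[pos].sum() / pos.sum())
    spec = float((~pred_pos[neg]).sum() / neg.sum())
    labels = np.where(pos, POSITIVE, np.where(neg, NEGATIVE, EXCLUDED))
    assert excl.sum() + pos.sum() + neg.sum() == data.n
    return StratificationResult(
        time_point=float(time_point),
        threshold=float(threshold),
        labels=tuple(labels.tolist()),
        sensitivity=sens,
        specificity=spec,
    )


def select_threshold(data: SurvivalData, scores, time_point: float) -> float:
    """Score cutoff maximizing sensitivity x specificity on the given data.

    Candidates are midpoints of adjacent sorted unique scores; ties are
    broken toward the smaller cutoff.  Intended to be run on *training*
    data and frozen before validation.
    """
    s = _check_scores(data, scores)
    uniq = np.unique(s)
    if uniq.size == 1:
        warnings.warn(
            "all scores identical; threshold selection is degenerate", UserWarning
        )
        candidates = np.array([uniq[0]])
    else:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_thr, best_prod = None, -1.0
    for thr in candidates:
        res = stratify(data, s, time_point, thr)
        prod = res.sensitivity * res.specificity
        if prod > best_prod + 1e-15:
            best_thr, best_prod = float(thr), prod
    return best_thr


def criterion(ci: float, sensitivity: float, specificity: float) -> float:
    """Combined model-selection criterion ``CI + sensitivity * specificity``.

    Each argument must lie in [0, 1]; the result lies in [0, 2].
    """
    for name, v in (("ci", ci), ("sensitivity", sensitivity), ("specificity", specificity)):
        if not (np.isfinite(v) and 0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return float(ci + sensitivity * specificity)


@dataclass(frozen=True)
class EvaluationResult:
    ci: float
    sensitivity: float
    specificity: float
    criterion: float
    threshold: float
    time_point: float

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(
    data: SurvivalData, scores, time_point: float, threshold: float
) -> EvaluationResult:
    """Single evaluation entry point: CI, sensitivity, specificity, criterion.

    This bundle (computed against the *original* observed times) is what the
    transduction search maximizes and what the pipeline reports.
    """
    s = _check_scores(data, scores)
    ci = concordance_index(data, s)
    strat = stratify(data, s, time_point, threshold)
    return EvaluationResult(
        ci=ci,
        sensitivity=strat.sensitivity,
        specificity=strat.specificity,
        criterion=criterion(ci, strat.sensitivity, strat.specificity),
        threshold=float(threshold),
        time_point=float(time_point),
    )
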
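"""Base learner contract shared by every survival model in the package.

A model is constructed from a :class:`~transurv.data.SurvivalData` instance;
``fit()`` returns a results object that can

* ``predict(data)`` survival-time-oriented scores (larger = longer survival),
* expose per-feature ``weights``,
* render a ``summary()`` table.

The transduction wrapper accepts anything honouring this contract.
"""

from __future__ import annotations

import abc

import numpy as np
import pandas as pd

from .data import SurvivalData

__all__ = ["SurvivalModel", "SurvivalResults"]


class SurvivalModel(abc.ABC):
    """A survival model bound to one training dataset."""

    def __init__(self, data: SurvivalData):
        if not isinstance(data, SurvivalData):
            raise TypeError("data must be a SurvivalData instance")
        self.data = data

    @abc.abstractmethod
    def fit(self, **kwargs) -> "SurvivalResults":
        """Estimate the model; returns a results object."""


class SurvivalResults(abc.ABC):
    """Fitted-model interface used by metrics, transduction and the pipeline."""

    @abc.abstractmethod
    def predict(self, data: SurvivalData) -> np.ndarray:
        """Survival-oriented scores, one per record of ``data``."""

    @property
    @abc.abstractmethod
    def weights(self) -> pd.Series:
        """Per-feature weights, labeled by feature name."""

    @abc.abstractmethod
    def summary(self) -> pd.DataFrame:
        """Human-readable estimate table."""
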
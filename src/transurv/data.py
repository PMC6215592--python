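"""Right-censored survival data container and CSV I/O.

A survival dataset holds, per patient, a vector of ``d`` numeric covariates,
an observed time ``U_i`` and an event indicator ``delta_i``.  For an event
(``delta_i = 1``) the observed time is the true event time; for a censored
record (``delta_i = 0``) it is the censoring time, a lower bound on the
unobserved true time.  The latent true/censoring times are never stored here
— only their observable minimum.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ColumnConfigurationError, DataValidationError

__all__ = ["SurvivalData", "load_dataset", "summarize_dataset", "Standardizer"]


class SurvivalData:
    """Immutable container for a right-censored survival dataset.

    Parameters
    ----------
    X : array-like, shape (n, d)
        Numeric covariates.  Must be finite; missing values are rejected,
        not imputed.
    time : array-like, shape (n,)
        Observed times ``U_i`` (nonnegative; unit-agnostic).
    event : array-like, shape (n,)
        Event indicators ``delta_i`` in {0, 1} (1 = event, 0 = censored).
    feature_names : sequence of str, optional
        Labels for the ``d`` covariates; defaults to ``x0..x{d-1}``.

    Notes
    -----
    Construction permits a dataset with zero events so that degenerate
    endpoints (e.g. a late endpoint nobody reached) are representable;
    every model fit and the CSV loader reject such datasets.
    """

    def __init__(self, X, time, event, feature_names: Sequence[str] | None = None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        time = np.asarray(time, dtype=float).ravel()
        event_arr = np.asarray(event)
        n = X.shape[0]
        if time.shape[0] != n or event_arr.shape[0] != n:
            raise DataValidationError(
                f"length mismatch: {n} feature rows, {time.shape[0]} times, "
                f"{event_arr.shape[0]} indicators"
            )
        if not np.all(np.isfinite(X)):
            bad = int(np.where(~np.isfinite(X).all(axis=1))[0][0])
            raise DataValidationError(f"non-finite covariate value in row {bad}")
        if not np.all(np.isfinite(time)):
            bad = int(np.where(~np.isfinite(time))[0][0])
            raise DataValidationError(f"non-finite observed time in row {bad}")
        if np.any(time < 0):
            bad = int(np.where(time < 0)[0][0])
            raise DataValidationError(f"negative observed time in row {bad}")
        event_f = np.asarray(event_arr, dtype=float).ravel()
        if not np.all(np.isin(event_f, (0.0, 1.0))):
            bad = int(np.where(~np.isin(event_f, (0.0, 1.0)))[0][0])
            raise DataValidationError(
                f"event indicator must be 0 or 1; row {bad} has {event_arr.ravel()[bad]!r}"
            )
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
        feature_names = [str(f) for f in feature_names]
        if len(feature_names) != X.shape[1]:
            raise DataValidationError(
                f"{len(feature_names)} feature names for {X.shape[1]} features"
            )
        self._X = X
        self._time = time
        self._event = event_f.astype(np.int8)
        self.feature_names = list(feature_names)
        for arr in (self._X, self._time, self._event):
            arr.setflags(write=False)

    # -- basic views ------------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        return self._X

    @property
    def time(self) -> np.ndarray:
        """Observed times U_i."""
        return self._time

    @property
    def event(self) -> np.ndarray:
        """Event indicators delta_i (1 = event, 0 = censored)."""
        return self._event

    @property
    def n(self) -> int:
        return self._X.shape[0]

    @property
    def n_features(self) -> int:
        return self._X.shape[1]

    @property
    def t_max(self) -> float:
        """Maximum observed time over all records (events or censored)."""
        return float(self._time.max()) if self.n else float("nan")

    @property
    def n_events(self) -> int:
        return int(self._event.sum())

    @property
    def event_rate(self) -> float:
        return self.n_events / self.n

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SurvivalData(n={self.n}, d={self.n_features}, "
            f"events={self.n_events} ({100 * self.event_rate:.1f}%), t_max={self.t_max:g})"
        )

    def summary(self) -> dict:
        """n, d, event count, event rate (fraction) and t_max."""
        return {
            "n": self.n,
            "n_features": self.n_features,
            "n_events": self.n_events,
            "event_rate": self.event_rate,
            "t_max": self.t_max,
        }

    def require_events(self) -> None:
        if self.n_events == 0:
            raise DataValidationError("dataset has no events (all records censored)")

    # -- derived datasets -------------------------------------------------
    def with_times(self, new_times) -> "SurvivalData":
        """Copy of the dataset with all observed times replaced (indicators kept)."""
        return SurvivalData(self._X, new_times, self._event, self.feature_names)

    def with_time(self, i: int, t: float) -> "SurvivalData":
        """Copy with only record ``i``'s observed time replaced by ``t``."""
        times = self._time.copy()
        times[i] = t
        return self.with_times(times)

    def subset(self, idx) -> "SurvivalData":
        idx = np.asarray(idx)
        return SurvivalData(self._X[idx], self._time[idx], self._event[idx], self.feature_names)

    # -- I/O --------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_column: str = "time",
        event_column: str = "event",
        feature_columns: Sequence[str] | None = None,
        require_events: bool = True,
    ) -> "SurvivalData":
        for col in (time_column, event_column):
            if col not in df.columns:
                raise ColumnConfigurationError(
                    f"column {col!r} not found (columns: {list(df.columns)})"
                )
        if feature_columns is None:
            feature_columns = [
                c
                for c in df.columns
                if c not in (time_column, event_column)
                and pd.api.types.is_numeric_dtype(df[c])
            ]
        if not feature_columns:
            raise DataValidationError("no numeric feature columns found")
        feat = df[list(feature_columns)]
        if feat.isna().any().any():
            bad = int(np.where(feat.isna().any(axis=1))[0][0])
            raise DataValidationError(
                f"missing covariate value in row {bad}; imputation is not supported"
            )
        ds = cls(
            feat.to_numpy(dtype=float),
            df[time_column].to_numpy(dtype=float),
            df[event_column].to_numpy(),
            feature_names=list(feature_columns),
        )
        if require_events:
            ds.require_events()
        return ds

    @classmethod
    def from_csv(
        cls,
        path,
        time_column: str = "time",
        event_column: str = "event",
        feature_columns: Sequence[str] | None = None,
        require_events: bool = True,
    ) -> "SurvivalData":
        return cls.from_dataframe(
            pd.read_csv(path, float_precision="round_trip"),
            time_column=time_column,
            event_column=event_column,
            feature_columns=feature_columns,
            require_events=require_events,
        )

    def to_dataframe(self, time_column: str = "time", event_column: str = "event") -> pd.DataFrame:
        df = pd.DataFrame(self._X, columns=self.feature_names)
        df[time_column] = self._time
        df[event_column] = self._event.astype(int)
        return df

    def to_csv(self, path, time_column: str = "time", event_column: str = "event") -> None:
        # %.17g preserves float64 exactly, so write->read round-trips bit-for-bit
        self.to_dataframe(time_column, event_column).to_csv(
            path, index=False, float_format="%.17g"
        )


def load_dataset(path, time_column: str = "time", event_column: str = "event") -> SurvivalData:
    """Read a CSV survival dataset (one patient per row, header row required).

    All numeric columns other than the named time/event columns are treated
    as features; row order is preserved.
    """
    return SurvivalData.from_csv(path, time_column=time_column, event_column=event_column)


def summarize_dataset(data: SurvivalData) -> dict:
    """Summary of a dataset: n, d, event count, event rate, t_max."""
    return data.summary()


class Standardizer:
    """Zero-mean / unit-variance feature transform, fit on training data only.

    Zero-variance columns are passed through unscaled (divisor 1) so that a
    constant feature does not produce NaNs; downstream fits warn about it.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
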
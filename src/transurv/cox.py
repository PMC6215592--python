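"""Cox proportional-hazards base learner.

The model assumes the hazard of patient i is ``h_i(t) = h0(t) * exp(b' x_i)``.
Coefficients are estimated by Newton-Raphson on the partial likelihood with
Breslow handling of tied event times.  The baseline hazard ``h0`` is never
estimated: every downstream use (concordance, thresholded stratification)
needs only the rank-preserving linear predictor, from which ``h0`` cancels.

Predicted scores are the *negated* linear predictor ``-b' x_i`` so that, as
everywhere in this package, a larger score means longer predicted survival.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import SurvivalData
from .exceptions import FitError, SeparationWarning
from .model import SurvivalModel, SurvivalResults

__all__ = ["CoxPH", "CoxPHResults", "fit_cox", "predict_cox", "cox_weights"]


def _breslow_quantities(X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray):
    """Log partial likelihood, gradient and information matrix (Breslow ties).

    Censored records contribute to risk sets only up to their censoring time.
    """
    n, d = X.shape
    order = np.argsort(-time, kind="stable")  # descending: accumulate risk sets
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    shift = eta.max() if n else 0.0
    w = np.exp(eta - shift)

    loglik = 0.0
    grad = np.zeros(d)
    info = np.zeros((d, d))
    S0 = 0.0
    S1 = np.zeros(d)
    S2 = np.zeros((d, d))
    i = 0
    while i < n:
        t = ts[i]
        j = i
        while j < n and ts[j] == t:  # absorb all records tied at this time
            S0 += w[j]
            S1 += w[j] * Xs[j]
            S2 += w[j] * np.outer(Xs[j], Xs[j])
            j += 1
        ev = np.arange(i, j)[es[i:j] == 1]
        if ev.size:
            dt = ev.size
            xbar = S1 / S0
            loglik += eta[ev].sum() - dt * (np.log(S0) + shift)
            grad += Xs[ev].sum(axis=0) - dt * xbar
            info += dt * (S2 / S0 - np.outer(xbar, xbar))
        i = j
    return loglik, grad, info


class CoxPH(SurvivalModel):
    """Cox proportional-hazards model for a right-censored dataset.

    Parameters
    ----------
    data : SurvivalData
        Training data; must contain at least one event.
    ridge : float, default 0.0
        Optional L2 penalty on the coefficients, off by default (the plain
        partial likelihood is used).  Intended only as an explicit fallback
        for separation pathologies.

    Features are used on their given scale; standardization is an explicit
    preprocessing choice left to the caller (weight magnitudes are then
    directly interpretable per covariate unit).
    """

    def __init__(self, data: SurvivalData, ridge: float = 0.0):
        super().__init__(data)
        data.require_events()
        self.ridge = float(ridge)
        self._const = data.X.std(axis=0, ddof=0) == 0.0
        if self._const.any():
            names = [data.feature_names[j] for j in np.where(self._const)[0]]
            warnings.warn(
                f"constant feature(s) {names} carry no partial-likelihood "
                "information; their coefficients are fixed at 0",
                UserWarning,
            )

    def fit(self, tol: float = 1e-8, max_iter: int = 100, coef_cap: float = 500.0) -> "CoxPHResults":
        """Newton-Raphson to gradient norm <= ``tol`` or ``max_iter`` iterations.

        A monotone partial likelihood (perfect separation) is detected when
        coefficients run away; the fit then stops with capped coefficients
        and a :class:`SeparationWarning` instead of failing.
        """
        data = self.data
        free = ~self._const
        X = data.X[:, free]
        Xc = X - X.mean(axis=0)  # centering leaves the partial likelihood invariant
        d = Xc.shape[1]
        beta = np.zeros(d)
        loglik, grad, info = self._penalized(Xc, data, beta)
        separated = False
        it = 0
        for it in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise FitError(
                    f"singular information matrix at iteration {it}; "
                    "check for collinear features"
                ) from exc
            # step-halving to guarantee ascent
            new_beta, new = beta, None
            for half in range(40):
                cand = beta + step / (2**half)
                new = self._penalized(Xc, data, cand)
                if new[0] >= loglik - 1e-12:
                    new_beta = cand
                    break
            else:
                break  # no ascent direction left; grad test below decides
            beta = new_beta
            loglik, grad, info = new
            if np.abs(beta).max() > coef_cap:
                separated = True
                beta = np.clip(beta, -coef_cap, coef_cap)
                loglik, grad, info = self._penalized(Xc, data, beta)
                warnings.warn(
                    "monotone partial likelihood (perfect separation?) — "
                    f"coefficients capped at ±{coef_cap:g}",
                    SeparationWarning,
                )
                break
            if np.linalg.norm(grad) <= tol:
                break
        else:
            raise FitError(
                f"Cox fit did not converge in {max_iter} iterations "
                f"(|grad| = {np.linalg.norm(grad):.3g})"
            )
        if not separated and np.linalg.norm(grad) > tol:
            raise FitError(
                f"Cox fit stalled (|grad| = {np.linalg.norm(grad):.3g} > {tol:g})"
            )

        if not separated:
            # monotone likelihood can "converge" by gradient tolerance while
            # beta runs off: flag fits whose per-feature linear-predictor
            # range implies an astronomical hazard ratio
            span = Xc.max(axis=0) - Xc.min(axis=0)
            if np.any(np.abs(beta) * span > 15.0):
                separated = True
                warnings.warn(
                    "monotone partial likelihood suspected (a single feature "
                    "spans a log-hazard range > 15); estimates are unreliable",
                    SeparationWarning,
                )
        params = np.zeros(data.n_features)
        params[free] = beta
        bse = np.full(data.n_features, np.nan)
        try:
            cov = np.linalg.inv(info)
            bse[free] = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            cov = None
        return CoxPHResults(
            model=self,
            params=params,
            bse=bse,
            feature_names=list(data.feature_names),
            loglik=float(loglik),
            n_iter=it,
            grad_norm=float(np.linalg.norm(grad)),
            separated=separated,
        )

    def _penalized(self, Xc, data, beta):
        loglik, grad, info = _breslow_quantities(Xc, data.time, data.event, beta)
        if self.ridge > 0:
            loglik -= 0.5 * self.ridge * beta @ beta
            grad = grad - self.ridge * beta
            info = info + self.ridge * np.eye(len(beta))
        return loglik, grad, info


@dataclass
class CoxPHResults(SurvivalResults):
    """Fitted Cox model: coefficients, standard errors and diagnostics."""

    model: CoxPH
    params: np.ndarray
    bse: np.ndarray
    feature_names: list
    loglik: float
    n_iter: int
    grad_norm: float
    separated: bool = False
    diagnostics: dict = field(init=False)

    def __post_init__(self):
        self.diagnostics = {
            "iterations": self.n_iter,
            "grad_norm": self.grad_norm,
            "loglik": self.loglik,
            "separated": self.separated,
        }

    def predict(self, data: SurvivalData) -> np.ndarray:
        """Survival-oriented scores ``-b' x_i`` (higher = longer survival)."""
        if data.n_features != len(self.params):
            raise ValueError(
                f"model has {len(self.params)} features, data has {data.n_features}"
            )
        return -(data.X @ self.params)

    @property
    def weights(self) -> pd.Series:
        """Raw coefficients b_j, hazard-oriented (positive = higher risk)."""
        return pd.Series(self.params, index=self.feature_names, name="cox_weight")

    def summary(self) -> pd.DataFrame:
        z = self.params / self.bse
        return pd.DataFrame(
            {
                "coef": self.params,
                "se(coef)": self.bse,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=self.feature_names,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "cox",
                "feature_names": self.feature_names,
                "coefficients": self.params.tolist(),
                "bse": self.bse.tolist(),
                "diagnostics": self.diagnostics,
            },
            indent=2,
        )


# -- thin functional layer ------------------------------------------------

def fit_cox(data: SurvivalData, **fit_kwargs) -> CoxPHResults:
    """Fit a Cox proportional-hazards model (see :class:`CoxPH`)."""
    return CoxPH(data).fit(**fit_kwargs)


def predict_cox(results: CoxPHResults, data: SurvivalData) -> np.ndarray:
    return results.predict(data)


def cox_weights(results: CoxPHResults) -> pd.Series:
    return results.weights
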
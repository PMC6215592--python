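"""Support vector regression for censored data (SVRc).

Standard epsilon-insensitive SVR is adapted to right censoring by giving
every sample its *own* slack penalty and tube half-width on each side of the
regression function, mixed by censoring status:

    minimize  1/2 ||W||^2 + sum_i ( C_i xi_i + C_i* xi_i* )
    s.t.      y_i - f(x_i) <= eps_i  + xi_i      (under-prediction side)
              f(x_i) - y_i <= eps_i* + xi_i*     (over-prediction side)
              xi_i, xi_i* >= 0

with, writing s_i = 1 for censored and 0 for an event,

    C_i*   = s_i C_c*   + (1 - s_i) C_n*        eps_i*   = s_i eps_c*   + (1 - s_i) eps_n*
    C_i    = s_i C_c    + (1 - s_i) C_n         eps_i    = s_i eps_c    + (1 - s_i) eps_n

A censored time is only a lower bound on the true survival time, so
over-predicting it should be cheap: the recommended regime is a wide upper
tube (eps_c* large) and a light upper penalty (C_c* small) for censored
records.  The convex program is solved in its dual (a QP with per-sample box
constraints) by an SMO-type maximal-violating-pair algorithm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import SurvivalData, Standardizer
from .exceptions import ConvergenceWarning, FitError, UnsupportedOperationError
from .model import SurvivalModel, SurvivalResults

__all__ = ["SvrcParams", "resolve_per_sample", "SVRc", "SVRcResults", "fit_svrc",
           "predict_svrc", "svrc_weights"]


@dataclass(frozen=True)
class SvrcParams:
    """Slack penalties and tube widths of the asymmetric censored-data loss.

    ``None`` epsilon values are resolved at fit time from the spread of the
    training times: eps_n = eps_n_star = eps_c = 0.1 * sd(times) and
    eps_c_star = 0.5 * sd(times), encoding "over-predicting a censored time
    is cheap".  All C must be positive and all eps nonnegative.
    """

    C_n: float = 1.0
    C_n_star: float = 1.0
    C_c: float = 1.0
    C_c_star: float = 0.2
    eps_n: float | None = None
    eps_n_star: float | None = None
    eps_c: float | None = None
    eps_c_star: float | None = None
    kernel: str = "linear"
    gamma: float | None = None  # rbf only; default 1/d

    def resolved(self, times) -> "SvrcParams":
        sd = float(np.std(np.asarray(times, dtype=float)))
        sd = sd if sd > 0 else 1.0
        out = replace(
            self,
            eps_n=0.1 * sd if self.eps_n is None else self.eps_n,
            eps_n_star=0.1 * sd if self.eps_n_star is None else self.eps_n_star,
            eps_c=0.1 * sd if self.eps_c is None else self.eps_c,
            eps_c_star=0.5 * sd if self.eps_c_star is None else self.eps_c_star,
        )
        out.validate()
        return out

    def validate(self) -> None:
        for name in ("C_n", "C_n_star", "C_c", "C_c_star"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("eps_n", "eps_n_star", "eps_c", "eps_c_star"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if (
            self.eps_c_star is not None
            and self.eps_n_star is not None
            and self.eps_c_star < self.eps_n_star
        ):
            warnings.warn(
                "eps_c_star < eps_n_star: censored over-prediction is penalized "
                "more tightly than event over-prediction (unusual for censored data)",
                UserWarning,
            )
        if self.C_c_star > self.C_n_star:
            warnings.warn(
                "C_c_star > C_n_star: censored over-prediction is penalized more "
                "heavily than event over-prediction (unusual for censored data)",
                UserWarning,
            )


def resolve_per_sample(params: SvrcParams, event_indicator):
    """Per-sample (C_i, C_i_star, eps_i, eps_i_star) from censoring status.

    ``event_indicator`` is delta (1 = event, 0 = censored), scalar or array;
    internally s = 1 - delta so censored records take the ``_c`` values and
    events the ``_n`` values.
    """
    if params.eps_n is None or params.eps_c_star is None:
        raise ValueError("epsilon values unresolved; call params.resolved(times) first")
    s = 1.0 - np.asarray(event_indicator, dtype=float)
    C = s * params.C_c + (1 - s) * params.C_n
    C_star = s * params.C_c_star + (1 - s) * params.C_n_star
    eps = s * params.eps_c + (1 - s) * params.eps_n
    eps_star = s * params.eps_c_star + (1 - s) * params.eps_n_star
    return C, C_star, eps, eps_star


def _kernel_matrix(params: SvrcParams, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    if params.kernel == "linear":
        return A @ B.T
    gamma = params.gamma if params.gamma is not None else 1.0 / A.shape[1]
    sq = (A**2).sum(1)[:, None] + (B**2).sum(1)[None, :] - 2 * A @ B.T
    return np.exp(-gamma * np.maximum(sq, 0.0))


def _solve_svr_dual(K, y, C_lo, C_up, eps_lo, eps_up, tol, max_iter):
    """SMO (maximal violating pair) for the asymmetric-tube SVR dual.

    Variables theta = [alpha; alpha*]: alpha drives the under-prediction
    constraints (box [0, C_i]), alpha* the over-prediction constraints
    (box [0, C_i*]); sum(alpha) = sum(alpha*) by the intercept constraint.
    Returns (beta = alpha - alpha*, intercept, diagnostics).
    """
    n = len(y)
    Kdup = np.concatenate([K, K], axis=0)  # row t of the lifted kernel = K[t % n]
    z = np.concatenate([np.ones(n), -np.ones(n)])
    ub = np.concatenate([C_lo, C_up])
    grad = np.concatenate([eps_lo - y, eps_up + y])
    theta = np.zeros(2 * n)
    diag2 = np.concatenate([np.diag(K), np.diag(K)])
    neg_inf = -np.inf
    it = 0
    gap = np.inf
    for it in range(1, max_iter + 1):
        v = -z * grad
        up = np.where(z > 0, theta < ub, theta > 0)
        low = np.where(z > 0, theta > 0, theta < ub)
        vi = np.where(up, v, neg_inf)
        vj = np.where(low, v, np.inf)
        i = int(np.argmax(vi))
        j = int(np.argmin(vj))
        gap = vi[i] - vj[j]
        if gap <= tol:
            break
        a = diag2[i] + diag2[j] - 2.0 * K[i % n, j % n]
        delta = gap / max(a, 1e-12)
        # box caps along the feasible direction (theta_i moves by z_i*delta,
        # theta_j by -z_j*delta)
        delta = min(delta, ub[i] - theta[i] if z[i] > 0 else theta[i])
        delta = min(delta, theta[j] if z[j] > 0 else ub[j] - theta[j])
        theta[i] += z[i] * delta
        theta[j] -= z[j] * delta
        grad += delta * z * (Kdup[:, i % n] - Kdup[:, j % n])
    beta = theta[:n] - theta[n:]

    # intercept from free (strictly inside the box) multipliers
    free = (theta > 1e-8 * np.maximum(ub, 1e-12)) & (theta < ub * (1 - 1e-8))
    v = -z * grad
    if free.any():
        b = float(v[free].mean())
    else:
        up = np.where(z > 0, theta < ub, theta > 0)
        low = np.where(z > 0, theta > 0, theta < ub)
        hi = v[up].max() if up.any() else 0.0
        lo = v[low].min() if low.any() else 0.0
        b = float((hi + lo) / 2.0)

    f = K @ beta
    dual_obj = -(0.5 * beta @ f + eps_lo @ theta[:n] + eps_up @ theta[n:] - y @ beta)
    xi = np.maximum(0.0, y - f - b - eps_lo)
    xi_star = np.maximum(0.0, f + b - y - eps_up)
    primal_obj = 0.5 * beta @ f + C_lo @ xi + C_up @ xi_star
    rel_gap = (primal_obj - dual_obj) / (abs(primal_obj) + 1.0)
    diagnostics = {
        "iterations": it,
        "kkt_violation": float(gap),
        "dual_objective": float(dual_obj),
        "primal_objective": float(primal_obj),
        "relative_duality_gap": float(rel_gap),
        "n_support": int(np.sum(np.abs(beta) > 0)),
    }
    return beta, b, theta[:n].copy(), theta[n:].copy(), diagnostics


class SVRc(SurvivalModel):
    """Censored-data support vector regression model.

    Parameters
    ----------
    data : SurvivalData
        Training data; regression targets are the observed times on their
        original scale.
    params : SvrcParams, optional
        Loss parameters; defaults as documented on :class:`SvrcParams`.
    standardize : bool, default True
        Standardize features (zero mean / unit variance, fit on this data)
        before training; the C/eps parameters are scale-sensitive.  The
        transform is reapplied automatically in ``predict``.
    log_time : bool, default False
        Fit on log1p-transformed targets (eps defaults then scale with the
        sd of the transformed times).  Scores remain monotone in predicted
        time either way.
    """

    def __init__(
        self,
        data: SurvivalData,
        params: SvrcParams | None = None,
        standardize: bool = True,
        log_time: bool = False,
    ):
        super().__init__(data)
        data.require_events()
        if data.n < 2:
            raise ValueError("SVRc requires at least 2 records")
        self.params = params if params is not None else SvrcParams()
        self.standardize = bool(standardize)
        self.log_time = bool(log_time)

    def fit(self, tol: float | None = None, max_iter: int = 2_000_000) -> "SVRcResults":
        data = self.data
        scaler = Standardizer().fit(data.X) if self.standardize else None
        Xs = scaler.transform(data.X) if scaler else data.X
        y = np.log1p(data.time) if self.log_time else data.time
        params = self.params.resolved(y)
        C_lo, C_up, eps_lo, eps_up = resolve_per_sample(params, data.event)
        K = _kernel_matrix(params, Xs, Xs)
        if tol is None:
            tol = 1e-8 * max(1.0, float(np.abs(y).max()))
        beta, b, alpha, alpha_star, diag = _solve_svr_dual(
            K, y, C_lo, C_up, eps_lo, eps_up, tol, max_iter
        )
        if diag["relative_duality_gap"] > 1e-6:
            # degenerate / near-singular kernels: jitter the diagonal once
            Kj = K + 1e-8 * (np.trace(K) / len(y) + 1.0) * np.eye(len(y))
            beta, b, alpha, alpha_star, diag = _solve_svr_dual(
                Kj, y, C_lo, C_up, eps_lo, eps_up, tol, max_iter
            )
            diag["jittered"] = True
        if diag["relative_duality_gap"] > 1e-6:
            if diag["relative_duality_gap"] > 1e-3:
                raise FitError(
                    "SVRc QP did not converge: relative duality gap "
                    f"{diag['relative_duality_gap']:.3g} after {diag['iterations']} iterations"
                )
            warnings.warn(
                f"SVRc solver stopped with loose duality gap "
                f"{diag['relative_duality_gap']:.3g}",
                ConvergenceWarning,
            )
        coef = Xs.T @ beta if params.kernel == "linear" else None
        return SVRcResults(
            model=self,
            params=params,
            beta=beta,
            alpha=alpha,
            alpha_star=alpha_star,
            intercept=b,
            coef=coef,
            feature_names=list(data.feature_names),
            scaler=scaler,
            support_X=Xs,
            diagnostics=diag,
        )


@dataclass
class SVRcResults(SurvivalResults):
    """Fitted SVRc model (dual coefficients, intercept, diagnostics)."""

    model: SVRc
    params: SvrcParams
    beta: np.ndarray          # alpha - alpha*, one per training record
    alpha: np.ndarray         # under-prediction multipliers, in [0, C_i]
    alpha_star: np.ndarray    # over-prediction multipliers, in [0, C_i*]
    intercept: float
    coef: np.ndarray | None   # primal W (linear kernel only)
    feature_names: list
    scaler: Standardizer | None
    support_X: np.ndarray = field(repr=False)
    diagnostics: dict = field(default_factory=dict)

    def predict(self, data: SurvivalData) -> np.ndarray:
        """Predicted survival times f(x) = W.phi(x) + b (survival-oriented)."""
        if data.n_features != len(self.feature_names):
            raise ValueError(
                f"model has {len(self.feature_names)} features, data has {data.n_features}"
            )
        Xs = self.scaler.transform(data.X) if self.scaler else data.X
        if self.params.kernel == "linear":
            return Xs @ self.coef + self.intercept
        Kx = _kernel_matrix(self.params, Xs, self.support_X)
        return Kx @ self.beta + self.intercept

    @property
    def weights(self) -> pd.Series:
        """Primal weights W, survival-oriented (negative = risk factor).

        Linear kernel only; weights refer to the standardized feature space
        when the model was fit with ``standardize=True``.
        """
        if self.params.kernel != "linear":
            raise UnsupportedOperationError(
                "per-feature weights are only defined for the linear kernel"
            )
        return pd.Series(self.coef, index=self.feature_names, name="svrc_weight")

    @property
    def n_upper_support_censored(self) -> int:
        """Censored records active on the over-prediction side (alpha* > 0)."""
        return int(np.sum((self.alpha_star > 1e-10) & (self.model.data.event == 0)))

    def summary(self) -> pd.DataFrame:
        df = self.weights.to_frame("weight")
        df.loc["(intercept)"] = self.intercept
        return df

    def to_json(self) -> str:
        p = self.params
        return json.dumps(
            {
                "model": "svrc",
                "feature_names": self.feature_names,
                "weights": None if self.coef is None else self.coef.tolist(),
                "intercept": self.intercept,
                "params": {
                    "C_n": p.C_n, "C_n_star": p.C_n_star,
                    "C_c": p.C_c, "C_c_star": p.C_c_star,
                    "eps_n": p.eps_n, "eps_n_star": p.eps_n_star,
                    "eps_c": p.eps_c, "eps_c_star": p.eps_c_star,
                    "kernel": p.kernel, "gamma": p.gamma,
                },
                "diagnostics": self.diagnostics,
            },
            indent=2,
        )


# -- thin functional layer ------------------------------------------------

def fit_svrc(data: SurvivalData, params: SvrcParams | None = None, **kwargs) -> SVRcResults:
    """Fit an SVRc model (see :class:`SVRc`)."""
    return SVRc(data, params=params, **kwargs).fit()


def predict_svrc(results: SVRcResults, data: SurvivalData) -> np.ndarray:
    return results.predict(data)


def svrc_weights(results: SVRcResults) -> pd.Series:
    return results.weights
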
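"""Gompertz proportional-hazards survival model.

Hazard  h(t | x) = exp(b0 + a*t + x'beta)  with time t in years since
baseline; ``a`` is the Gompertz shape (log-hazard slope per year of
follow-up, the adult-mortality doubling-time parameter), ``b0`` the log
baseline rate at t = 0, and ``beta`` named log-hazard-ratios.  The
censored-data log likelihood

    sum_i  d_i*(b0 + a*t_i + x_i'beta) - exp(b0 + x_i'beta) * (exp(a*t_i) - 1)/a

is maximized by quasi-Newton iteration with the analytic gradient; the a->0
(exponential) limit is handled by a series expansion so fits near the
boundary stay well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["GompertzModel", "fit_gompertz", "gompertz_cuminc"]

_A_TINY = 1e-9


def _growth(t, a):
    """(exp(a*t) - 1)/a, with the a->0 limit t + a t^2/2."""
    t = np.asarray(t, dtype=float)
    if abs(a) < _A_TINY:
        return t * (1.0 + 0.5 * a * t)
    return np.expm1(a * t) / a


def _dgrowth_da(t, a):
    """d/da of (exp(a*t) - 1)/a."""
    t = np.asarray(t, dtype=float)
    if abs(a) < _A_TINY:
        return 0.5 * t * t * (1.0 + 2.0 * a * t / 3.0)
    return (a * t * np.exp(a * t) - np.expm1(a * t)) / (a * a)


@dataclass
class GompertzModel:
    """Fitted (or hand-specified) Gompertz proportional-hazards model."""

    shape: float  # a, 1/years
    lograte: float  # b0
    coef: pd.Series  # named log-hazard-ratios (may be empty)
    se: pd.Series | None = field(default=None, repr=False)  # SEs for (shape, lograte, *coef)
    loglik: float | None = field(default=None, repr=False)
    n: int | None = field(default=None, repr=False)
    n_events: int | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.shape):
            raise ValueError("shape must be finite")

    @property
    def covariate_names(self) -> list[str]:
        return list(self.coef.index)

    def linear_predictor(self, x) -> np.ndarray:
        """x'beta for a row mapping / DataFrame of covariates."""
        if len(self.coef) == 0:
            if x is None or np.isscalar(x) or isinstance(x, dict):
                return np.zeros(1)
            return np.zeros(len(x))
        if isinstance(x, pd.DataFrame):
            return x[self.covariate_names].to_numpy(dtype=float) @ self.coef.to_numpy()
        if isinstance(x, (dict, pd.Series)):
            return np.array([sum(self.coef[c] * float(x[c]) for c in self.covariate_names)])
        return np.atleast_2d(np.asarray(x, dtype=float)) @ self.coef.to_numpy()

    def to_dict(self) -> dict:
        return {
            "shape": float(self.shape),
            "lograte": float(self.lograte),
            "coefficients": {str(k): float(v) for k, v in self.coef.items()},
            "n": self.n,
            "n_events": self.n_events,
            "loglik": None if self.loglik is None else float(self.loglik),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GompertzModel":
        coef = pd.Series(d.get("coefficients", {}), dtype=float)
        return cls(shape=float(d["shape"]), lograte=float(d["lograte"]), coef=coef,
                   loglik=d.get("loglik"), n=d.get("n"), n_events=d.get("n_events"))


def gompertz_cuminc(model: GompertzModel, x, k: float) -> np.ndarray:
    """Cumulative mortality risk by horizon k years.

    M = 1 - exp(-exp(b0 + x'beta) * (exp(a*k) - 1)/a); the a->0 limit uses
    exp(b0 + x'beta)*k.
    """
    if k < 0:
        raise ValueError("horizon must be non-negative")
    eta = model.linear_predictor(x)
    cumhaz = np.exp(model.lograte + eta) * _growth(k, model.shape)
    out = -np.expm1(-cumhaz)
    if x is None or np.isscalar(x) or isinstance(x, (dict, pd.Series)):
        return float(out[0])
    return out


def _negloglik_and_grad(theta, Xv, t, d):
    a, b0 = theta[0], theta[1]
    beta = theta[2:]
    eta = Xv @ beta if Xv is not None else 0.0
    lin = b0 + eta
    growth = _growth(t, a)
    mu = np.exp(lin) * growth  # expected cumulative hazard per subject
    ll = np.sum(d * (lin + a * t)) - np.sum(mu)
    g_a = np.sum(d * t) - np.sum(np.exp(lin) * _dgrowth_da(t, a))
    g_b0 = np.sum(d) - np.sum(mu)
    if Xv is not None:
        g_beta = Xv.T @ (d - mu)
        grad = np.concatenate([[g_a, g_b0], g_beta])
    else:
        grad = np.array([g_a, g_b0])
    return -ll, -grad


def _hessian_fd(theta, Xv, t, d, eps=1e-5):
    """Finite differences of the analytic gradient (for standard errors)."""
    p = len(theta)
    H = np.zeros((p, p))
    for j in range(p):
        step = eps * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += step
        tm = theta.copy()
        tm[j] -= step
        gp = _negloglik_and_grad(tp, Xv, t, d)[1]
        gm = _negloglik_and_grad(tm, Xv, t, d)[1]
        H[:, j] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


def fit_gompertz(X, time, event, init_shape: float = 0.05,
                 grad_tol: float = 1e-6, max_iter: int = 500) -> GompertzModel:
    """Maximum-likelihood Gompertz proportional-hazards fit.

    Parameters
    ----------
    X
        Covariate DataFrame (or None / zero-column for an intercept-only
        model).  Covariates are centered internally for conditioning; the
        reported lograte is on the original covariate scale.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=float)
    if np.any(t <= 0):
        raise ValueError("all times must be positive")
    if d.sum() < 1:
        raise ValueError("need at least one event")

    names: list[str] = []
    Xv = None
    center = None
    if X is not None:
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        if Xdf.shape[1] > 0:
            names = [str(c) for c in Xdf.columns]
            center = Xdf.to_numpy(dtype=float).mean(axis=0)
            Xv = Xdf.to_numpy(dtype=float) - center

    crude = np.log(max(d.sum(), 1.0) / t.sum())
    theta0 = np.concatenate([[init_shape, crude], np.zeros(len(names))])

    best = None
    rng = np.random.default_rng(0)
    for attempt in range(4):
        res = optimize.minimize(
            _negloglik_and_grad, theta0, args=(Xv, t, d), jac=True,
            method="L-BFGS-B", options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        # polish with a few Newton steps to drive the gradient down
        theta = res.x
        for _ in range(50):
            nll, ngrad = _negloglik_and_grad(theta, Xv, t, d)
            gnorm = float(np.max(np.abs(ngrad)))
            if gnorm < grad_tol:
                break
            H = _hessian_fd(theta, Xv, t, d)
            try:
                step = np.linalg.solve(H, ngrad)
            except np.linalg.LinAlgError:
                break
            scale = 1.0
            for _ in range(30):
                cand = theta - scale * step
                if _negloglik_and_grad(cand, Xv, t, d)[0] <= nll:
                    theta = cand
                    break
                scale *= 0.5
            else:
                break
        if best is None or _negloglik_and_grad(theta, Xv, t, d)[0] < best[1]:
            best = (theta, _negloglik_and_grad(theta, Xv, t, d)[0], gnorm)
        if gnorm < grad_tol:
            break
        theta0 = np.concatenate([[init_shape * (1 + rng.normal(0, 0.5)), crude],
                                 rng.normal(0, 0.01, len(names))])
    theta, nll, gnorm = best
    if gnorm >= max(grad_tol, 1e-4 * (1 + abs(nll))):
        raise RuntimeError(
            f"Gompertz fit did not converge: max|gradient| = {gnorm:.3g} "
            f"(negloglik {nll:.6g}, {len(t)} rows, {int(d.sum())} events)"
        )

    H = _hessian_fd(theta, Xv, t, d)
    try:
        cov = np.linalg.inv(H)
        se_vals = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        if center is not None and len(names):
            # delta method for the de-centered intercept b0 - c'beta
            grad_b0 = np.concatenate([[0.0, 1.0], -center])
            se_vals[1] = float(np.sqrt(max(grad_b0 @ cov @ grad_b0, 0.0)))
    except np.linalg.LinAlgError:
        se_vals = np.full(len(theta), np.nan)

    a, b0 = float(theta[0]), float(theta[1])
    beta = pd.Series(theta[2:], index=names, dtype=float)
    if center is not None:
        b0 = b0 - float(center @ theta[2:])  # undo the centering
    se = pd.Series(se_vals, index=["shape", "lograte", *names])
    return GompertzModel(shape=a, lograte=b0, coef=beta, se=se, loglik=-float(nll),
                         n=len(t), n_events=int(d.sum()))
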
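"""Weibull proportional-hazards regression for one transition.

The hazard for a subject with covariate row ``x`` is

    h(t | x) = lam * gam * t**(gam - 1) * exp(x @ beta)

with cumulative hazard ``H(t | x) = lam * t**gam * exp(x @ beta)``; ``gam``
is the Weibull shape, ``lam`` the rate-scale, and ``exp(beta)`` are hazard
ratios.  Each at-risk interval ``(t_start, t_stop]`` contributes

    status * log h(t_stop | x)  -  [H(t_stop | x) - H(t_start | x)]

to the log-likelihood; the subtraction of ``H(t_start)`` handles delayed
entry (left truncation) on the clock-forward time scale, which is how
sojourns entered after diagnosis are represented.  Optimization is over the
unconstrained parameters ``(log lam, log gam, beta)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .state_space import TransitionRow

__all__ = [
    "WeibullPHFit",
    "FitError",
    "transition_log_likelihood",
    "fit_transition",
    "hazard_ratios",
    "aic",
]


class FitError(RuntimeError):
    """Fitting failed (no events, singular design, non-convergence)."""


@dataclass
class WeibullPHFit:
    """MLE of a transition-specific Weibull PH model.

    ``covariance`` is the inverse observed information over the parameter
    vector ``(log scale, log shape, *coefficients)``; ``None`` when the
    Hessian was singular at the optimum.
    """

    transition: int
    shape: float
    scale: float
    coefficients: dict[str, float]
    covariance: np.ndarray | None
    log_likelihood: float
    n_events: int
    n_rows: int

    @property
    def n_parameters(self) -> int:
        return 2 + len(self.coefficients)

    @property
    def params(self) -> np.ndarray:
        """Parameter vector (log scale, log shape, *betas)."""
        return np.concatenate(
            [[np.log(self.scale), np.log(self.shape)],
             list(self.coefficients.values())]
        )

    def to_dict(self) -> dict:
        return {
            "transition": self.transition,
            "shape": self.shape,
            "scale": self.scale,
            "coefficients": dict(self.coefficients),
            "covariance": None
            if self.covariance is None
            else self.covariance.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_events": self.n_events,
            "n_rows": self.n_rows,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "WeibullPHFit":
        cov = doc.get("covariance")
        return cls(
            transition=int(doc["transition"]),
            shape=float(doc["shape"]),
            scale=float(doc["scale"]),
            coefficients={k: float(v) for k, v in doc["coefficients"].items()},
            covariance=None if cov is None else np.asarray(cov, dtype=float),
            log_likelihood=float(doc["log_likelihood"]),
            n_events=int(doc["n_events"]),
            n_rows=int(doc["n_rows"]),
        )


def _rows_to_arrays(
    rows: Sequence[TransitionRow], covariate_names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    t0 = np.array([r.t_start for r in rows], dtype=float)
    t1 = np.array([r.t_stop for r in rows], dtype=float)
    d = np.array([r.status for r in rows], dtype=float)
    X = np.array(
        [[r.covariates[c] for c in covariate_names] for r in rows], dtype=float
    ).reshape(len(rows), len(covariate_names))
    if np.any(t0 < 0) or np.any(t1 <= t0):
        raise ValueError("rows must satisfy 0 <= t_start < t_stop")
    if np.any(d * (t1 <= 0)):
        raise ValueError("event times must be positive")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate values")
    return t0, t1, d, X


def _loglik_and_grad(
    theta: np.ndarray,
    t0: np.ndarray,
    t1: np.ndarray,
    d: np.ndarray,
    X: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Log-likelihood and its analytic gradient in (log lam, log gam, beta)."""
    log_lam, log_gam = theta[0], theta[1]
    beta = theta[2:]
    gam = np.exp(log_gam)
    eta = X @ beta
    # cumulative-hazard increment per row
    p1 = np.power(t1, gam)
    p0 = np.power(t0, gam)
    w = np.exp(log_lam + eta) * (p1 - p0)
    log_t1 = np.log(t1)
    ll = float(
        np.sum(d * (log_lam + log_gam + (gam - 1.0) * log_t1 + eta)) - np.sum(w)
    )
    # gradient
    g_log_lam = float(np.sum(d - w))
    # d/dgam of (t1^gam - t0^gam); t0 == 0 contributes 0
    with np.errstate(divide="ignore", invalid="ignore"):
        log_t0 = np.where(t0 > 0, np.log(np.where(t0 > 0, t0, 1.0)), 0.0)
    dw_dgam = np.exp(log_lam + eta) * (p1 * log_t1 - p0 * log_t0)
    g_log_gam = float(gam * (np.sum(d * (1.0 / gam + log_t1)) - np.sum(dw_dgam)))
    g_beta = X.T @ (d - w)
    return ll, np.concatenate([[g_log_lam, g_log_gam], g_beta])


def transition_log_likelihood(
    params: Sequence[float],
    rows: Sequence[TransitionRow],
    covariate_names: Sequence[str] = (),
) -> float:
    """Delayed-entry Weibull PH log-likelihood at ``params``.

    ``params`` is ``(log lam, log gam, *beta)`` with one beta per name in
    ``covariate_names`` (in order).
    """
    theta = np.asarray(params, dtype=float)
    if theta.size != 2 + len(covariate_names):
        raise ValueError(
            f"expected {2 + len(covariate_names)} parameters, got {theta.size}"
        )
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameters")
    transitions = {r.transition for r in rows}
    if len(transitions) > 1:
        raise ValueError(f"rows span multiple transitions: {sorted(transitions)}")
    t0, t1, d, X = _rows_to_arrays(rows, covariate_names)
    ll, _ = _loglik_and_grad(theta, t0, t1, d, X)
    return ll


def _numerical_hessian(fun_grad, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    p = theta.size
    H = np.empty((p, p))
    for j in range(p):
        step = h * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += step
        tm = theta.copy()
        tm[j] -= step
        _, gp = fun_grad(tp)
        _, gm = fun_grad(tm)
        H[:, j] = (gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)


def fit_transition(
    rows: Sequence[TransitionRow],
    covariate_names: Sequence[str] = (),
    transition: int | None = None,
    fix_shape: float | None = None,
) -> WeibullPHFit:
    """Maximum-likelihood Weibull PH fit for one transition's stacked rows.

    Starting values are the exponential fit (shape 1, scale =
    events/exposure, betas 0); quasi-Newton (BFGS) optimization with up to
    five deterministic shape-jittered restarts on failure.  ``fix_shape``
    constrains the Weibull shape (e.g. ``fix_shape=1`` gives the
    exponential model).

    Raises
    ------
    FitError
        If no events are present, the design matrix is rank-deficient, or
        the optimizer fails to converge after restarts.
    """
    rows = list(rows)
    transitions = {r.transition for r in rows}
    if transition is None:
        if len(transitions) != 1:
            raise ValueError(
                f"rows span multiple transitions: {sorted(transitions)}; "
                "pass transition= to disambiguate"
            )
        transition = transitions.pop()
    else:
        rows = [r for r in rows if r.transition == transition]
    covariate_names = list(covariate_names)
    t0, t1, d, X = _rows_to_arrays(rows, covariate_names)
    n_events = int(d.sum())
    if n_events == 0:
        raise FitError(
            f"transition {transition}: no events; drop this transition or "
            "its covariates"
        )
    if covariate_names:
        design = np.column_stack([np.ones(len(rows)), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise FitError(
                f"transition {transition}: design matrix is rank deficient"
            )

    exposure = float(np.sum(t1 - t0))
    lam0 = n_events / exposure

    if fix_shape is not None:
        log_gam_fixed = float(np.log(fix_shape))

        def fg(free: np.ndarray):
            theta = np.concatenate([[free[0], log_gam_fixed], free[1:]])
            ll, g = _loglik_and_grad(theta, t0, t1, d, X)
            return ll, np.concatenate([[g[0]], g[2:]])

        x0_full = np.concatenate([[np.log(lam0)], np.zeros(len(covariate_names))])
    else:

        def fg(theta: np.ndarray):
            return _loglik_and_grad(theta, t0, t1, d, X)

        x0_full = np.concatenate(
            [[np.log(lam0), 0.0], np.zeros(len(covariate_names))]
        )

    def neg(theta):
        ll, g = fg(theta)
        return -ll, -g

    rng = np.random.default_rng(1234)  # deterministic restart jitter
    best = None
    for attempt in range(6):
        x0 = x0_full.copy()
        if attempt > 0:
            jitter_idx = 0 if fix_shape is not None else 1
            x0[jitter_idx] += rng.normal(scale=0.5)
        res = optimize.minimize(
            neg, x0, jac=True, method="BFGS",
            options={"gtol": 1e-9, "maxiter": 500},
        )
        # polish with a few Newton steps on the analytic gradient
        theta = res.x
        for _ in range(10):
            ll, g = fg(theta)
            if np.max(np.abs(g)) < 1e-8:
                break
            H = _numerical_hessian(fg, theta)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            cand = theta - step
            ll_new, _ = fg(cand)
            if not np.isfinite(ll_new) or ll_new < ll - 1e-9:
                break
            theta = cand
        ll, g = fg(theta)
        converged = np.isfinite(ll) and np.max(np.abs(g)) < 1e-5
        if converged and (best is None or ll > best[0]):
            best = (ll, theta)
        if best is not None and attempt >= 1:
            break
        if converged:
            break
    if best is None:
        raise FitError(
            f"transition {transition}: optimizer failed to converge after "
            f"restarts (last gradient max {np.max(np.abs(g)):.2e})"
        )
    ll, theta = best

    H = _numerical_hessian(fg, theta)
    info = -H  # observed information
    try:
        cov_free = np.linalg.inv(info)
        if not np.all(np.isfinite(cov_free)) or np.any(np.diag(cov_free) <= 0):
            cov_free = None
    except np.linalg.LinAlgError:
        cov_free = None

    if fix_shape is not None:
        shape = float(fix_shape)
        scale = float(np.exp(theta[0]))
        betas = theta[1:]
        cov = None
        if cov_free is not None:
            # embed into the (log lam, log gam, beta) layout with zero
            # variance for the fixed shape
            p = len(covariate_names) + 2
            cov = np.zeros((p, p))
            idx = [0] + list(range(2, p))
            cov[np.ix_(idx, idx)] = cov_free
    else:
        scale = float(np.exp(theta[0]))
        shape = float(np.exp(theta[1]))
        betas = theta[2:]
        cov = cov_free

    return WeibullPHFit(
        transition=int(transition),
        shape=shape,
        scale=scale,
        coefficients=dict(zip(covariate_names, map(float, betas))),
        covariance=cov,
        log_likelihood=float(ll),
        n_events=n_events,
        n_rows=len(rows),
    )


def hazard_ratios(fit: WeibullPHFit, level: float = 0.95) -> pd.DataFrame:
    """Wald hazard-ratio table: HR, CI bounds and two-sided p per covariate."""
    if fit.covariance is None:
        raise FitError(
            f"transition {fit.transition}: covariance unavailable "
            "(singular information matrix)"
        )
    z = stats.norm.ppf(0.5 + level / 2.0)
    recs = []
    for j, (name, beta) in enumerate(fit.coefficients.items()):
        se = float(np.sqrt(fit.covariance[2 + j, 2 + j]))
        wald = beta / se if se > 0 else np.inf * np.sign(beta)
        p = 2.0 * stats.norm.sf(abs(wald)) if se > 0 else 0.0
        with np.errstate(over="ignore"):  # huge SE -> infinite CI bound
            recs.append(
                {
                    "covariate": name,
                    "HR": float(np.exp(beta)),
                    "CI_low": float(np.exp(beta - z * se)),
                    "CI_high": float(np.exp(beta + z * se)),
                    "p": float(p),
                }
            )
    return pd.DataFrame(recs, columns=["covariate", "HR", "CI_low", "CI_high", "p"])


def aic(fit: WeibullPHFit) -> float:
    """Akaike information criterion, ``-2 log L + 2 k``; lower is better."""
    return -2.0 * fit.log_likelihood + 2.0 * fit.n_parameters
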
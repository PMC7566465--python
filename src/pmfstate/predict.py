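"""Transition-probability and state-occupation prediction.

Given one fitted Weibull proportional-hazards model per transition, the
time-inhomogeneous Markov intensity matrix Q(t) is assembled from the
transition hazards and the transition-probability matrix P(s, t) is
obtained two ways:

* deterministically, by integrating the Kolmogorov forward equation
  dP(s,t)/dt = P(s,t) Q(t) with an adaptive Runge-Kutta solver;
* stochastically, by simulating Markov paths whose next-event times invert
  the total cumulative hazard out of the current state (the standard
  simulation approach for parametric multistate prediction).

State-occupation probabilities are the initial-state row of P(0, t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .state_space import StateSpace
from .weibull_ph import WeibullPHFit

__all__ = [
    "ModelSet",
    "ProbabilityCurves",
    "intensity_matrix",
    "transition_probabilities_ode",
    "simulate_transition_probabilities",
    "state_occupation",
    "sample_paths",
]

#: lower end of time grids; Weibull hazards with shape < 1 diverge at 0
T_EPS = 1e-6

#: default prediction grid: 0 to 25 years, 401 points
DEFAULT_GRID = np.linspace(0.0, 25.0, 401)

#: bisection tolerance (years) for inverting the total cumulative hazard
_BISECT_TOL = 1e-8

#: most negative probability tolerated from the forward solver before
#: erroring; round-off at the solver's error-control scale is clipped to 0
_NEG_CLIP = 1e-8


@dataclass
class ModelSet:
    """A state space plus one fitted Weibull PH model per transition."""

    space: StateSpace
    fits: dict[int, WeibullPHFit]

    def __post_init__(self) -> None:
        want = set(range(1, self.space.n_transitions + 1))
        have = set(self.fits)
        if want != have:
            raise ValueError(
                f"fits must cover transitions {sorted(want)}, got {sorted(have)}"
            )

    @property
    def shapes(self) -> np.ndarray:
        return np.array(
            [self.fits[k].shape for k in range(1, self.space.n_transitions + 1)]
        )

    @property
    def scales(self) -> np.ndarray:
        return np.array(
            [self.fits[k].scale for k in range(1, self.space.n_transitions + 1)]
        )

    def linear_predictor(self, x: dict[str, float]) -> np.ndarray:
        """Per-transition linear predictor x @ beta for one covariate profile."""
        out = np.zeros(self.space.n_transitions)
        for k in range(1, self.space.n_transitions + 1):
            for name, beta in self.fits[k].coefficients.items():
                if name not in x:
                    raise KeyError(
                        f"profile missing covariate {name!r} used by "
                        f"transition {k}"
                    )
                out[k - 1] += beta * float(x[name])
        return out


@dataclass
class ProbabilityCurves:
    """Time-indexed transition-probability matrices and occupation vectors.

    ``P[i]`` is the matrix ``P_ab(s, times[i])`` over state pairs (ordered
    as in the state space); ``occupation[i]`` is the row of ``P`` for the
    initial state.
    """

    space: StateSpace
    times: np.ndarray
    P: np.ndarray
    occupation: np.ndarray
    profile: dict[str, float]
    s: float
    method: str
    initial_state: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy long frame: time, from_state, to_state, probability, method."""
        recs = []
        for i, t in enumerate(self.times):
            for a_idx, a in enumerate(self.space.state_ids):
                for b_idx, b in enumerate(self.space.state_ids):
                    recs.append(
                        (float(t), a, b, float(self.P[i, a_idx, b_idx]), self.method)
                    )
        return pd.DataFrame(
            recs, columns=["time", "from_state", "to_state", "probability", "method"]
        )

    def occupation_frame(self) -> pd.DataFrame:
        recs = []
        for i, t in enumerate(self.times):
            for s_idx, state in enumerate(self.space.state_ids):
                recs.append((float(t), state, float(self.occupation[i, s_idx])))
        return pd.DataFrame(recs, columns=["time", "state", "probability"])

    def stacked_bands(self) -> pd.DataFrame:
        """Cumulative occupation bands for a stacked plot (state order)."""
        bands = np.cumsum(self.occupation, axis=1)
        cols = {"time": self.times}
        for s_idx, state in enumerate(self.space.state_ids):
            cols[self.space.label(state)] = bands[:, s_idx]
        return pd.DataFrame(cols)


def intensity_matrix(
    model_set: ModelSet, t: float, x: dict[str, float]
) -> np.ndarray:
    """Markov intensity matrix Q(t) for covariate profile ``x``.

    Off-diagonal entries are the transition hazards
    ``scale * shape * t**(shape-1) * exp(x beta)`` for allowed transitions
    and 0 otherwise; diagonals are minus the row sums, and absorbing rows
    are identically zero.
    """
    space = model_set.space
    if t < 0 or (t == 0 and np.any(model_set.shapes < 1)):
        raise ValueError(
            f"hazard undefined at t={t} (shape < 1 diverges at 0); "
            f"start the grid at a small positive time"
        )
    eta = model_set.linear_predictor(x)
    n = space.n_states
    Q = np.zeros((n, n))
    for k, (a, b) in enumerate(space.transitions, start=1):
        fit = model_set.fits[k]
        h = fit.scale * fit.shape * t ** (fit.shape - 1.0) * np.exp(eta[k - 1])
        Q[space.state_index(a), space.state_index(b)] = h
    np.fill_diagonal(Q, 0.0)
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    return Q


def _first_order_step(
    model_set: ModelSet, eta: np.ndarray, s: float, t: float
) -> np.ndarray:
    """P(s, t) to first order in the cumulative-hazard increments.

    Used to step across the origin where shapes < 1 make Q singular; the
    neglected terms are O(increment^2), negligible for t - s ~ 1e-6.
    """
    space = model_set.space
    n = space.n_states
    P = np.eye(n)
    for k, (a, b) in enumerate(space.transitions, start=1):
        fit = model_set.fits[k]
        dH = fit.scale * np.exp(eta[k - 1]) * (t**fit.shape - s**fit.shape)
        ai, bi = space.state_index(a), space.state_index(b)
        P[ai, bi] += dH
        P[ai, ai] -= dH
    return P


def transition_probabilities_ode(
    model_set: ModelSet,
    s: float = 0.0,
    times: np.ndarray | None = None,
    x: dict[str, float] | None = None,
    rtol: float = 1e-11,
    atol: float = 1e-13,
) -> ProbabilityCurves:
    """Solve the Kolmogorov forward equation for P(s, t) on a time grid.

    Negative entries within solver round-off (above -1e-8) are clipped to
    zero and rows renormalized; anything more negative raises.
    """
    space = model_set.space
    if times is None:
        times = DEFAULT_GRID[DEFAULT_GRID >= s]
    times = np.asarray(times, dtype=float)
    if s < 0 or np.any(times < s):
        raise ValueError("need 0 <= s <= times")
    eta = model_set.linear_predictor(x or {})
    n = space.n_states
    shapes = model_set.shapes
    scales = model_set.scales * np.exp(eta)
    from_idx = np.array([space.state_index(a) for a, _ in space.transitions])
    to_idx = np.array([space.state_index(b) for _, b in space.transitions])

    def rhs(t: float, p_flat: np.ndarray) -> np.ndarray:
        haz = scales * shapes * t ** (shapes - 1.0)
        Q = np.zeros((n, n))
        Q[from_idx, to_idx] = haz
        Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
        return (p_flat.reshape(n, n) @ Q).ravel()

    start = max(s, T_EPS)
    P0 = np.eye(n)
    if s < start:
        P0 = _first_order_step(model_set, eta, s, start)

    t_end = max(times.max(), start)
    interior = times[times > start]
    if t_end > start:
        sol = solve_ivp(
            rhs,
            (start, t_end),
            P0.ravel(),
            t_eval=interior,
            method="DOP853",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"Kolmogorov forward solver failed: {sol.message}")
        solved = {float(t): sol.y[:, j].reshape(n, n) for j, t in enumerate(sol.t)}
    else:
        solved = {}

    P = np.empty((len(times), n, n))
    for i, t in enumerate(times):
        if t <= s:
            P[i] = np.eye(n)
        elif t <= start:
            P[i] = _first_order_step(model_set, eta, s, t)
        else:
            P[i] = solved[float(t)]
    if P.min() < -_NEG_CLIP:
        raise RuntimeError(
            f"solver produced probability {P.min():.3e} < -{_NEG_CLIP}"
        )
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=2, keepdims=True)
    init_idx = 0
    return ProbabilityCurves(
        space=space,
        times=times,
        P=P,
        occupation=P[:, init_idx, :],
        profile=dict(x or {}),
        s=s,
        method="ode",
        initial_state=space.state_ids[init_idx],
    )


# ---------------------------------------------------------------------------
# path simulation


def sample_paths(
    space: StateSpace,
    shapes: np.ndarray,
    coef: np.ndarray,
    start_states: np.ndarray,
    start_times: np.ndarray,
    horizons: np.ndarray,
    rng: np.random.Generator,
) -> list[list[tuple[int, float]]]:
    """Simulate Markov paths under Weibull transition intensities.

    ``coef[i, k-1] = scale_k * exp(x_i beta_k)`` so that the cumulative
    hazard of transition k for subject i over (t0, t] is
    ``coef[i, k-1] * (t**shape_k - t0**shape_k)``.  For each sojourn an
    Exp(1) draw E is inverted through the *total* cumulative hazard out of
    the current state by vectorized bisection (to 1e-8 years); the
    destination is drawn proportionally to the cause-specific hazards at
    the event time.  Paths are truncated at ``horizons`` (censoring /
    prediction horizon); a subject still in a state at its horizon simply
    stays there.

    Returns one ``[(state, entry_time), ...]`` trajectory per subject,
    starting with ``(start_state, start_time)``.
    """
    n = len(start_states)
    states = np.asarray(start_states, dtype=int).copy()
    times = np.asarray(start_times, dtype=float).copy()
    horizons = np.broadcast_to(np.asarray(horizons, dtype=float), (n,)).copy()
    paths: list[list[tuple[int, float]]] = [
        [(int(states[i]), float(times[i]))] for i in range(n)
    ]
    absorbing = {s for s, ab in zip(space.state_ids, space.absorbing) if ab}
    active = np.array(
        [states[i] not in absorbing and times[i] < horizons[i] for i in range(n)]
    )
    for _ in range(space.n_states):  # path length bounded by state count
        if not active.any():
            break
        for state_id in space.state_ids:
            if state_id in absorbing:
                continue
            sel = np.flatnonzero(active & (states == state_id))
            if sel.size == 0:
                continue
            ks = np.array(space.transitions_from(state_id)) - 1
            gam = shapes[ks]  # (m_k,)
            c = coef[np.ix_(sel, ks)]  # (m, m_k)
            t0 = times[sel]
            cap = horizons[sel]
            E = rng.exponential(size=sel.size)
            p0 = np.power(t0[:, None], gam[None, :])
            H_cap = np.sum(c * (np.power(cap[:, None], gam[None, :]) - p0), axis=1)
            has_event = H_cap >= E
            # bisection for subjects whose event falls before the horizon
            lo = t0.copy()
            hi = cap.copy()
            idx = np.flatnonzero(has_event)
            if idx.size:
                lo_e, hi_e = lo[idx], hi[idx]
                c_e, p0_e, E_e = c[idx], p0[idx], E[idx]
                while np.max(hi_e - lo_e) > _BISECT_TOL:
                    mid = 0.5 * (lo_e + hi_e)
                    H_mid = np.sum(
                        c_e * (np.power(mid[:, None], gam[None, :]) - p0_e), axis=1
                    )
                    ge = H_mid >= E_e
                    hi_e = np.where(ge, mid, hi_e)
                    lo_e = np.where(ge, lo_e, mid)
                t_event = 0.5 * (lo_e + hi_e)
                # destination ~ cause-specific hazard at the event time
                haz = (
                    c_e
                    * gam[None, :]
                    * np.power(t_event[:, None], gam[None, :] - 1.0)
                )
                probs = haz / haz.sum(axis=1, keepdims=True)
                u = rng.uniform(size=idx.size)
                dest_col = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
                dest_states = np.array(
                    [space.transitions[k][1] for k in ks], dtype=int
                )[dest_col]
                gsel = sel[idx]
                states[gsel] = dest_states
                times[gsel] = t_event
                for g, st, tt in zip(gsel, dest_states, t_event):
                    paths[g].append((int(st), float(tt)))
                    if int(st) in absorbing:
                        active[g] = False
            # no event before horizon -> subject leaves the risk set there
            no_event = sel[~has_event]
            active[no_event] = False
    return paths


def simulate_transition_probabilities(
    model_set: ModelSet,
    s: float = 0.0,
    times: np.ndarray | None = None,
    x: dict[str, float] | None = None,
    n_paths: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> ProbabilityCurves:
    """Monte-Carlo estimate of P(s, t): empirical state frequencies of
    simulated paths started in each non-absorbing state at time ``s``."""
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    space = model_set.space
    if times is None:
        times = DEFAULT_GRID[DEFAULT_GRID >= s]
    times = np.asarray(times, dtype=float)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    eta = model_set.linear_predictor(x or {})
    coef_row = model_set.scales * np.exp(eta)
    n = space.n_states
    horizon = float(max(times.max(), s)) * (1.0 + 1e-9) + T_EPS
    P = np.zeros((len(times), n, n))
    state_pos = {sid: i for i, sid in enumerate(space.state_ids)}
    for a_idx, a in enumerate(space.state_ids):
        if space.absorbing[a_idx]:
            P[:, a_idx, a_idx] = 1.0
            continue
        start = max(s, T_EPS) if s == 0 and np.any(model_set.shapes < 1) else s
        paths = sample_paths(
            space,
            model_set.shapes,
            np.tile(coef_row, (n_paths, 1)),
            np.full(n_paths, a, dtype=int),
            np.full(n_paths, start),
            np.full(n_paths, horizon),
            rng,
        )
        # padded jump arrays: state occupied at t is the last jump with time <= t
        L = max(len(p) for p in paths)
        JT = np.full((n_paths, L), np.inf)
        JS = np.zeros((n_paths, L), dtype=int)
        for i, path in enumerate(paths):
            m = len(path)
            JT[i, :m] = [t for _, t in path]
            JS[i, :m] = [state_pos[st] for st, _ in path]
            JS[i, m:] = JS[i, m - 1]
        row_idx = np.arange(n_paths)
        for j, t in enumerate(times):
            pos = np.clip((JT <= t).sum(axis=1) - 1, 0, L - 1)
            counts = np.bincount(JS[row_idx, pos], minlength=n)
            P[j, a_idx, :] = counts / n_paths
    init_idx = 0
    return ProbabilityCurves(
        space=space,
        times=times,
        P=P,
        occupation=P[:, init_idx, :],
        profile=dict(x or {}),
        s=s,
        method="sim",
        initial_state=space.state_ids[init_idx],
    )


def state_occupation(
    model_set: ModelSet,
    times: np.ndarray | None = None,
    x: dict[str, float] | None = None,
    initial_state: int | None = None,
    method: str = "ode",
    n_paths: int = 10_000,
    seed: int = 0,
) -> ProbabilityCurves:
    """State-occupation probabilities from ``initial_state`` at time 0.

    The occupation vector at time t is the ``initial_state`` row of
    P(0, t); the curves object also exposes cumulative stacked bands for
    plotting (alive-in-initial first, then intermediate states, then the
    absorbing state, i.e. state order).
    """
    space = model_set.space
    if initial_state is None:
        initial_state = space.state_ids[0]
    if space.is_absorbing(initial_state):
        raise ValueError(f"initial state {initial_state} is absorbing")
    if method == "ode":
        curves = transition_probabilities_ode(model_set, 0.0, times, x)
    elif method == "sim":
        curves = simulate_transition_probabilities(
            model_set, 0.0, times, x, n_paths=n_paths, seed=seed
        )
    else:
        raise ValueError(f"method must be 'ode' or 'sim', got {method!r}")
    init_idx = space.state_index(initial_state)
    curves.occupation = curves.P[:, init_idx, :]
    curves.initial_state = initial_state
    return curves


def population_average_occupation(
    model_set: ModelSet,
    profiles: pd.DataFrame,
    times: np.ndarray | None = None,
    initial_state: int | None = None,
) -> ProbabilityCurves:
    """Cohort-averaged occupation curves: mean of per-profile ODE curves
    weighted by profile multiplicity (the marginal, not the curve at the
    mean covariates)."""
    space = model_set.space
    if times is None:
        times = DEFAULT_GRID
    uniq = profiles.groupby(list(profiles.columns), as_index=False).size()
    weights = uniq["size"].to_numpy(dtype=float)
    weights /= weights.sum()
    n = space.n_states
    P = np.zeros((len(times), n, n))
    for w, (_, row) in zip(weights, uniq.drop(columns="size").iterrows()):
        curves = transition_probabilities_ode(
            model_set, 0.0, times, row.to_dict()
        )
        P += w * curves.P
    if initial_state is None:
        initial_state = space.state_ids[0]
    init_idx = space.state_index(initial_state)
    return ProbabilityCurves(
        space=space,
        times=np.asarray(times, dtype=float),
        P=P,
        occupation=P[:, init_idx, :],
        profile={},
        s=0.0,
        method="ode-population-average",
        initial_state=initial_state,
    )
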
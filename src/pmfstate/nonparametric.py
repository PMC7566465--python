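"""Nonparametric estimators for Markov multistate event histories.

Nelson-Aalen cumulative transition hazards and the Aalen-Johansen
product-integral estimator of transition probabilities.  Both honour
delayed entry: a subject is at risk for the transitions out of state ``a``
over ``(t_start, t_stop]`` exactly as recorded in the stacked long-format
rows.  These estimators are model-free and serve as the validation oracle
for the parametric predictions on simulated data; they are also part of
the public interface.

Tie convention: a censoring recorded at an event time is still counted at
risk for that event (censor-after-event).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .state_space import StateSpace, TransitionRow
from .predict import ProbabilityCurves

__all__ = ["StepCurve", "nelson_aalen", "aalen_johansen"]


@dataclass
class StepCurve:
    """Right-continuous step function: value ``values[i]`` from
    ``jump_times[i]`` (inclusive) onward, 0 before the first jump."""

    jump_times: np.ndarray
    values: np.ndarray

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if len(self.jump_times) == 0:
            out = np.zeros_like(t)
            return out if out.ndim else 0.0
        idx = np.searchsorted(self.jump_times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)


def _risk_set_counter(t_start: np.ndarray, t_stop: np.ndarray):
    """Return Y(t) = #{i: t_start_i < t <= t_stop_i}, vectorized over t."""
    starts = np.sort(t_start)
    stops = np.sort(t_stop)

    def Y(t: np.ndarray) -> np.ndarray:
        return np.searchsorted(starts, t, side="left") - np.searchsorted(
            stops, t, side="left"
        )

    return Y


def nelson_aalen(
    rows: Sequence[TransitionRow], transition_index: int
) -> StepCurve:
    """Nelson-Aalen cumulative hazard for one transition.

    At each event time the increment is (events at t) / (number at risk
    just before t), with delayed entry honoured through the row intervals.
    No events gives a flat zero curve.
    """
    rows = [r for r in rows if r.transition == transition_index]
    if not rows:
        return StepCurve(np.array([]), np.array([]))
    t_start = np.array([r.t_start for r in rows])
    t_stop = np.array([r.t_stop for r in rows])
    event_times = np.array(sorted({r.t_stop for r in rows if r.status == 1}))
    if event_times.size == 0:
        return StepCurve(np.array([]), np.array([]))
    d = np.array(
        [sum(1 for r in rows if r.status == 1 and r.t_stop == t) for t in event_times],
        dtype=float,
    )
    Y = _risk_set_counter(t_start, t_stop)(event_times).astype(float)
    increments = d / Y
    return StepCurve(event_times, np.cumsum(increments))


def aalen_johansen(
    rows: Sequence[TransitionRow],
    space: StateSpace,
    s: float = 0.0,
    times: np.ndarray | None = None,
) -> ProbabilityCurves:
    """Aalen-Johansen estimator of the transition-probability matrix.

    P(s, t) is the product integral over event times u in (s, t] of
    ``I + dA(u)`` where ``dA`` collects the Nelson-Aalen increments into
    an intensity-increment matrix.  Rows sum to one exactly (each factor
    is a stochastic matrix).

    Raises
    ------
    ValueError
        If some increment would make a diagonal entry negative (more
        events out of a state at one instant than subjects at risk can
        support: the data are too sparse for the product integral).
    """
    n = space.n_states
    if times is None:
        all_stop = [r.t_stop for r in rows]
        times = np.linspace(s, max(all_stop) if all_stop else s, 101)
    times = np.asarray(times, dtype=float)

    # representative rows per from-state (intervals repeat across the
    # transitions out of a state, so take the lowest-indexed one)
    rep_transition = {
        a: min(space.transitions_from(a))
        for a in space.state_ids
        if not space.is_absorbing(a)
    }
    risk_counters = {}
    for a, k in rep_transition.items():
        rs = [r for r in rows if r.transition == k]
        if rs:
            risk_counters[a] = _risk_set_counter(
                np.array([r.t_start for r in rs]),
                np.array([r.t_stop for r in rs]),
            )

    event_times = np.array(
        sorted({r.t_stop for r in rows if r.status == 1 and r.t_stop > s})
    )
    horizon = times.max()
    event_times = event_times[event_times <= horizon]

    # events per transition per event time
    d = np.zeros((event_times.size, space.n_transitions))
    time_pos = {t: i for i, t in enumerate(event_times)}
    for r in rows:
        if r.status == 1 and s < r.t_stop <= horizon:
            d[time_pos[r.t_stop], r.transition - 1] += 1

    Y = np.zeros((event_times.size, n))
    for a, counter in risk_counters.items():
        Y[:, space.state_index(a)] = counter(event_times)

    P_steps = np.empty((event_times.size, n, n))
    P = np.eye(n)
    for i, t in enumerate(event_times):
        dA = np.zeros((n, n))
        for k, (a, b) in enumerate(space.transitions, start=1):
            if d[i, k - 1] > 0:
                ai = space.state_index(a)
                dA[ai, space.state_index(b)] += d[i, k - 1] / Y[i, ai]
        np.fill_diagonal(dA, 0.0)
        diag = -dA.sum(axis=1)
        if np.any(1.0 + diag < 0):
            raise ValueError(
                f"Aalen-Johansen increment at t={t} makes a diagonal "
                "negative; data too sparse"
            )
        dA[np.arange(n), np.arange(n)] = diag
        P = P @ (np.eye(n) + dA)
        P_steps[i] = P

    P_grid = np.empty((times.size, n, n))
    idx = np.searchsorted(event_times, times, side="right") - 1
    for j, i in enumerate(idx):
        P_grid[j] = np.eye(n) if i < 0 else P_steps[i]
    init_idx = 0
    return ProbabilityCurves(
        space=space,
        times=times,
        P=P_grid,
        occupation=P_grid[:, init_idx, :],
        profile={},
        s=s,
        method="aalen-johansen",
        initial_state=space.state_ids[init_idx],
    )
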
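"""Multistate topology and event-history data structures.

The default topology is the four-state clinical course of prefibrotic
primary myelofibrosis (pre-PMF): patients start in the pre-PMF state and can
move to overt PMF, to acute myeloid leukemia (AML), or directly to death;
overt PMF can progress to AML or death; AML can only progress to death.
Death is the single absorbing state, giving six allowed transitions.

Subject trajectories are converted to the stacked "long format" used by
transition-specific hazard regression: one row per at-risk interval per
transition, with delayed entry (left truncation) under the clock-forward
(Markov) time scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StateSpace",
    "SubjectRecord",
    "TransitionRow",
    "StateSpaceError",
    "TrajectoryError",
    "default_state_space",
    "validate_state_space",
    "build_long_format",
    "count_transitions",
    "long_format_to_frame",
    "frame_to_long_format",
    "subjects_from_long_format",
    "read_subject_csv",
    "write_subject_csv",
    "read_state_space_yaml",
    "write_state_space_yaml",
]


class StateSpaceError(ValueError):
    """Structural violation in a multistate topology."""


class TrajectoryError(ValueError):
    """A subject trajectory is inconsistent with the state space."""


@dataclass(frozen=True)
class StateSpace:
    """Directed multistate topology.

    Parameters
    ----------
    state_ids
        Ordered integer state codes.
    state_labels
        Human-readable label per state, same order as ``state_ids``.
    absorbing
        Boolean flag per state; absorbing states have no out-transitions.
    transitions
        Ordered ``(from_state, to_state)`` pairs.  The 1-based position in
        this list is the transition index used throughout the package.
    """

    state_ids: tuple[int, ...]
    state_labels: tuple[str, ...]
    absorbing: tuple[bool, ...]
    transitions: tuple[tuple[int, int], ...]

    @property
    def n_states(self) -> int:
        return len(self.state_ids)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def state_index(self, state_id: int) -> int:
        """0-based position of a state id."""
        try:
            return self.state_ids.index(state_id)
        except ValueError:
            raise StateSpaceError(f"unknown state id {state_id}") from None

    def transition_index(self, from_state: int, to_state: int) -> int:
        """1-based index of the transition ``from_state -> to_state``."""
        try:
            return self.transitions.index((from_state, to_state)) + 1
        except ValueError:
            raise StateSpaceError(
                f"transition {from_state}->{to_state} is not allowed"
            ) from None

    def transitions_from(self, state_id: int) -> list[int]:
        """1-based indices of transitions leaving ``state_id``."""
        return [k + 1 for k, (a, _) in enumerate(self.transitions) if a == state_id]

    def is_absorbing(self, state_id: int) -> bool:
        return self.absorbing[self.state_index(state_id)]

    def label(self, state_id: int) -> str:
        return self.state_labels[self.state_index(state_id)]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's covariates and observed multistate trajectory.

    ``trajectory`` lists ``(state_id, entry_time)`` pairs in years since
    diagnosis, starting at the initial state at time 0.  ``censoring_time``
    is the end of observation for subjects whose last state is
    non-absorbing; it must be ``None`` when the subject reached an
    absorbing state.
    """

    subject_id: str
    covariates: dict[str, float]
    trajectory: tuple[tuple[int, float], ...]
    censoring_time: float | None = None

    def final_state(self) -> int:
        return self.trajectory[-1][0]

    def end_of_followup(self) -> float:
        if self.censoring_time is not None:
            return float(self.censoring_time)
        return float(self.trajectory[-1][1])


@dataclass(frozen=True)
class TransitionRow:
    """One at-risk interval for one transition (the fitting unit)."""

    subject_id: str
    transition: int
    t_start: float
    t_stop: float
    status: int
    covariates: dict[str, float]


PRE_PMF, OVERT_PMF, AML, DEATH = 1, 2, 3, 4


def default_state_space() -> StateSpace:
    """The four-state / six-transition pre-PMF progression topology."""
    return StateSpace(
        state_ids=(PRE_PMF, OVERT_PMF, AML, DEATH),
        state_labels=("pre-PMF", "overt PMF", "AML", "death"),
        absorbing=(False, False, False, True),
        transitions=((1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)),
    )


def validate_state_space(space: StateSpace) -> StateSpace:
    """Check the structural invariants of a topology; return it unchanged.

    Raises
    ------
    StateSpaceError
        Naming the offending state or transition: duplicate ids, a
        transition leaving an absorbing state, unknown endpoints,
        duplicate transitions, or self-loops.
    """
    if len(space.state_ids) == 0:
        raise StateSpaceError("state space has no states")
    if len(set(space.state_ids)) != len(space.state_ids):
        raise StateSpaceError("duplicate state ids")
    if not (len(space.state_labels) == len(space.absorbing) == len(space.state_ids)):
        raise StateSpaceError("labels/absorbing flags do not match state_ids")
    seen: set[tuple[int, int]] = set()
    for k, (a, b) in enumerate(space.transitions, start=1):
        if a not in space.state_ids or b not in space.state_ids:
            raise StateSpaceError(f"transition {k} ({a}->{b}) uses unknown state")
        if a == b:
            raise StateSpaceError(f"transition {k} ({a}->{b}) is a self-loop")
        if (a, b) in seen:
            raise StateSpaceError(f"duplicate transition {a}->{b}")
        seen.add((a, b))
        if space.absorbing[space.state_index(a)]:
            raise StateSpaceError(
                f"transition {k} ({a}->{b}) leaves absorbing state {a}"
            )
    return space


def _validate_trajectory(subject: SubjectRecord, space: StateSpace) -> None:
    traj = subject.trajectory
    if len(traj) == 0:
        raise TrajectoryError(f"subject {subject.subject_id}: empty trajectory")
    if traj[0][1] != 0.0:
        raise TrajectoryError(
            f"subject {subject.subject_id}: trajectory must start at time 0"
        )
    times = [t for _, t in traj]
    if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
        raise TrajectoryError(
            f"subject {subject.subject_id}: entry times must strictly increase"
        )
    for (a, _), (b, _) in zip(traj, traj[1:]):
        if (a, b) not in space.transitions:
            raise TrajectoryError(
                f"subject {subject.subject_id}: disallowed jump {a}->{b}"
            )
    last_state, last_time = traj[-1]
    if space.is_absorbing(last_state):
        if subject.censoring_time is not None:
            raise TrajectoryError(
                f"subject {subject.subject_id}: censoring time given after "
                f"absorbing state {last_state}"
            )
    else:
        if subject.censoring_time is None:
            raise TrajectoryError(
                f"subject {subject.subject_id}: non-absorbing final state "
                f"{last_state} requires a censoring time"
            )
        if subject.censoring_time <= last_time:
            raise TrajectoryError(
                f"subject {subject.subject_id}: censoring time "
                f"{subject.censoring_time} not after last entry {last_time}"
            )


def build_long_format(
    subjects: Sequence[SubjectRecord],
    space: StateSpace,
    clock: str = "forward",
) -> list[TransitionRow]:
    """Expand trajectories into stacked transition-specific at-risk rows.

    For each sojourn of a subject in a non-absorbing state ``s`` over
    ``(t_entry, t_exit]``, one row is emitted per transition out of ``s``,
    all sharing the interval; ``status`` is 1 only on the row of the
    transition actually taken (0 everywhere for a censored sojourn).

    ``clock='forward'`` keeps times on the years-since-diagnosis scale, so
    sojourns entered after time 0 appear as delayed entry (``t_start > 0``);
    ``clock='reset'`` restarts the clock at each state entry (semi-Markov),
    giving ``t_start = 0`` and ``t_stop`` equal to the sojourn duration.
    """
    if clock not in ("forward", "reset"):
        raise ValueError(f"clock must be 'forward' or 'reset', got {clock!r}")
    validate_state_space(space)
    rows: list[TransitionRow] = []
    for subj in subjects:
        _validate_trajectory(subj, space)
        traj = list(subj.trajectory)
        for i, (state, t_entry) in enumerate(traj):
            if space.is_absorbing(state):
                break
            if i + 1 < len(traj):
                next_state, t_exit = traj[i + 1]
                taken = space.transition_index(state, next_state)
            else:
                next_state, t_exit = None, subj.censoring_time
                taken = None
            if clock == "forward":
                t0, t1 = t_entry, t_exit
            else:
                t0, t1 = 0.0, t_exit - t_entry
            for k in space.transitions_from(state):
                rows.append(
                    TransitionRow(
                        subject_id=subj.subject_id,
                        transition=k,
                        t_start=float(t0),
                        t_stop=float(t1),
                        status=int(k == taken),
                        covariates=subj.covariates,
                    )
                )
    return rows


def count_transitions(
    subjects: Sequence[SubjectRecord], space: StateSpace
) -> pd.DataFrame:
    """Per-transition jump counts and percentages of the initial cohort.

    Returns a frame with one row per transition: ``transition``,
    ``from_state``, ``to_state``, ``n`` (subjects making the jump) and
    ``pct_of_cohort`` (``100 * n / n_subjects`` rounded to one decimal).
    The frame's ``attrs`` carry ``n_subjects`` and ``ending_counts``, the
    number of subjects ending follow-up in each state.
    """
    if len(subjects) == 0:
        raise ValueError("empty cohort")
    validate_state_space(space)
    n_jump = {k: 0 for k in range(1, space.n_transitions + 1)}
    ending = {s: 0 for s in space.state_ids}
    for subj in subjects:
        _validate_trajectory(subj, space)
        for (a, _), (b, _) in zip(subj.trajectory, subj.trajectory[1:]):
            n_jump[space.transition_index(a, b)] += 1
        ending[subj.final_state()] += 1
    n0 = len(subjects)
    out = pd.DataFrame(
        {
            "transition": list(n_jump.keys()),
            "from_state": [space.transitions[k - 1][0] for k in n_jump],
            "to_state": [space.transitions[k - 1][1] for k in n_jump],
            "n": list(n_jump.values()),
        }
    )
    out["pct_of_cohort"] = (100.0 * out["n"] / n0).round(1)
    out.attrs["n_subjects"] = n0
    out.attrs["ending_counts"] = ending
    return out


# ---------------------------------------------------------------------------
# long format <-> DataFrame / trajectory round trips


def long_format_to_frame(rows: Iterable[TransitionRow]) -> pd.DataFrame:
    rows = list(rows)
    cov_names: list[str] = []
    for r in rows:
        for name in r.covariates:
            if name not in cov_names:
                cov_names.append(name)
    data = {
        "subject_id": [r.subject_id for r in rows],
        "transition": [r.transition for r in rows],
        "t_start": [r.t_start for r in rows],
        "t_stop": [r.t_stop for r in rows],
        "status": [r.status for r in rows],
    }
    for name in cov_names:
        data[name] = [r.covariates.get(name, np.nan) for r in rows]
    return pd.DataFrame(data)


def frame_to_long_format(frame: pd.DataFrame) -> list[TransitionRow]:
    base = {"subject_id", "transition", "t_start", "t_stop", "status"}
    cov_names = [c for c in frame.columns if c not in base]
    return [
        TransitionRow(
            subject_id=str(rec["subject_id"]),
            transition=int(rec["transition"]),
            t_start=float(rec["t_start"]),
            t_stop=float(rec["t_stop"]),
            status=int(rec["status"]),
            covariates={c: float(rec[c]) for c in cov_names},
        )
        for rec in frame.to_dict("records")
    ]


def subjects_from_long_format(
    rows: Sequence[TransitionRow], space: StateSpace
) -> list[SubjectRecord]:
    """Reconstruct clock-forward trajectories from stacked rows.

    Inverse of :func:`build_long_format` with ``clock='forward'``; used for
    round-trip validation and for re-reading exported long-format CSVs.
    """
    by_subject: dict[str, list[TransitionRow]] = {}
    for r in rows:
        by_subject.setdefault(r.subject_id, []).append(r)
    subjects = []
    for sid, rs in by_subject.items():
        # one sojourn per distinct (t_start, t_stop) interval
        sojourns: dict[tuple[float, float], list[TransitionRow]] = {}
        for r in rs:
            sojourns.setdefault((r.t_start, r.t_stop), []).append(r)
        traj: list[tuple[int, float]] = []
        censoring: float | None = None
        for (t0, t1), srows in sorted(sojourns.items()):
            state = space.transitions[srows[0].transition - 1][0]
            if not traj:
                traj.append((state, t0))
            taken = [r for r in srows if r.status == 1]
            if len(taken) > 1:
                raise TrajectoryError(
                    f"subject {sid}: multiple events in one sojourn"
                )
            if taken:
                traj.append((space.transitions[taken[0].transition - 1][1], t1))
            else:
                censoring = t1
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                covariates=rs[0].covariates,
                trajectory=tuple(traj),
                censoring_time=censoring,
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# CSV / YAML interfaces

_TIME_COLS = {2: "time_overtPMF", 3: "time_AML", 4: "time_death"}


def write_subject_csv(subjects: Sequence[SubjectRecord], path) -> None:
    """Write a cohort as one wide row per subject.

    Columns: ``subject_id``, covariates, ``time_overtPMF``, ``time_AML``,
    ``time_death`` (empty if the state was never reached), ``time_censor``
    (empty if the subject died).  Only the default 4-state topology is
    representable in this schema.
    """
    cov_names: list[str] = []
    for s in subjects:
        for name in s.covariates:
            if name not in cov_names:
                cov_names.append(name)
    recs = []
    for s in subjects:
        rec: dict[str, object] = {"subject_id": s.subject_id}
        rec.update({c: s.covariates.get(c, np.nan) for c in cov_names})
        entry = {state: t for state, t in s.trajectory}
        for state, col in _TIME_COLS.items():
            rec[col] = entry.get(state, np.nan)
        rec["time_censor"] = (
            s.censoring_time if s.censoring_time is not None else np.nan
        )
        recs.append(rec)
    pd.DataFrame(recs).to_csv(path, index=False)


def read_subject_csv(path) -> list[SubjectRecord]:
    """Read the wide subject schema written by :func:`write_subject_csv`."""
    frame = pd.read_csv(path)
    required = {"subject_id", *_TIME_COLS.values(), "time_censor"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"subject CSV missing columns: {sorted(missing)}")
    cov_names = [c for c in frame.columns if c not in required]
    subjects = []
    for i, rec in enumerate(frame.to_dict("records")):
        events = [(1, 0.0)]
        for state, col in _TIME_COLS.items():
            if pd.notna(rec[col]):
                events.append((state, float(rec[col])))
        events.sort(key=lambda e: e[1])
        censor = float(rec["time_censor"]) if pd.notna(rec["time_censor"]) else None
        try:
            subjects.append(
                SubjectRecord(
                    subject_id=str(rec["subject_id"]),
                    covariates={c: float(rec[c]) for c in cov_names},
                    trajectory=tuple(events),
                    censoring_time=censor,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"subject CSV row {i + 2}: {exc}") from exc
    return subjects


def write_state_space_yaml(space: StateSpace, path) -> None:
    doc = {
        "states": [
            {"id": s, "label": lab, "absorbing": bool(ab)}
            for s, lab, ab in zip(
                space.state_ids, space.state_labels, space.absorbing
            )
        ],
        "transitions": [{"from": a, "to": b} for a, b in space.transitions],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_state_space_yaml(path) -> StateSpace:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    states = doc["states"]
    space = StateSpace(
        state_ids=tuple(int(s["id"]) for s in states),
        state_labels=tuple(str(s["label"]) for s in states),
        absorbing=tuple(bool(s["absorbing"]) for s in states),
        transitions=tuple(
            (int(t["from"]), int(t["to"])) for t in doc["transitions"]
        ),
    )
    return validate_state_space(space)
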
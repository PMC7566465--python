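"""Topology validation, long-format construction, transition counting."""

import numpy as np
import pandas as pd
import pytest

import pmfstate as pm
from pmfstate.state_space import StateSpaceError, TrajectoryError


class TestValidation:
    def test_default_topology_accepted(self, space):
        assert pm.validate_state_space(space) is space
        assert space.n_states == 4
        assert space.n_transitions == 6
        assert space.transitions == ((1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4))

    def test_transition_out_of_absorbing_rejected(self):
        bad = pm.StateSpace(
            state_ids=(1, 2),
            state_labels=("alive", "dead"),
            absorbing=(False, True),
            transitions=((1, 2), (2, 1)),
        )
        with pytest.raises(StateSpaceError, match="absorbing"):
            pm.validate_state_space(bad)

    def test_minimal_two_state_model_accepted(self, two_state_space):
        assert pm.validate_state_space(two_state_space).n_transitions == 1

    @pytest.mark.parametrize(
        "transitions, msg",
        [
            (((1, 2), (1, 2)), "duplicate"),
            (((1, 1),), "self-loop"),
            (((1, 9),), "unknown"),
        ],
    )
    def test_structural_errors_name_offender(self, transitions, msg):
        bad = pm.StateSpace((1, 2), ("a", "b"), (False, True), transitions)
        with pytest.raises(StateSpaceError, match=msg):
            pm.validate_state_space(bad)


class TestLongFormat:
    def test_censored_single_sojourn(self, space):
        subj = pm.SubjectRecord("s", {}, ((1, 0.0),), censoring_time=5.0)
        rows = pm.build_long_format([subj], space)
        assert {(r.transition, r.t_start, r.t_stop, r.status) for r in rows} == {
            (1, 0.0, 5.0, 0),
            (2, 0.0, 5.0, 0),
            (3, 0.0, 5.0, 0),
        }

    def test_two_sojourn_trajectory_clock_forward(self, space):
        subj = pm.SubjectRecord("s", {}, ((1, 0.0), (2, 3.0), (4, 7.0)))
        rows = pm.build_long_format([subj], space, clock="forward")
        by_k = {r.transition: r for r in rows}
        assert set(by_k) == {1, 2, 3, 4, 5}
        for k in (1, 2, 3):
            assert (by_k[k].t_start, by_k[k].t_stop) == (0.0, 3.0)
        for k in (4, 5):
            assert (by_k[k].t_start, by_k[k].t_stop) == (3.0, 7.0)
        assert [k for k, r in by_k.items() if r.status] == [1, 5]

    def test_clock_reset_restarts_sojourns(self, space):
        subj = pm.SubjectRecord("s", {}, ((1, 0.0), (2, 3.0), (4, 7.0)))
        rows = pm.build_long_format([subj], space, clock="reset")
        later = [r for r in rows if r.transition in (4, 5)]
        assert all(r.t_start == 0.0 and r.t_stop == 4.0 for r in later)

    def test_disallowed_jump_names_subject_and_pair(self, space):
        subj = pm.SubjectRecord("bad", {}, ((1, 0.0), (4, 2.0), (3, 5.0)))
        with pytest.raises(TrajectoryError, match="bad.*4->3"):
            pm.build_long_format([subj], space)

    def test_zero_length_sojourn_rejected(self, space):
        subj = pm.SubjectRecord("s", {}, ((1, 0.0), (2, 3.0)), censoring_time=3.0)
        with pytest.raises(TrajectoryError):
            pm.build_long_format([subj], space)

    def test_status_sums_match_direct_counting(self, space):
        """Summing status by transition reproduces count_transitions."""
        cohort = pm.generate_cohort(pm.reference_config(), seed=11)
        rows = pm.build_long_format(cohort, space)
        frame = pm.long_format_to_frame(rows)
        by_status = frame.groupby("transition")["status"].sum()
        counts = pm.count_transitions(cohort, space)
        for k in range(1, 7):
            assert by_status.get(k, 0) == counts.loc[counts.transition == k, "n"].item()

    def test_round_trip_through_trajectories(self, space, small_cohort):
        rows = pm.build_long_format(small_cohort, space)
        rebuilt = pm.subjects_from_long_format(rows, space)
        rows2 = pm.build_long_format(rebuilt, space)
        key = lambda r: (r.subject_id, r.transition, r.t_start)
        assert sorted(rows, key=key) == sorted(rows2, key=key)


class TestCounts:
    def test_reference_percentages_one_decimal(self, space):
        """58/18/66 direct jumps out of 382 give 15.2 / 4.7 / 17.3 percent."""
        cohort = _cohort_with_counts(382, n12=58, n13=18, n14=66, n23=10,
                                     n24=14, n34=25)
        counts = pm.count_transitions(cohort, space)
        assert counts["pct_of_cohort"].tolist()[:3] == [15.2, 4.7, 17.3]
        assert counts["n"].tolist() == [58, 18, 66, 10, 14, 25]

    def test_reference_outcome_tallies(self, space):
        """Conservation arithmetic: who is where at end of follow-up."""
        cohort = _cohort_with_counts(382, n12=58, n13=18, n14=66, n23=10,
                                     n24=14, n34=25)
        counts = pm.count_transitions(cohort, space)
        ending = counts.attrs["ending_counts"]
        assert ending == {1: 240, 2: 34, 3: 3, 4: 105}

    def test_nobody_moves(self, space):
        cohort = [
            pm.SubjectRecord(str(i), {}, ((1, 0.0),), censoring_time=2.0)
            for i in range(10)
        ]
        counts = pm.count_transitions(cohort, space)
        assert (counts["n"] == 0).all()
        assert counts.attrs["ending_counts"][1] == 10

    def test_empty_cohort_is_error(self, space):
        with pytest.raises(ValueError, match="empty"):
            pm.count_transitions([], space)

    def test_conservation_on_random_cohort(self, space):
        """entries - exits = subjects ending there, for every state."""
        cohort = pm.generate_cohort(pm.reference_config(), seed=3)
        counts = pm.count_transitions(cohort, space)
        ending = counts.attrs["ending_counts"]
        for s in space.state_ids:
            entries = counts.loc[counts.to_state == s, "n"].sum() + (
                len(cohort) if s == 1 else 0
            )
            exits = counts.loc[counts.from_state == s, "n"].sum()
            assert entries - exits == ending[s]


def _cohort_with_counts(n, n12, n13, n14, n23, n24, n34):
    """Deterministic cohort realizing a given transition mix.

    Of the subjects entering overt PMF, n23 continue to AML and n24 to
    death; AML deaths n34 are drawn first from direct AML entries.
    """
    subjects = []
    i = 0

    def sid():
        nonlocal i
        i += 1
        return f"p{i}"

    aml_deaths = n34
    # direct to overt PMF, then onward
    onward23, onward24 = n23, n24
    for _ in range(n12):
        if onward23 > 0:
            onward23 -= 1
            if aml_deaths > n13:  # this AML entry also dies
                aml_deaths -= 1
                traj = ((1, 0.0), (2, 1.0), (3, 2.0), (4, 3.0))
                subjects.append(pm.SubjectRecord(sid(), {}, traj))
            else:
                traj = ((1, 0.0), (2, 1.0), (3, 2.0))
                subjects.append(pm.SubjectRecord(sid(), {}, traj, 4.0))
        elif onward24 > 0:
            onward24 -= 1
            subjects.append(
                pm.SubjectRecord(sid(), {}, ((1, 0.0), (2, 1.0), (4, 2.0)))
            )
        else:
            subjects.append(
                pm.SubjectRecord(sid(), {}, ((1, 0.0), (2, 1.0)), 5.0)
            )
    for _ in range(n13):
        if aml_deaths > 0:
            aml_deaths -= 1
            subjects.append(
                pm.SubjectRecord(sid(), {}, ((1, 0.0), (3, 1.0), (4, 2.0)))
            )
        else:
            subjects.append(pm.SubjectRecord(sid(), {}, ((1, 0.0), (3, 1.0)), 5.0))
    for _ in range(n14):
        subjects.append(pm.SubjectRecord(sid(), {}, ((1, 0.0), (4, 1.0))))
    while len(subjects) < n:
        subjects.append(pm.SubjectRecord(sid(), {}, ((1, 0.0),), 5.0))
    return subjects


class TestTrajectoryProperties:
    """Randomized trajectories: long format is lossless and consistent."""

    @staticmethod
    def _strategy():
        from hypothesis import strategies as st

        space = pm.default_state_space()

        @st.composite
        def subject(draw, i=st.integers()):
            path = [1]
            while not space.is_absorbing(path[-1]) and draw(st.booleans()):
                nexts = [b for a, b in space.transitions if a == path[-1]]
                path.append(draw(st.sampled_from(nexts)))
            gaps = draw(
                st.lists(
                    st.floats(0.1, 10.0, allow_nan=False),
                    min_size=len(path), max_size=len(path),
                )
            )
            times = np.cumsum([0.0] + gaps[1:]).tolist()
            censor = None
            if not space.is_absorbing(path[-1]):
                censor = times[-1] + gaps[0]
            return pm.SubjectRecord(
                draw(st.uuids()).hex,
                {},
                tuple(zip(path, times)),
                censor,
            )

        return subject()

    def test_round_trip_and_count_consistency(self):
        from hypothesis import given, settings, strategies as st

        space = pm.default_state_space()

        @given(st.lists(self._strategy(), min_size=1, max_size=20,
                        unique_by=lambda s: s.subject_id))
        @settings(max_examples=50, derandomize=True, deadline=None)
        def check(subjects):
            rows = pm.build_long_format(subjects, space)
            rebuilt = pm.subjects_from_long_format(rows, space)
            key = lambda r: (r.subject_id, r.transition, r.t_start)
            assert sorted(pm.build_long_format(rebuilt, space), key=key) == \
                sorted(rows, key=key)
            counts = pm.count_transitions(subjects, space)
            by_status = pm.long_format_to_frame(rows).groupby(
                "transition")["status"].sum() if rows else {}
            for k in range(1, 7):
                expected = counts.loc[counts.transition == k, "n"].item()
                got = by_status.get(k, 0) if rows else 0
                assert got == expected

        check()


class TestCsvYaml:
    def test_subject_csv_round_trip(self, space, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        pm.write_subject_csv(small_cohort, path)
        back = pm.read_subject_csv(path)
        assert [s.trajectory for s in back] == [s.trajectory for s in small_cohort]
        assert [s.censoring_time for s in back] == [
            s.censoring_time for s in small_cohort
        ]
        assert back[0].covariates == small_cohort[0].covariates

    def test_state_space_yaml_round_trip(self, space, tmp_path):
        path = tmp_path / "space.yaml"
        pm.write_state_space_yaml(space, path)
        assert pm.read_state_space_yaml(path) == space

    def test_long_format_frame_round_trip(self, space, small_cohort):
        rows = pm.build_long_format(small_cohort, space)
        frame = pm.long_format_to_frame(rows)
        assert pm.frame_to_long_format(frame) == rows
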
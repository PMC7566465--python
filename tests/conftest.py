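import numpy as np
import pytest

import pmfstate as pm


@pytest.fixture
def space():
    return pm.default_state_space()


@pytest.fixture
def two_state_space():
    return pm.StateSpace(
        state_ids=(1, 2),
        state_labels=("alive", "dead"),
        absorbing=(False, True),
        transitions=((1, 2),),
    )


def make_model_set(space, shapes, scales, coefs=None):
    """ModelSet with given true parameters (no fitted covariance)."""
    fits = {}
    for k in range(1, space.n_transitions + 1):
        fits[k] = pm.WeibullPHFit(
            transition=k,
            shape=float(shapes[k - 1]),
            scale=float(scales[k - 1]),
            coefficients=dict(coefs[k - 1]) if coefs else {},
            covariance=None,
            log_likelihood=np.nan,
            n_events=0,
            n_rows=0,
        )
    return pm.ModelSet(space=space, fits=fits)


@pytest.fixture
def exp_model(space):
    """All-exponential 4-state model (constant intensities)."""
    return make_model_set(space, [1.0] * 6, [0.05, 0.02, 0.03, 0.1, 0.08, 0.3])


@pytest.fixture
def weibull_model(space):
    """Mixed-shape Weibull 4-state model."""
    return make_model_set(
        space, [1.0, 1.0, 1.3, 0.6, 1.2, 1.4], [0.05, 0.02, 0.03, 0.1, 0.08, 0.3]
    )


@pytest.fixture
def small_cohort(space):
    """Hand-written 4-subject cohort exercising every sojourn type."""
    return [
        pm.SubjectRecord("a", {"z": 1.0}, ((1, 0.0), (2, 3.0), (4, 7.0))),
        pm.SubjectRecord("b", {"z": 0.0}, ((1, 0.0),), censoring_time=5.0),
        pm.SubjectRecord("c", {"z": 1.0}, ((1, 0.0), (3, 2.0), (4, 4.0))),
        pm.SubjectRecord("d", {"z": 0.0}, ((1, 0.0), (2, 1.0), (3, 6.0)),
                         censoring_time=9.0),
    ]
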
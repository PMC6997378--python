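import numpy as np
import pytest

from voxnorm.core_io import Group, Modality, ParameterMapStack, Session
from voxnorm.synthetic import SyntheticCohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but full-featured cohort shared by read-only tests."""
    spec = SyntheticCohortSpec(shape=(8, 8, 8), n_controls=12, n_concussed=3,
                               seed=42)
    return generate_cohort(spec)


def make_stack(values, modality=Modality.FA, session=Session.BASELINE,
               mask=None, subject_ids=None):
    """Wrap an (S, V) array as a stack over a flat 1 x 1 x V grid."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones((1, 1, values.shape[1]), dtype=bool)
    if subject_ids is None:
        subject_ids = [f"s{i:02d}" for i in range(values.shape[0])]
    return ParameterMapStack(modality=modality, session=session,
                             subject_ids=subject_ids, values=values,
                             mask=mask, affine=np.eye(4))
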
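import numpy as np
import pytest

from perfmismatch.phantom import (
    AcquisitionParams,
    SubjectSpec,
    _build_geometry,
    _truth_from_levels,
    gamma_variate_aif,
    synthesize_subject,
)


@pytest.fixture(scope="session")
def params():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def aif(params):
    return gamma_variate_aif(params)


@pytest.fixture(scope="session")
def subject_spec():
    return SubjectSpec()


@pytest.fixture(scope="session")
def baseline_truth(subject_spec):
    """Noiseless ground truth of the default phantom geometry."""
    return _truth_from_levels(subject_spec, subject_spec.levels, _build_geometry(subject_spec))


@pytest.fixture(scope="session")
def subject(subject_spec):
    """One noiseless treated-arm phantom subject (fixed seed)."""
    return synthesize_subject(subject_spec, seed=42)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
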
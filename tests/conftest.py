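import numpy as np
import pytest

from restalpha import Recording, simulate_subject, standard_montage
from restalpha.synth import SubjectSpec, default_alpha_topography


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def default_amp(montage):
    return default_alpha_topography(montage)


@pytest.fixture(scope="session")
def subject_spec(default_amp):
    return SubjectSpec(subject_id="V1", group="case", iaf_true=10.3,
                       alpha_amp=default_amp)


@pytest.fixture(scope="session")
def subject_rec(subject_spec, montage):
    """A default synthetic subject, shared across test modules."""
    return simulate_subject(subject_spec, montage, duration=180.0, fs=250.0,
                            seed=7)


def make_recording(channels, fs, data, subject_id="x", **kw):
    return Recording(subject_id=subject_id, channels=tuple(channels), fs=fs,
                     data=np.asarray(data, dtype=float), **kw)
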
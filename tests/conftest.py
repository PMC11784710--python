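import numpy as np
import pytest

from cbrisk.cohort import Cohort, Group, StimulusProtocol, SubjectRecord
from cbrisk.fixtures import reference_cohort
from cbrisk.simulate import GeneratorParams, generate_cohort


def make_subject(
    subject_id="s1",
    group=Group.CONTROL,
    T=80,
    hr_level=70.0,
    rr_level=17.0,
    glucose_level=None,
    rng=None,
):
    """A plain valid subject with optional mild jitter."""
    hr = np.full(T, hr_level)
    rr = np.full(T, rr_level)
    if rng is not None:
        hr = hr + rng.normal(0, 1.0, T)
        rr = rr + rng.normal(0, 0.4, T)
    glucose = None if glucose_level is None else np.full(T, float(glucose_level))
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        minutes=np.arange(1, T + 1),
        hr=hr,
        rr=rr,
        glucose=glucose,
    )


@pytest.fixture
def small_cohort():
    rng = np.random.default_rng(0)
    return Cohort(
        subjects=(
            make_subject("a", Group.PREDIABETES, glucose_level=110, rng=rng),
            make_subject("b", Group.CONTROL, rng=rng),
        ),
        protocol=StimulusProtocol(),
    )


@pytest.fixture(scope="session")
def reference():
    """The engineered training cohort and its expected association table."""
    return reference_cohort()


@pytest.fixture(scope="session")
def study_cohort():
    """Default synthetic cohort at the study's group sizes (8 vs 25)."""
    return generate_cohort(GeneratorParams(seed=42))
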
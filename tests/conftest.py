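import numpy as np
import pytest

import physioad as pa
from physioad.session import SessionConfig


@pytest.fixture(scope="session")
def compact_timeline():
    return pa.generate_timeline(SessionConfig.compact(), seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """Two subjects, autonomic signals only, strong class effects."""
    return pa.generate_cohort(
        2,
        pa.ClassEffects.strong(),
        seed=3,
        session_config=SessionConfig.compact(),
        drop=pa.DropModel.none(),
        modalities=("ecg", "gsr", "rsp"),
    )


@pytest.fixture(scope="session")
def eeg_subject():
    """One full subject including EEG (compact session); expensive, shared."""
    cohort = pa.generate_cohort(
        1,
        pa.ClassEffects.default(),
        seed=5,
        session_config=SessionConfig.compact(),
        drop=pa.DropModel.none(),
    )
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
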
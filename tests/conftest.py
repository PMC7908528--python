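import numpy as np
import pytest

from fvtp.model import FVProfile
from fvtp.synthetic import SubjectTruth


@pytest.fixture
def subject_truth():
    """One nominal simulated subject with fixed profiles."""
    return SubjectTruth(
        subject_id="s001",
        body_mass=67.4,
        lever_arm=0.28,
        crank_length=0.17,
        ability=0.0,
        profiles={
            "jump": FVProfile(F0=2300.0, V0=3.0),
            "cycling": FVProfile(F0=900.0, V0=2.2),
            "isokinetic": FVProfile(F0=700.0, V0=2.0),
        },
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
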
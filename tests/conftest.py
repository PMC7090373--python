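import pytest

from ocor.core import CorrectionParams
from ocor.session import COSample, OcorSession, Subject


@pytest.fixture
def params():
    return CorrectionParams()


@pytest.fixture
def session():
    """A hand-built session: baseline 1.62%, plateau ~6.9% declining slowly."""
    return OcorSession(
        subject_id="s1",
        dose_co_ml=50.0,
        baseline=[COSample(-1.0, [1.6, 1.64])],
        timed=[
            COSample(6.0, [6.9, 6.9]),
            COSample(8.0, [6.88, 6.92]),
            COSample(10.0, [6.85]),
            COSample(12.0, [6.83]),
            COSample(15.0, [6.80]),
            COSample(20.0, [6.75]),
        ],
    )


@pytest.fixture
def subject():
    return Subject(
        id="s1",
        sex="male",
        weight_kg=80.0,
        height_cm=176.0,
        hb_g_l=113.0,
        hct=0.34,
        performance_status=1,
    )
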
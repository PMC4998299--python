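import numpy as np
import pytest

from trendim import ChangeObservation, PairedSeries


def oracle_classify(rm1, tm1, rm2, tm2, rc):
    """Independent classifier: the two printed-line inequalities tested
    directly, gray-zone membership by dense sampling of the precision
    interval.  Deliberately shares no code with the package."""
    lo1, hi1 = rm1 - abs(rm1) * rc, rm1 + abs(rm1) * rc
    lo2, hi2 = rm2 - abs(rm2) * rc, rm2 + abs(rm2) * rc
    if not (hi1 < lo2 or hi2 < lo1):
        return "uninterpretable"
    x_upper = tm2 * (1 + rc) + (1 + rc) * (rm1 - tm1)
    x_lower = tm2 * (1 - rc) + (1 + rc) * (rm1 - tm1)
    lo, hi = min(x_upper, x_lower), max(x_upper, x_lower)
    if lo <= rm2 <= hi:
        return "interchangeable"
    samples = np.linspace(rm2 - abs(rm2) * rc, rm2 + abs(rm2) * rc, 2001)
    if np.any((samples >= lo) & (samples <= hi)):
        return "gray_zone"
    return "noninterchangeable"


@pytest.fixture
def identity_series():
    """Positive series where the test method copies the reference exactly."""
    values = (2.0, 2.6, 3.4, 4.5, 6.0, 4.0, 3.0)
    return PairedSeries(
        subject_id="S1",
        device="copy",
        values=tuple((v, v, i) for i, v in enumerate(values)),
    )


@pytest.fixture
def random_quadruples():
    """Positive random (rm1, tm1, rm2, tm2) quadruples for oracle checks."""
    rng = np.random.default_rng(20160624)
    vals = rng.uniform(0.2, 8.0, size=(12_000, 4))
    return [ChangeObservation(*row) for row in vals]
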
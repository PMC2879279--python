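import math

import pytest

from ampliquant import builtin_nb_panels
from ampliquant.dosage import DosageQuotient


@pytest.fixture(scope="session")
def panels():
    return builtin_nb_panels()


@pytest.fixture(scope="session")
def kit3(panels):
    return panels["NB-MAQ3"]


def dqs(values, sample_id="S", prefix="amp"):
    """Build a position-ordered DQ list from plain floats; None = no data."""
    out = []
    for i, v in enumerate(values):
        if v is None:
            out.append(DosageQuotient.no_data(sample_id, f"{prefix}-{i:02d}"))
        else:
            out.append(DosageQuotient(sample_id, f"{prefix}-{i:02d}", float(v), 0.0, 1))
    return out


@pytest.fixture
def make_dqs():
    return dqs
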
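import numpy as np
import pytest

from npcquant import triage


@pytest.fixture(scope="session")
def reference_records():
    """The packaged worked-example table (10 candidates + 2 reference sterols)."""
    return triage.load_reference_table()


@pytest.fixture(scope="session")
def candidate_records(reference_records):
    return [r for r in reference_records if not r.is_reference]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
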
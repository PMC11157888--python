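import numpy as np
import pytest

from fragmetrics import StateSeries, extract_bouts

# the worked 15-epoch example: bouts r=(2,1,2,2), a=(3,1,3,1), ends in rest
WORKED_SEQUENCE = ["a", "a", "a", "r", "r", "a", "r", "a", "a", "a",
                   "r", "r", "a", "r", "r"]


@pytest.fixture
def worked_states() -> StateSeries:
    return StateSeries.from_symbols(WORKED_SEQUENCE)


@pytest.fixture
def worked_bouts(worked_states):
    return extract_bouts(worked_states)


@pytest.fixture
def rng():
    return np.random.default_rng(20240607)
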
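import numpy as np
import pytest

from lingcontact.synthetic import AdmixtureEventSpec


@pytest.fixture
def planted_event():
    return AdmixtureEventSpec(
        target_pop="POP000",
        source1_pop="POP001",
        source2_pop="POP002",
        alpha=0.3,
        k_support=frozenset(range(12, 17)),
        families={"POP000": "FAM_X", "POP001": "FAM_X", "POP002": "FAM_Y"},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
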
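import numpy as np
import pytest

from dualstore import detailed_codec as dc
from dualstore.library import build_demo_library, demo_payload


@pytest.fixture(scope="session")
def primer_pair():
    return dc.design_primer_pairs(1, seed=7)[0]


@pytest.fixture(scope="session")
def fixture_payload():
    """The 1,999-byte demonstration payload (404 B text + 1,595 B binary)."""
    return demo_payload(0)


@pytest.fixture(scope="session")
def fixture_strands(fixture_payload, primer_pair):
    return dc.encode_file(fixture_payload, file_id=1, primer_pair=primer_pair, seed=3)


@pytest.fixture(scope="session")
def demo_library():
    return build_demo_library(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
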
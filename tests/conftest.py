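import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from adfba import fixtures


@pytest.fixture
def chain_fixture():
    """Minimal chain: uptake -10..0, conversion, objective export."""
    return fixtures.make_toy_model("minimal-chain")


@pytest.fixture
def diauxic_fixture():
    return fixtures.make_toy_model("diauxic")


@pytest.fixture
def secretion_fixture():
    return fixtures.make_toy_model("secretion-conflict")
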
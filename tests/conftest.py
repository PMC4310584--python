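import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from domscan.datamodel import PairConfig
from domscan.synth import fixture_panel


@pytest.fixture(scope="session")
def fixture_trio():
    """The deterministic 24-individual, 40-locus test panel."""
    return fixture_panel()


@pytest.fixture()
def default_cfg():
    return PairConfig()
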
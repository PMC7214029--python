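import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from molpage import fixtures as fx  # noqa: E402


@pytest.fixture(scope="session")
def helix12():
    return fx.make_helix(12)


@pytest.fixture(scope="session")
def dimer():
    return fx.make_dimer()


@pytest.fixture(scope="session")
def clash_pair():
    return fx.make_clash_pair()


@pytest.fixture(scope="session")
def pocket():
    return fx.make_pocket()


@pytest.fixture()
def manifest():
    return fx.make_session_manifest()


@pytest.fixture(scope="session")
def all_fixture_structures():
    return [fx.make_helix(12), fx.make_helix(2), fx.make_dimer(),
            fx.make_clash_pair(), fx.make_pocket()]
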
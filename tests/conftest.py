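import pytest

from vsitetools.ffstore import read_forcefield
from vsitetools.fixtures import (make_ethanol_top, make_min_forcefield,
                                 make_novel_type_top, make_scan_molecule,
                                 write_fixture_set)


@pytest.fixture(scope="session")
def ff_dir(tmp_path_factory):
    return make_min_forcefield(tmp_path_factory.mktemp("ff") / "testff.ff")


@pytest.fixture(scope="session")
def store(ff_dir):
    return read_forcefield(ff_dir)


@pytest.fixture()
def ethanol():
    return make_ethanol_top()


@pytest.fixture()
def novel():
    return make_novel_type_top()


@pytest.fixture(scope="session")
def scan():
    return make_scan_molecule()


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory):
    return write_fixture_set(tmp_path_factory.mktemp("fixtures"))
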
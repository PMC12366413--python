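from __future__ import annotations

import pytest

from taxonames import build_indexes, load_taxdump, reference_fixture, write_fixture
from taxonames.fixtures import REF


@pytest.fixture(scope="session")
def ref_spec():
    return reference_fixture()


@pytest.fixture(scope="session")
def ref_dir(tmp_path_factory, ref_spec):
    directory = tmp_path_factory.mktemp("taxdump")
    write_fixture(ref_spec, directory)
    return directory


@pytest.fixture(scope="session")
def store(ref_dir):
    return build_indexes(load_taxdump(ref_dir))


@pytest.fixture(scope="session")
def ref_ids():
    return REF
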
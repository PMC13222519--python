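import pytest

from ncres.ccd import load_component_library
from ncres.fixtures import mini_component_library, toy_molecule_set
from ncres.similarity import library_fingerprints


@pytest.fixture(scope="session")
def library_sdf(tmp_path_factory):
    path = tmp_path_factory.mktemp("lib") / "mini_ccd_synthetic.sdf"
    return mini_component_library(path)


@pytest.fixture(scope="session")
def library(library_sdf):
    return load_component_library(library_sdf)


@pytest.fixture(scope="session")
def library_fps(library):
    return library_fingerprints(library)


@pytest.fixture(scope="session")
def toy_panel():
    return toy_molecule_set()
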
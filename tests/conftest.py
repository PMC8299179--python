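import pytest

from scaffnet import fixtures, nine_representations, standardize


@pytest.fixture(scope="session")
def examples():
    return fixtures.worked_examples()


@pytest.fixture(scope="session")
def sample_compounds():
    return fixtures.load_cox2_sample()


@pytest.fixture(scope="session")
def sample_rep_sets(sample_compounds):
    return [nine_representations(c) for c in sample_compounds]


@pytest.fixture(scope="session")
def small_library():
    return fixtures.synthetic_library(n_scaffolds=6, n_per_scaffold=8, seed=7)


@pytest.fixture(scope="session")
def library_rep_sets(small_library):
    return [nine_representations(c) for c in small_library.compounds]


def compound(smiles, cid=""):
    return standardize(smiles, cid or smiles)
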
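import pytest

from peptergent import synthetic as syn


@pytest.fixture(scope="session")
def sheet_2x10():
    return syn.make_sheet(2, 10)


@pytest.fixture(scope="session")
def barrel_8x10():
    return syn.make_barrel(8, 10)


@pytest.fixture(scope="session")
def protein():
    return syn.make_cylinder_protein()


@pytest.fixture(scope="session")
def shell(protein):
    return syn.make_detergent_shell(protein, n_detergent=24, seed=11, n_patches=3)
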
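import pytest

from aggnuc import datasets


@pytest.fixture(scope="session")
def dna_peak_table():
    return datasets.load_dna_peak_table()


@pytest.fixture(scope="session")
def rna_diff_table():
    return datasets.load_rna_diff_table()


@pytest.fixture(scope="session")
def viral_screen_table():
    return datasets.load_viral_screen_table()


@pytest.fixture(scope="session")
def viral_library_sizes():
    return datasets.load_viral_library_sizes()
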
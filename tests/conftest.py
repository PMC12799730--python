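import pytest

from twocodon import load_reference_params


@pytest.fixture(scope="session")
def baseline():
    """Symmetric reference set: 1250/1250 tRNAs, calibrated constants."""
    return load_reference_params("baseline")


@pytest.fixture(scope="session")
def ratio07():
    return load_reference_params("ratio07")


@pytest.fixture(scope="session")
def ratio09():
    return load_reference_params("ratio09")
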
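import numpy as np
import pytest

from eldermatch.synthetic_province import ProvinceConfig, generate_province


@pytest.fixture(scope="session")
def province():
    """One default synthetic province shared across read-only tests."""
    return generate_province(ProvinceConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
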
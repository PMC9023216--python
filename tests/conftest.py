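import numpy as np
import pytest

from otoseg.synthetic_phantom import generate_case, toy_config


@pytest.fixture(scope="session")
def toy_case():
    """One deterministic small high-contrast phantom."""
    return generate_case(toy_config(0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
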
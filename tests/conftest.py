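import numpy as np
import pytest

from ccswitch.peptides import RegisteredPeptide


@pytest.fixture
def toy_heptad():
    """One ideal acidic heptad starting at register a."""
    return RegisteredPeptide(name="toy", sequence="IAALEQE", register_offset=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
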
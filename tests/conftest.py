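import numpy as np
import pytest

from mepsurvey import FamilySpec, make_family


@pytest.fixture(scope="session")
def tiny_family():
    """Small synthetic family reused across tests (60 aa, 12 members, 10%)."""
    return make_family(
        FamilySpec("Dxs", ancestor_length=60, n_members=12, divergence=0.1, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
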
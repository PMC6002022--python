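import numpy as np
import pytest
from hypothesis import settings

import odorlex as ox

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def worked():
    """Tiny deterministic world with hand-checkable intermediates."""
    cat, spectra, emb, truth = ox.generate_worked_fixture()
    return {"cat": cat, "spectra": spectra, "emb": emb, "truth": truth}


@pytest.fixture(scope="session")
def small_world():
    """Small exclusive-mode synthetic world shared across tests."""
    cfg = ox.SyntheticConfig(n_chemicals=120, seed=7)
    cat, spectra, emb, truth = ox.generate_world(cfg)
    return {"cfg": cfg, "cat": cat, "spectra": spectra, "emb": emb, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
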
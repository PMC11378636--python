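import numpy as np
import pytest

from transcell.synthetic import SyntheticConfig, generate_domains


@pytest.fixture(scope="session")
def small_study():
    """A fast paired-domain study shared across tests (50 genes, 5 shifted)."""
    return generate_domains(
        SyntheticConfig(
            n_source=300,
            n_target=80,
            n_genes=50,
            n_shifted_genes=5,
            n_continuous_features=6,
            n_binary_features=3,
            seed=7,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
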
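import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully featured synthetic clade (shared across tests)."""
    from polyload.simulate import SimulationParams, simulate_clade

    params = SimulationParams(
        n_gene_pairs=80,
        cds_length_bp=300,
        he_rate=0.25,
        collapse_rate=0.004,
        conversion_rate=0.02,
        depth_dispersion=0.0,
        masking_m=0.3,
        seed=11,
    )
    return simulate_clade(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
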
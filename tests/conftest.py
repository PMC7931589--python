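import numpy as np
import pytest

from mirgrn.simulate import SimulationParams


@pytest.fixture
def small_params():
    """Three-group world, small enough for per-test simulation."""
    return SimulationParams(
        seed=7,
        groups=(("fishes", 3), ("amphibians", 2), ("mammals", 4)),
        n_conserved_families=8,
        n_specific_per_group=2,
        n_genes=60,
        ppi_n_edges=80,
        subst_rate=0.0,
        dropout_prob=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
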
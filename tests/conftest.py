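import numpy as np
import pytest

from codonsfs import (
    RecombMapSpec,
    SimulationParams,
    load_reference_scores,
    simulate_sites,
)


@pytest.fixture(scope="session")
def ref_table():
    return load_reference_scores()


@pytest.fixture(scope="session")
def small_dataset():
    """A compact selected dataset with ASM, masks, and a recombination map."""
    params = SimulationParams(
        seed=20_001,
        n_genes=30,
        gene_length_codons=250,
        gamma=1.0,
        recomb=RecombMapSpec(n_segments=12),
        mask_fail_rate=0.002,
    )
    return simulate_sites(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
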
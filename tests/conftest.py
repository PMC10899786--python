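import numpy as np
import pytest

from xrdeam import KmerIndex, SimConfig, generate_fragments, generate_genome


@pytest.fixture(scope="session")
def hand_genome():
    """A tiny hand-constructed genome for coordinate/strand-convention tests."""
    #           0         1         2         3         4         5
    #           0123456789012345678901234567890123456789012345678901234
    seq = "ACGTACCATGGTCTGATTACAGGCATTCGATCCAGTGGACCTTGAACGTTAGCCA"
    return {"toy": seq}


@pytest.fixture(scope="session")
def sim_bundle():
    """A moderate mixed-lesion simulation shared by read-level tests."""
    cfg = SimConfig(genome_length=60_000, n_fragments=8_000,
                    p_deaminate=0.4, p_tandem=0.3, seed=7)
    genome = generate_genome(cfg)
    reads, truth = generate_fragments(genome, cfg)
    return cfg, genome, reads, truth


@pytest.fixture(scope="session")
def sim_index(sim_bundle):
    _, genome, _, _ = sim_bundle
    return KmerIndex(genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
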
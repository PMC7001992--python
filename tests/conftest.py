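import pytest

from xlinksob.simulate import (GroundTruth, SimConfig, generate_reference,
                               simulate_iclip_reads)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, n_genes=3, corruption_prob=0.0)


@pytest.fixture(scope="session")
def small_sim(small_config):
    """Reference + reads for a 3-gene error-free simulation."""
    contigs, genes, truth = generate_reference(small_config)
    reads, truth = simulate_iclip_reads(small_config, contigs, genes, truth)
    return small_config, contigs, genes, truth, reads
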
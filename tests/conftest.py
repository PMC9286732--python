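import pytest

from alleletx.sim import SimConfig, generate_genome_pair, plant_truth, simulate_read_ends


@pytest.fixture(scope="session")
def mixed_sim():
    """One moderate simulation with every effect class, shared by tests that
    only need plausibly structured data."""
    cfg = SimConfig(seed=11, n_loci=30)
    genome = generate_genome_pair(cfg)
    truth = plant_truth(genome, cfg)
    reads = simulate_read_ends(truth)
    return cfg, genome, truth, reads
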
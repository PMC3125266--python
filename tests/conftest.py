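import numpy as np
import pytest

from titmine.simulate import (
    SimulationConfig,
    generate_contigs,
    generate_expression,
    generate_genome,
    generate_genome_sequences,
    generate_snp_candidates,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def dataset(default_config):
    """One full synthetic study at the default settings, shared read-only."""
    rng = default_config.rng()
    genome = generate_genome(default_config, rng)
    sequences = generate_genome_sequences(genome, rng)
    contigs, alignments, truth = generate_contigs(
        genome, default_config, rng, sequences)
    matrix, expr_truth = generate_expression(contigs, default_config, rng)
    candidates = generate_snp_candidates(contigs, default_config, rng)
    return {
        "config": default_config,
        "genome": genome,
        "sequences": sequences,
        "contigs": contigs,
        "alignments": alignments,
        "truth": truth,
        "matrix": matrix,
        "expr_truth": expr_truth,
        "candidates": candidates,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
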
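import numpy as np
import pytest

from tradistat import (
    GeneRecord,
    GenomeAnnotation,
    InsertionProfile,
    NullModelConfig,
    default_preset,
    generate_annotation,
    simulate_gene_null,
    simulate_library,
)

@pytest.fixture
def tiny_profile():
    """5-base genome with evidence at bases 1 (fwd) and 3 (rev)."""
    fwd = np.array([0, 2, 0, 0, 0])
    rev = np.array([0, 0, 0, 1, 0])
    return InsertionProfile(fwd, rev)


@pytest.fixture
def tiny_annotation():
    genes = [GeneRecord("gA", 0, 5)]
    return GenomeAnnotation(genome_length=5, genes=genes)


@pytest.fixture(scope="session")
def default_synth():
    """One desk-scale synthetic library with planted truth (fixed seed)."""
    cfg = default_preset(seed=11)
    annotation, truth = generate_annotation(cfg)
    profile = simulate_library(annotation, truth, cfg)
    return cfg, annotation, truth, profile


@pytest.fixture(scope="session")
def gene_null_rho195():
    """Simulated g=1000 longest-run table at the full-scale density."""
    cfg = NullModelConfig(
        G=4_631_469, N=901_383, g=1000, n_gene_instances=100_000, seed=5
    )
    return simulate_gene_null(cfg)
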
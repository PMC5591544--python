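import numpy as np
import pytest

from genoweave import (
    GeneModel,
    GenomeSequence,
    SimulationConfig,
    generate_genome,
    plant_gene_models,
)


def make_model(mid="m1", scaffold="s1", strand="+", segments=((0, 300),),
               source="testset", origin=None):
    return GeneModel(id=mid, source=source, scaffold=scaffold, strand=strand,
                     segments=tuple(segments), origin=origin)


def span_model(mid, start, end, scaffold="s1", strand="+"):
    """Single-exon model occupying [start, end)."""
    return make_model(mid, scaffold=scaffold, strand=strand,
                      segments=((start, end),))


@pytest.fixture(scope="session")
def planted_world():
    """A small simulated genome with planted genes, shared across tests."""
    config = SimulationConfig(seed=11, n_scaffolds=4, scaffold_length=60_000,
                              n_loci=60)
    genome = generate_genome(config)
    genome, truth = plant_gene_models(config, genome)
    return config, {g.id: g for g in genome}, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_genome():
    return {"s1": GenomeSequence("s1", "ATGAAATAAACGTACGTACGT")}
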
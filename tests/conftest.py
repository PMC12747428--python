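import numpy as np
import pytest

import phyloshot as ps
from phyloshot.cooccurrence import CoocTrainConfig, NoiseConfig, train_cooccurrence
from phyloshot.data_io import reference_index
from phyloshot.dna_encoder import DnaTrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def three_leaf_tree():
    return ps.PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_world():
    """A 64-species world with full reference coverage, for pipeline tests."""
    return ps.make_world(n_species=64, gap_fraction=0.0, segregation=0.9,
                         seed=7, n_regions=4, sites_per_region=10, richness=8)


@pytest.fixture(scope="session")
def small_models(small_world):
    """Embeddings, DNA encoder and community co-occurrence model trained on
    the 64-species world (dim 8, narrow encoder; trains in a few seconds)."""
    world = small_world
    emb, _ = ps.train_species_embeddings(
        world.tree, ps.EmbedConfig(embed_dim=8, epochs=150, seed=7))
    dna, dna_trace = ps.train_dna_encoder(
        world.records, emb,
        DnaTrainConfig(channels=32, hidden_dim=256, max_len=96, epochs=30, seed=7))
    cooc, _ = train_cooccurrence(
        world.sites, emb, dna, reference_index(world.records),
        CoocTrainConfig(rank=32, epochs=5, seed=7), NoiseConfig(sigma=0.1, seed=7))
    return {"embeddings": emb, "dna": dna, "cooc": cooc, "dna_trace": dna_trace}
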
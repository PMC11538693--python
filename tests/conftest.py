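"""Shared fixtures: small deterministic datasets and helper builders."""

import numpy as np
import pandas as pd
import pytest

import microhgt as mg


@pytest.fixture(scope="session")
def tiny_abundance():
    """2 species x 2 samples, columns already normalized."""
    return mg.AbundanceMatrix(["s1", "s2"], ["p1", "p2"], [[0.5, 0.0], [0.5, 1.0]])


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial synthetic dataset for unit tests."""
    spec = mg.SyntheticSpec(M=40, N=24, C=2, community_size=6, genus_size=4, seed=7)
    return mg.generate(spec)


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    return mg.preprocess_abundance(small_dataset.abundance)


@pytest.fixture(scope="session")
def small_graph(small_dataset, small_preprocessed):
    A = small_preprocessed
    D1 = mg.metabolic_relations(small_dataset.compound_table, A.species_ids)
    D2 = mg.phylogenetic_relations(small_dataset.taxonomy, A.species_ids)
    return mg.build_graph(A, D1, D2)


@pytest.fixture(scope="session")
def small_trained(small_dataset, small_preprocessed, small_graph):
    """A short full-stack training run shared across tests."""
    from microhgt.embeddings import AutoencoderConfig, train_sample_autoencoder, train_species_autoencoder
    from microhgt.hgt_core import TrainConfig, train_model

    A = small_preprocessed
    ae = AutoencoderConfig(hidden_dim=16, epochs=120, seed=3)
    se = train_species_autoencoder(A, ae)
    pe = train_sample_autoencoder(A, ae)
    cfg = TrainConfig(heads=4, layers=2, epochs=60, seed=3)
    res = train_model(small_graph, se, pe, small_dataset.labels, cfg)
    return res


def make_compound_table(records):
    return mg.CompoundInteractionTable(
        pd.DataFrame(records, columns=["species_id", "compound_id", "direction"])
    )


def make_taxonomy(records):
    return mg.TaxonomyTable(pd.DataFrame(records, columns=["species_id", "genus_id"]))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
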
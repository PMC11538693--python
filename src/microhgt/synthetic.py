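"""Synthetic datasets with planted class-associated microbial communities.

The generator emulates the structure of sparse compositional tissue
microbiome profiles: per-species log-normal baseline abundances (species
differ in typical abundance), independent zero-inflation (dropout), and
per-sample renormalisation to relative abundances.  Each class plants a
disjoint community of species whose abundance is multiplied by `effect` in
samples of that class.  Genera are assigned in consecutive blocks (so some
planted pairs share a genus), and a compound-interaction table links planted
within-class pairs through shared compounds (randomly competition, i.e. both
consume, or complementarity, i.e. producer/consumer).  Everything is drawn
from a single seeded generator, so a spec reproduces bit-identically.

Defaults match the study conditions used throughout the test-suite:
M=200 species, N=120 samples, C=3 classes, 15 planted species per class,
20-fold effect, 0.3 zero-inflation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import AbundanceMatrix, SampleLabels, encode_labels
from .errors import ConfigError
from .relations import CompoundInteractionTable, TaxonomyTable

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "null_attention", "write_dataset"]


@dataclass
class SyntheticSpec:
    M: int = 200
    N: int = 120
    C: int = 3
    community_size: int = 15
    effect: float = 20.0  # multiplicative elevation of planted species, >= 1 (1 = null)
    sparsity: float = 0.3  # zero-inflation probability, in [0, 1)
    genus_size: int = 5
    compound_link_prob: float = 0.5
    seed: int = 0
    baseline: str = "lognormal"  # "lognormal" | "dirichlet"
    overlap: int = 0  # species shared between consecutive class communities

    def __post_init__(self):
        if self.C * self.community_size - max(0, self.C - 1) * self.overlap > self.M:
            raise ConfigError("planted communities do not fit: C * community_size > M")
        if self.effect < 1:
            raise ConfigError("effect must be >= 1 (1 = no planted signal)")
        if not 0 <= self.sparsity < 1:
            raise ConfigError("sparsity must be in [0, 1)")
        if self.baseline not in ("lognormal", "dirichlet"):
            raise ConfigError(f"unknown baseline {self.baseline!r}")
        if not 0 <= self.overlap < self.community_size:
            raise ConfigError("overlap must be in [0, community_size)")


@dataclass
class SyntheticDataset:
    abundance: AbundanceMatrix
    labels: SampleLabels
    truth: dict  # class label -> set of planted species ids
    compound_table: CompoundInteractionTable
    taxonomy: TaxonomyTable
    spec: SyntheticSpec = field(repr=False, default=None)


def _community_indices(spec: SyntheticSpec) -> list[np.ndarray]:
    step = spec.community_size - spec.overlap
    return [np.arange(c * step, c * step + spec.community_size) for c in range(spec.C)]


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a full dataset (abundance, labels, truth, knowledge tables)."""
    rng = np.random.default_rng(spec.seed)
    M, N, C = spec.M, spec.N, spec.C
    species_ids = [f"sp_{i:04d}" for i in range(M)]
    sample_ids = [f"samp_{j:04d}" for j in range(N)]
    class_names = [f"class_{c}" for c in range(C)]
    # near-balanced class assignment in sample order
    cls = np.sort(np.arange(N) % C)
    communities = _community_indices(spec)

    # fold-change matrix: planted species elevated in their class's samples
    fold = np.ones((M, N))
    for c in range(C):
        cols = np.flatnonzero(cls == c)
        fold[np.ix_(communities[c], cols)] = spec.effect

    loc = rng.normal(0.0, 1.0, size=M)  # species-specific log-abundance location
    if spec.baseline == "lognormal":
        X = np.exp(rng.normal(loc[:, None], 1.0, size=(M, N))) * fold
    else:
        alpha = np.exp(loc)[:, None] * fold
        X = np.stack([rng.dirichlet(alpha[:, j] / alpha[:, j].sum() * M) for j in range(N)], axis=1)

    drop = rng.random(size=(M, N)) < spec.sparsity
    X = np.where(drop, 0.0, X)
    for j in np.flatnonzero(X.sum(axis=0) == 0):  # extremely unlikely; redraw the column mask
        X[:, j] = np.exp(rng.normal(loc, 1.0)) * fold[:, j]
    X = X / X.sum(axis=0)

    abundance = AbundanceMatrix(species_ids, sample_ids, X)
    labels = encode_labels(sample_ids, [class_names[c] for c in cls], class_names)
    truth = {class_names[c]: {species_ids[i] for i in communities[c]} for c in range(C)}

    # genus blocks of genus_size consecutive species
    taxonomy = TaxonomyTable(
        pd.DataFrame(
            {
                "species_id": species_ids,
                "genus_id": [f"genus_{i // spec.genus_size:03d}" for i in range(M)],
            }
        )
    )

    # compound-mediated links among planted within-class pairs
    records = []
    n_compounds = 0
    for c in range(C):
        comm = communities[c]
        for a in range(len(comm)):
            for b in range(a + 1, len(comm)):
                if rng.random() >= spec.compound_link_prob:
                    continue
                compound = f"cmpd_{n_compounds:05d}"
                n_compounds += 1
                i, j = comm[a], comm[b]
                if rng.random() < 0.5:  # competition: both consume
                    records.append((species_ids[i], compound, "consume"))
                    records.append((species_ids[j], compound, "consume"))
                else:  # complementarity: one produces what the other consumes
                    if rng.random() < 0.5:
                        i, j = j, i
                    records.append((species_ids[i], compound, "produce"))
                    records.append((species_ids[j], compound, "consume"))
    compound_table = CompoundInteractionTable(
        pd.DataFrame(records, columns=["species_id", "compound_id", "direction"])
    )
    return SyntheticDataset(abundance, labels, truth, compound_table, taxonomy, spec)


def null_attention(M: int, N: int, h: int, seed: int = 0) -> np.ndarray:
    """Exchangeable null attention: i.i.d. positive values per (head, species,
    sample), normalised so each (head, sample) column sums to 1."""
    rng = np.random.default_rng(seed)
    att = rng.exponential(1.0, size=(h, M, N))
    return att / att.sum(axis=1, keepdims=True)


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write the five TSVs plus a JSON truth file."""
    from pathlib import Path

    from .data_io import write_abundance, write_labels
    from .relations import metabolic_relations, phylogenetic_relations, write_relation_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_abundance(ds.abundance, out / "abundance.tsv")
    write_labels(ds.labels, out / "labels.tsv")
    ds.compound_table.records.to_csv(out / "compound_table.tsv", sep="\t", index=False)
    ds.taxonomy.records.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    D1 = metabolic_relations(ds.compound_table, ds.abundance.species_ids)
    D2 = phylogenetic_relations(ds.taxonomy, ds.abundance.species_ids)
    write_relation_matrix(D1, out / "metabolic_relations.tsv")
    write_relation_matrix(D2, out / "phylogenetic_relations.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump({c: sorted(s) for c, s in ds.truth.items()}, fh, indent=2)
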
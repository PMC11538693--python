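"""Species-sample heterogeneous graph assembly.

Two node types (species, sample) and three undirected edge types:

* abundance: species i -- sample j whenever a_ij > 0, weight a_ij;
* metabolic: species pairs from the metabolic relation matrix;
* phylogenetic: species pairs from the phylogenetic relation matrix.

For message passing each undirected edge is realised as two directed edges,
giving four meta-relations: (species, metabolic, species),
(species, phylogenetic, species), (species, abundance, sample) and
(sample, abundance, species).  Omitting one or both relation matrices yields
the corresponding ablation graph; with neither, the graph is bipartite.
Edge weights are stored for diagnostics but do not enter attention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import AbundanceMatrix
from .errors import ValidationError
from .relations import RelationMatrix

__all__ = ["HeteroGraph", "build_graph", "graph_summary"]

NODE_TYPES = ("species", "sample")
EDGE_TYPES = ("metabolic", "phylogenetic", "abundance")


@dataclass
class HeteroGraph:
    species_ids: list[str]
    sample_ids: list[str]
    # undirected species-species pairs, index arrays of shape (n_edges, 2), i < j
    edges_metabolic: np.ndarray
    edges_phylogenetic: np.ndarray
    # species-sample incidences: indices (nnz, 2) = (species_idx, sample_idx)
    edges_species_sample: np.ndarray
    weights_species_sample: np.ndarray  # a_ij for each incidence
    abundance: np.ndarray = field(repr=False)  # (M, N), kept for diagnostics

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def node_type(self, global_id: int) -> str:
        """tau(v): species occupy global ids 0..M-1, samples M..M+N-1."""
        return "species" if global_id < self.n_species else "sample"

    def meta_relations(self):
        """Directed edge groups (src_type, edge_type, tgt_type, src, tgt).

        src/tgt are local node indices within their type; groups with no
        edges are omitted.
        """
        out = []
        for name, pairs in (
            ("metabolic", self.edges_metabolic),
            ("phylogenetic", self.edges_phylogenetic),
        ):
            if len(pairs):
                src = np.concatenate([pairs[:, 0], pairs[:, 1]])
                tgt = np.concatenate([pairs[:, 1], pairs[:, 0]])
                out.append(("species", name, "species", src, tgt))
        if len(self.edges_species_sample):
            sp = self.edges_species_sample
            out.append(("species", "abundance", "sample", sp[:, 0], sp[:, 1]))
            out.append(("sample", "abundance", "species", sp[:, 1], sp[:, 0]))
        return out

    def to_networkx(self):
        """Convenience export to a networkx.Graph with typed nodes/edges."""
        import networkx as nx

        g = nx.Graph()
        for s in self.species_ids:
            g.add_node(("species", s), node_type="species")
        for p in self.sample_ids:
            g.add_node(("sample", p), node_type="sample")
        for i, j in self.edges_metabolic:
            g.add_edge(("species", self.species_ids[i]), ("species", self.species_ids[j]),
                       edge_type="metabolic")
        for i, j in self.edges_phylogenetic:
            g.add_edge(("species", self.species_ids[i]), ("species", self.species_ids[j]),
                       edge_type="phylogenetic")
        for (i, j), w in zip(self.edges_species_sample, self.weights_species_sample):
            g.add_edge(("species", self.species_ids[i]), ("sample", self.sample_ids[j]),
                       edge_type="abundance", weight=float(w))
        return g

    def export(self, out_dir) -> None:
        """Write edge-list TSVs per edge type plus a node table."""
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        nodes = pd.DataFrame(
            {
                "node_id": list(self.species_ids) + list(self.sample_ids),
                "type": ["species"] * self.n_species + ["sample"] * self.n_samples,
            }
        )
        nodes.to_csv(out_dir / "nodes.tsv", sep="\t", index=False)
        for name, pairs in (
            ("metabolic", self.edges_metabolic),
            ("phylogenetic", self.edges_phylogenetic),
        ):
            pd.DataFrame(
                {
                    "src": [self.species_ids[i] for i, _ in pairs],
                    "dst": [self.species_ids[j] for _, j in pairs],
                    "weight": 1.0,
                }
            ).to_csv(out_dir / f"edges_{name}.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "src": [self.species_ids[i] for i, _ in self.edges_species_sample],
                "dst": [self.sample_ids[j] for _, j in self.edges_species_sample],
                "weight": self.weights_species_sample,
            }
        ).to_csv(out_dir / "edges_abundance.tsv", sep="\t", index=False)


def build_graph(
    A: AbundanceMatrix,
    D1: RelationMatrix | None = None,
    D2: RelationMatrix | None = None,
) -> HeteroGraph:
    """Assemble the heterogeneous graph from abundance and relation matrices.

    `A` should already be preprocessed (columns summing to 1).  D1 (metabolic)
    and D2 (phylogenetic) must be aligned to A's species when present.
    """
    for D, name in ((D1, "metabolic"), (D2, "phylogenetic")):
        if D is not None and list(D.species_ids) != list(A.species_ids):
            raise ValidationError(f"{name} relation matrix species do not match abundance matrix")
    nz = np.argwhere(A.values > 0)
    empty = np.zeros((0, 2), dtype=np.intp)
    return HeteroGraph(
        species_ids=list(A.species_ids),
        sample_ids=list(A.sample_ids),
        edges_metabolic=D1.pairs() if D1 is not None else empty,
        edges_phylogenetic=D2.pairs() if D2 is not None else empty,
        edges_species_sample=nz,
        weights_species_sample=A.values[nz[:, 0], nz[:, 1]],
        abundance=A.values,
    )


def graph_summary(G: HeteroGraph) -> dict:
    """Node/edge counts, species-sample density and isolated-node count."""
    M, N = G.n_species, G.n_samples
    deg = np.zeros(M + N, dtype=np.int64)
    for pairs in (G.edges_metabolic, G.edges_phylogenetic):
        for col in (0, 1):
            np.add.at(deg, pairs[:, col], 1)
    if len(G.edges_species_sample):
        np.add.at(deg, G.edges_species_sample[:, 0], 1)
        np.add.at(deg, G.edges_species_sample[:, 1] + M, 1)
    return {
        "species": M,
        "samples": N,
        "abundance_edges": int(len(G.edges_species_sample)),
        "metabolic": int(len(G.edges_metabolic)),
        "phylogenetic": int(len(G.edges_phylogenetic)),
        "species_sample_density": float(len(G.edges_species_sample)) / (M * N),
        "isolated_nodes": int((deg == 0).sum()),
    }
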
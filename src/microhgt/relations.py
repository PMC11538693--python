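"""Species-species relation matrices from knowledge tables.

Two binary, symmetric, zero-diagonal M x M matrices enter the graph:

* metabolic: a pair is linked when both species consume a common compound
  (competition) or one produces a compound the other consumes
  (complementarity); the two mechanisms are merged without distinction and
  edges are unweighted and undirected.
* phylogenetic: a pair is linked when both species belong to the same genus.

Species absent from the knowledge tables simply receive no edges: curated
interaction databases cover only well-studied organisms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundInteractionTable",
    "TaxonomyTable",
    "RelationMatrix",
    "metabolic_relations",
    "phylogenetic_relations",
    "validate_relation_matrix",
    "read_compound_table",
    "read_taxonomy",
    "read_relation_matrix",
    "write_relation_matrix",
]

_DIRECTIONS = ("produce", "consume")


@dataclass
class CompoundInteractionTable:
    """Deduplicated (species, compound, produce/consume) records."""

    records: pd.DataFrame  # columns: species_id, compound_id, direction

    def __post_init__(self):
        df = self.records
        for col in ("species_id", "compound_id", "direction"):
            if col not in df.columns:
                raise ParseError(f"compound table missing column {col!r}")
        bad = set(df["direction"]) - set(_DIRECTIONS)
        if bad:
            raise ParseError(f"unknown direction token(s): {sorted(bad)}")
        self.records = df.drop_duplicates(ignore_index=True)


@dataclass
class TaxonomyTable:
    """Species -> genus mapping; each species maps to exactly one genus."""

    records: pd.DataFrame  # columns: species_id, genus_id

    def __post_init__(self):
        df = self.records
        for col in ("species_id", "genus_id"):
            if col not in df.columns:
                raise ParseError(f"taxonomy table missing column {col!r}")
        df = df.drop_duplicates(ignore_index=True)
        dup = df["species_id"][df["species_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"species mapped to multiple genera: {sorted(set(dup))}")
        self.records = df

    def genus_of(self) -> dict:
        return dict(zip(self.records["species_id"], self.records["genus_id"]))


@dataclass
class RelationMatrix:
    """Symmetric binary species-species matrix with zero diagonal."""

    species_ids: list[str]
    values: np.ndarray  # (M, M) of {0, 1}
    kind: str  # "metabolic" | "phylogenetic"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        M = len(self.species_ids)
        if self.values.shape != (M, M):
            raise ValidationError("relation matrix shape does not match species list")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("relation matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        if not np.array_equal(self.values, self.values.T):
            raise ValidationError("relation matrix must be symmetric")
        if np.diagonal(self.values).any():
            raise ValidationError("relation matrix must have a zero diagonal")

    @property
    def n_edges(self) -> int:
        return int(self.values.sum()) // 2

    def pairs(self) -> np.ndarray:
        """Undirected edges as an (n_edges, 2) array of indices with i < j."""
        iu, ju = np.triu_indices(len(self.species_ids), k=1)
        on = self.values[iu, ju] == 1
        return np.column_stack([iu[on], ju[on]])


def metabolic_relations(table: CompoundInteractionTable, species_ids: list[str]) -> RelationMatrix:
    """Link species pairs by shared consumption or producer->consumer compounds.

    A compound consumed by more than two species links every pair of its
    consumers (pairwise rule, yielding a clique).  Records mentioning species
    outside `species_ids` are ignored.
    """
    if not species_ids:
        raise ValidationError("species_ids must be non-empty")
    M = len(species_ids)
    idx = {s: i for i, s in enumerate(species_ids)}
    D = np.zeros((M, M), dtype=np.int8)
    df = table.records
    df = df[df["species_id"].isin(idx)]
    for _, grp in df.groupby("compound_id"):
        consumers = np.array(sorted({idx[s] for s in grp.loc[grp["direction"] == "consume", "species_id"]}))
        producers = np.array(sorted({idx[s] for s in grp.loc[grp["direction"] == "produce", "species_id"]}))
        if consumers.size > 1:  # competition clique among co-consumers
            D[np.ix_(consumers, consumers)] = 1
        if consumers.size and producers.size:  # complementarity
            D[np.ix_(producers, consumers)] = 1
            D[np.ix_(consumers, producers)] = 1
    np.fill_diagonal(D, 0)
    return RelationMatrix(list(species_ids), D, "metabolic")


def phylogenetic_relations(taxonomy: TaxonomyTable, species_ids: list[str]) -> RelationMatrix:
    """Link species pairs that share a genus."""
    if not species_ids:
        raise ValidationError("species_ids must be non-empty")
    genus = taxonomy.genus_of()
    missing = [s for s in species_ids if s not in genus]
    if missing:
        logger.warning("%d species missing from taxonomy receive no edges", len(missing))
    M = len(species_ids)
    D = np.zeros((M, M), dtype=np.int8)
    by_genus: dict = {}
    for i, s in enumerate(species_ids):
        if s in genus:
            by_genus.setdefault(genus[s], []).append(i)
    for members in by_genus.values():
        if len(members) > 1:
            m = np.array(members)
            D[np.ix_(m, m)] = 1
    np.fill_diagonal(D, 0)
    return RelationMatrix(list(species_ids), D, "phylogenetic")


def validate_relation_matrix(
    species_ids_in: list[str], values: np.ndarray, kind: str, species_ids: list[str]
) -> RelationMatrix:
    """Sanitise a user-supplied matrix and align it to the abundance species.

    Symmetrises by OR, forces the diagonal to zero, and reorders/subsets the
    rows and columns to `species_ids`; species absent from the input matrix
    get all-zero rows.
    """
    values = np.asarray(values)
    if not np.isin(values, (0, 1)).all():
        raise ValidationError("relation matrix entries must be 0 or 1")
    if values.shape != (len(species_ids_in), len(species_ids_in)):
        raise ValidationError("relation matrix is not square over its species list")
    sym = ((values.astype(bool)) | (values.astype(bool).T)).astype(np.int8)
    if not np.array_equal(sym, values):
        logger.warning("relation matrix symmetrized by OR")
    if np.diagonal(sym).any():
        logger.warning("relation matrix diagonal forced to zero")
        np.fill_diagonal(sym, 0)
    pos = {s: i for i, s in enumerate(species_ids_in)}
    M = len(species_ids)
    out = np.zeros((M, M), dtype=np.int8)
    present = [(i, pos[s]) for i, s in enumerate(species_ids) if s in pos]
    if present:
        new_i = np.array([p[0] for p in present])
        old_i = np.array([p[1] for p in present])
        out[np.ix_(new_i, new_i)] = sym[np.ix_(old_i, old_i)]
    return RelationMatrix(list(species_ids), out, kind)


# ---- readers / writers ------------------------------------------------------


def read_compound_table(path) -> CompoundInteractionTable:
    return CompoundInteractionTable(pd.read_csv(path, sep="\t", dtype=str))


def read_taxonomy(path) -> TaxonomyTable:
    return TaxonomyTable(pd.read_csv(path, sep="\t", dtype=str))


def read_relation_matrix(path, kind: str, species_ids: list[str]) -> RelationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        # order can differ; require the same identifier sets
        if set(df.index) != set(df.columns):
            raise ValidationError("relation matrix row and column identifiers differ")
        df = df.loc[df.index, df.index]
    return validate_relation_matrix(list(df.index), df.to_numpy(), kind, species_ids)


def write_relation_matrix(D: RelationMatrix, path) -> None:
    pd.DataFrame(D.values, index=D.species_ids, columns=D.species_ids).to_csv(
        path, sep="\t", index_label="species_id"
    )
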
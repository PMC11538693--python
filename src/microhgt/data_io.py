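"""Tabular input/output and abundance preprocessing.

The central object is the species x sample relative-abundance matrix.
Preprocessing follows the standard recipe for compositional microbiome
profiles: drop species rows whose fraction of non-zero entries falls below
a prevalence cutoff, then renormalise every sample column to sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceMatrix",
    "SampleLabels",
    "read_abundance",
    "write_abundance",
    "read_labels",
    "write_labels",
    "preprocess_abundance",
    "encode_labels",
]


def _check_unique(ids, what: str):
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class AbundanceMatrix:
    """Species x sample relative-abundance matrix.

    values[i, j] is the (non-negative) abundance of species i in sample j.
    After :func:`preprocess_abundance` every column sums to 1.
    """

    species_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (M, N) float64, >= 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("abundance values must be a 2-D matrix")
        if self.values.shape != (len(self.species_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.sample_ids)} samples"
            )
        _check_unique(self.species_ids, "species")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("abundance matrix contains non-finite entries")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative abundance at species {self.species_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species_ids, columns=self.sample_ids)


@dataclass
class SampleLabels:
    """Per-sample class labels with a one-hot encoding.

    `classes` fixes the column order of `onehot`; every label must appear
    in `classes` and each one-hot row sums to exactly 1.
    """

    sample_ids: list[str]
    labels: list[str]
    classes: list[str]
    onehot: np.ndarray = field(default=None)  # (N, C) 0/1

    def __post_init__(self):
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.classes, "class")
        if len(self.labels) != len(self.sample_ids):
            raise ValidationError("labels and sample_ids differ in length")
        cls_index = {c: k for k, c in enumerate(self.classes)}
        unknown = sorted({l for l in self.labels if l not in cls_index})
        if unknown:
            raise ValidationError(f"labels not in class list: {unknown}")
        if self.onehot is None:
            onehot = np.zeros((len(self.labels), len(self.classes)), dtype=np.int64)
            for i, lab in enumerate(self.labels):
                onehot[i, cls_index[lab]] = 1
            self.onehot = onehot
        else:
            self.onehot = np.asarray(self.onehot, dtype=np.int64)
            if not np.array_equal(self.onehot.sum(axis=1), np.ones(len(self.labels))):
                raise ValidationError("each one-hot row must sum to exactly 1")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_indices(self) -> np.ndarray:
        """Integer class index per sample, in `classes` order."""
        return self.onehot.argmax(axis=1)

    def subset(self, idx) -> "SampleLabels":
        idx = np.asarray(idx)
        return SampleLabels(
            [self.sample_ids[i] for i in idx],
            [self.labels[i] for i in idx],
            list(self.classes),
        )


# ---- readers / writers ----------------------------------------------------


def read_abundance(path, orientation: str = "species_rows") -> AbundanceMatrix:
    """Read an abundance TSV (identifier header row and column, numeric body).

    `orientation="sample_rows"` transposes on read so the returned matrix is
    always species x sample.
    """
    if orientation not in ("species_rows", "sample_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    body = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                body[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric cell {raw!r} at row {df.index[i]!r}, column {col!r}"
                ) from None
    if orientation == "sample_rows":
        return AbundanceMatrix(list(df.columns), [str(x) for x in df.index], body.T)
    return AbundanceMatrix([str(x) for x in df.index], list(df.columns), body)


def write_abundance(A: AbundanceMatrix, path) -> None:
    A.to_frame().to_csv(path, sep="\t", index_label="species_id")


def read_labels(path, classes: list[str] | None = None) -> SampleLabels:
    """Read a two-column labels TSV (`sample_id`, `label`, with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise ParseError(f"labels file missing required column {col!r}")
    return encode_labels(df["sample_id"].tolist(), df["label"].tolist(), classes)


def write_labels(labels: SampleLabels, path) -> None:
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels}).to_csv(
        path, sep="\t", index=False
    )


# ---- preprocessing ---------------------------------------------------------


def preprocess_abundance(A: AbundanceMatrix, min_nonzero_frac: float = 0.0005) -> AbundanceMatrix:
    """Prevalence-filter species rows, then renormalise sample columns.

    Rows whose fraction of non-zero entries across samples is strictly below
    `min_nonzero_frac` are dropped (the default 0.05% removes only all-zero
    rows unless N is in the thousands).  Each remaining column is divided by
    its sum, so columns sum to 1.  Idempotent.
    """
    if not 0.0 <= min_nonzero_frac <= 1.0:
        raise ValidationError("min_nonzero_frac must be in [0, 1]")
    if A.n_species < 1 or A.n_samples < 1:
        raise ValidationError("abundance matrix must be non-empty")
    frac_nonzero = (A.values > 0).mean(axis=1)
    keep = frac_nonzero >= min_nonzero_frac if min_nonzero_frac > 0 else frac_nonzero > 0
    # min_nonzero_frac == 0 still drops all-zero rows: they carry no edges.
    dropped = int((~keep).sum())
    if dropped:
        logger.info("prevalence filter removed %d of %d species rows", dropped, A.n_species)
    vals = A.values[keep]
    colsum = vals.sum(axis=0)
    empty = np.flatnonzero(colsum == 0)
    if empty.size:
        names = [A.sample_ids[j] for j in empty[:5]]
        raise ValidationError(f"samples with no retained species after filtering: {names}")
    return AbundanceMatrix(
        [s for s, k in zip(A.species_ids, keep) if k], list(A.sample_ids), vals / colsum
    )


def encode_labels(sample_ids, labels, classes: list[str] | None = None) -> SampleLabels:
    """One-hot encode labels; class order lexicographic unless given."""
    if classes is None:
        classes = sorted(set(labels))
    return SampleLabels(list(sample_ids), list(labels), list(classes))


def align_labels(A: AbundanceMatrix, labels: SampleLabels) -> SampleLabels:
    """Reorder labels to the abundance sample order (exact string match)."""
    pos = {s: i for i, s in enumerate(labels.sample_ids)}
    missing = [s for s in A.sample_ids if s not in pos]
    if missing:
        raise ValidationError(f"unlabeled samples: {missing}")
    idx = [pos[s] for s in A.sample_ids]
    return labels.subset(idx)
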
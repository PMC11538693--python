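"""Autoencoder initial embeddings for species and sample nodes.

Sparse compositional abundance profiles are noisy inputs for a graph
transformer, so each node type gets a d-dimensional starting embedding from
a small autoencoder: one hidden layer of width d (the embedding), a linear
decoder, and a mean-square-error reconstruction loss.  Species inputs are
the rows of the abundance matrix (length-N profiles); sample inputs are the
columns (length-M profiles).  Both node types share the same d so they enter
the transformer with equal width.

The embedding dimension, epoch count, learning rate and hidden activation
are implementation defaults (d=64, 200 epochs, Adam at 1e-3, ReLU), all
exposed in :class:`AutoencoderConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor
from .data_io import AbundanceMatrix
from .errors import ConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "AutoencoderConfig",
    "EmbeddingMatrix",
    "train_species_autoencoder",
    "train_sample_autoencoder",
]


@dataclass
class AutoencoderConfig:
    hidden_dim: int = 64
    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0
    activation: str = "relu"  # "relu" | "linear"

    def __post_init__(self):
        if self.hidden_dim <= 0:
            raise ConfigError("hidden_dim must be positive")
        if self.epochs <= 0:
            raise ConfigError("epochs must be positive")
        if self.activation not in ("relu", "linear"):
            raise ConfigError(f"unknown activation {self.activation!r}")


@dataclass
class EmbeddingMatrix:
    node_ids: list[str]
    values: np.ndarray  # (n_nodes, d)
    role: str  # "species" | "sample"
    mse_trace: list = None  # per-epoch reconstruction MSE, first entry untrained

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.node_ids):
            raise ValueError("embedding row count does not match node count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains non-finite entries")

    def write(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.node_ids)
        df.columns = [f"dim_{k}" for k in range(self.values.shape[1])]
        df.to_csv(path, sep="\t", index_label="node_id")


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (n_in + n_out))
    return rng.normal(0.0, scale, size=(n_in, n_out))


def _train_autoencoder(X: np.ndarray, cfg: AutoencoderConfig):
    """Fit encoder->hidden->decoder on rows of X; return (hidden, mse_trace)."""
    n, p = X.shape
    rng = np.random.default_rng(cfg.seed)
    W1 = Tensor(_glorot(rng, p, cfg.hidden_dim), requires_grad=True)
    b1 = Tensor(np.zeros(cfg.hidden_dim), requires_grad=True)
    W2 = Tensor(_glorot(rng, cfg.hidden_dim, p), requires_grad=True)
    b2 = Tensor(np.zeros(p), requires_grad=True)
    Xt = Tensor(X)
    opt = Adam([W1, b1, W2, b2], lr=cfg.learning_rate)

    def forward():
        h = Xt @ W1 + b1
        if cfg.activation == "relu":
            h = h.relu()
        recon = h @ W2 + b2
        loss = (recon - Xt).power(2.0).mean()
        return h, loss

    _, loss0 = forward()
    trace = [loss0.item()]
    for _ in range(cfg.epochs):
        opt.zero_grad()
        _, loss = forward()
        loss.backward()
        opt.step()
        trace.append(loss.item())
    hidden, final_loss = forward()
    trace.append(final_loss.item())
    if trace[-1] > trace[0]:
        logger.warning("autoencoder reconstruction MSE did not improve (%.3g -> %.3g)",
                       trace[0], trace[-1])
    return hidden.data.copy(), trace


def train_species_autoencoder(A: AbundanceMatrix, cfg: AutoencoderConfig) -> EmbeddingMatrix:
    """Embed each species from its length-N abundance profile."""
    if A.n_species < 2:
        raise ConfigError("need at least 2 species to train the species autoencoder")
    if cfg.hidden_dim > min(A.n_species, A.n_samples):
        logger.warning("hidden_dim %d exceeds min(M, N) = %d",
                       cfg.hidden_dim, min(A.n_species, A.n_samples))
    hidden, trace = _train_autoencoder(A.values, cfg)
    return EmbeddingMatrix(list(A.species_ids), hidden, "species", trace)


def train_sample_autoencoder(A: AbundanceMatrix, cfg: AutoencoderConfig) -> EmbeddingMatrix:
    """Embed each sample from its length-M abundance profile."""
    if A.n_samples < 2:
        raise ConfigError("need at least 2 samples to train the sample autoencoder")
    if cfg.hidden_dim > min(A.n_species, A.n_samples):
        logger.warning("hidden_dim %d exceeds min(M, N) = %d",
                       cfg.hidden_dim, min(A.n_species, A.n_samples))
    hidden, trace = _train_autoencoder(A.values.T, cfg)
    return EmbeddingMatrix(list(A.sample_ids), hidden, "sample", trace)
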
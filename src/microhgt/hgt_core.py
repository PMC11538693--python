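"""Heterogeneous graph transformer: attention, message passing, losses, training.

Each layer computes node- and edge-type dependent multi-head attention.  For
a directed edge (v_s, e, v_t) with meta-relation <tau(v_s), phi(e), tau(v_t)>
and head k:

    score_k = K^k(v_s) . W_att_phi . Q^k(v_t) * mu_<...> / sqrt(d)

where K^k / Q^k are head slices of node-type-specific linear projections of
the previous-layer embeddings.  Scores are softmax-normalised per head across
all source nodes of each target (so per-target, per-head attention sums to 1),
and weight per-head messages MSG^k = V^k(v_s) . W_msg_phi.  The aggregated
message H~ updates the target through a gated residual

    H^l[v_t] = theta * ReLU(H~[v_t]) + (1 - theta) * H^{l-1}[v_t]

with a trainable per-node-type gate theta = sigmoid(raw).  (The alternative
residual weight (theta - 1) is available as ``residual_form="literal"``.)
Sample embeddings after L layers feed a softmax classifier over the C classes.

Training minimises focal loss (class weights alpha_c = 1 - n_c/N, focusing
exponent gamma) plus a KL regulariser that ties the row distributions of
softmax(S_encoder . P_encoder^T) to the renormalised abundance rows, weighted
by reg_alpha (default 0.003).  Training is full-batch and transductive: the
goal is attention extraction over all samples, not held-out prediction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor, concat, gather, segment_softmax, segment_sum
from .data_io import SampleLabels
from .embeddings import EmbeddingMatrix, _glorot
from .errors import ConfigError, TrainingError, ValidationError
from .hetgraph import HeteroGraph

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "HGTParams",
    "AttentionTensor",
    "PredictionMatrix",
    "TrainResult",
    "attention_head",
    "normalize_attention",
    "message_head",
    "aggregate_message",
    "aggregate_update",
    "classify",
    "class_weights",
    "focal_loss",
    "kl_regularizer",
    "total_loss",
    "init_params",
    "forward",
    "train_model",
]

NODE_TYPES = ("species", "sample")
EDGE_TYPES = ("metabolic", "phylogenetic", "abundance")


@dataclass
class TrainConfig:
    heads: int = 8
    layers: int = 2
    gamma: float = 2.0  # focal-loss focusing exponent, >= 0
    reg_alpha: float = 0.003  # weight of the KL regulariser
    epochs: int = 500
    learning_rate: float = 1e-3
    seed: int = 0
    residual_form: str = "gated"  # "gated": (1-theta) residual; "literal": (theta-1)
    attention_softmax_scope: str = "all"  # "all" | "per_edge_type"
    attention_layer: str = "final"  # "final" | "mean"

    def __post_init__(self):
        if self.gamma < 0:
            raise ConfigError("gamma must be >= 0")
        if self.reg_alpha < 0:
            raise ConfigError("reg_alpha must be >= 0")
        if self.heads < 1 or self.layers < 1:
            raise ConfigError("heads and layers must be >= 1")
        if self.residual_form not in ("gated", "literal"):
            raise ConfigError(f"unknown residual_form {self.residual_form!r}")
        if self.attention_softmax_scope not in ("all", "per_edge_type"):
            raise ConfigError(f"unknown attention_softmax_scope {self.attention_softmax_scope!r}")
        if self.attention_layer not in ("final", "mean"):
            raise ConfigError(f"unknown attention_layer {self.attention_layer!r}")


@dataclass
class HGTParams:
    """All trainable tensors of the model.

    Projections and relation matrices are per layer; the head structure is
    realised by viewing each d x d projection as h slices of width d/h.
    """

    d: int
    heads: int
    layers: int
    n_classes: int
    layer_params: list  # per layer: dict with k_lin/q_lin/v_lin, w_att/w_msg, mu, theta_raw
    clf_W: Tensor
    clf_b: Tensor

    def parameters(self) -> list[Tensor]:
        out = []
        for lp in self.layer_params:
            for group in ("k_lin", "q_lin", "v_lin", "w_att", "w_msg", "mu", "theta_raw"):
                out.extend(lp[group].values())
        out.extend([self.clf_W, self.clf_b])
        return out


@dataclass
class AttentionTensor:
    """Per-layer, per-head normalized attention on every directed edge."""

    n_species: int
    n_samples: int
    heads: int
    # per layer: dict (src_type, edge_type, tgt_type) -> (src_idx, tgt_idx, att (E, h))
    layers: list

    def species_to_sample(self, layer: str = "final") -> np.ndarray:
        """Dense (h, M, N) attention on (species, abundance, sample) edges.

        Entries without an edge are exactly 0.  `layer="mean"` averages the
        attention over all layers; the default reads the final layer.
        """
        key = ("species", "abundance", "sample")
        chosen = self.layers if layer == "mean" else [self.layers[-1]]
        out = np.zeros((self.heads, self.n_species, self.n_samples))
        for rec in chosen:
            if key not in rec:
                raise ValidationError("graph has no species->sample abundance edges")
            src, tgt, att = rec[key]
            out[:, src, tgt] += att.T
        out /= len(chosen)
        return out


@dataclass
class PredictionMatrix:
    sample_ids: list[str]
    probs: np.ndarray  # (N, C), rows sum to 1

    def predicted_indices(self) -> np.ndarray:
        return self.probs.argmax(axis=1)


@dataclass
class TrainResult:
    params: HGTParams
    attention: AttentionTensor
    predictions: PredictionMatrix
    loss_trace: list[float]
    train_accuracy: float
    species_encoder: np.ndarray = field(repr=False)  # final species embeddings (M, d)
    sample_encoder: np.ndarray = field(repr=False)  # final sample embeddings (N, d)


# ---- single-edge reference operations (numpy) ------------------------------
# These spell out the per-edge algebra; the training path uses the vectorised
# Tensor implementation in `forward`, which the tests check against these.


def attention_head(h_src, h_tgt, k_lin, q_lin, w_att, mu, k, n_heads) -> float:
    """Raw (pre-softmax) attention of one head for a single directed edge."""
    h_src = np.asarray(h_src, dtype=float)
    d = h_src.shape[0]
    dh = d // n_heads
    K = (h_src @ np.asarray(k_lin)).reshape(n_heads, dh)[k]
    Q = (np.asarray(h_tgt, dtype=float) @ np.asarray(q_lin)).reshape(n_heads, dh)[k]
    return float((K @ np.asarray(w_att)) @ Q * mu / math.sqrt(d))


def normalize_attention(raw_scores, tgt_idx, n_targets) -> np.ndarray:
    """Head-wise softmax of raw scores across the source nodes of each target.

    raw_scores: (E, h); tgt_idx: (E,) target of each row.  Targets that appear
    get per-head attention summing to 1; targets with no incoming edges simply
    have no rows (they are excluded from normalization).
    """
    raw_scores = np.asarray(raw_scores, dtype=float)
    tgt_idx = np.asarray(tgt_idx, dtype=np.intp)
    present = np.unique(tgt_idx)
    if present.size < n_targets:
        logger.warning("%d target(s) have no source nodes and are excluded",
                       n_targets - present.size)
    m = np.full((n_targets,) + raw_scores.shape[1:], -np.inf)
    np.maximum.at(m, tgt_idx, raw_scores)
    z = np.exp(raw_scores - m[tgt_idx])
    denom = np.zeros_like(m)
    np.add.at(denom, tgt_idx, z)
    return z / denom[tgt_idx]


def message_head(h_src, v_lin, w_msg, k, n_heads) -> np.ndarray:
    """Per-head message vector (length d/h) for a single directed edge."""
    h_src = np.asarray(h_src, dtype=float)
    d = h_src.shape[0]
    dh = d // n_heads
    V = (h_src @ np.asarray(v_lin)).reshape(n_heads, dh)[k]
    return V @ np.asarray(w_msg)


def aggregate_message(h_src, v_lin, w_msg, n_heads) -> np.ndarray:
    """All h message heads concatenated in head order (length d)."""
    return np.concatenate(
        [message_head(h_src, v_lin, w_msg, k, n_heads) for k in range(n_heads)]
    )


def aggregate_update(att, msg, tgt_idx, H_prev, theta, residual_form: str = "gated") -> np.ndarray:
    """Attention-weighted message aggregation plus the gated residual update.

    att: (E, h) normalized attention; msg: (E, h, d/h) per-head messages;
    H_prev: (n, d).  Head k of the aggregate uses head-k attention.
    """
    att = np.asarray(att, dtype=float)
    msg = np.asarray(msg, dtype=float)
    n, d = np.asarray(H_prev).shape
    agg = np.zeros((n, att.shape[1], msg.shape[2]))
    np.add.at(agg, np.asarray(tgt_idx, dtype=np.intp), att[:, :, None] * msg)
    agg = agg.reshape(n, d)
    if not np.all(np.isfinite(agg)):
        raise TrainingError("NaN in aggregated update")
    res_w = (1.0 - theta) if residual_form == "gated" else (theta - 1.0)
    return theta * np.maximum(agg, 0.0) + res_w * np.asarray(H_prev, dtype=float)


def classify(H_samples, W, b) -> np.ndarray:
    """Softmax class probabilities from final sample embeddings."""
    W = np.asarray(W, dtype=float)
    if W.shape[1] < 2:
        raise ConfigError("classifier needs at least 2 classes")
    logits = np.asarray(H_samples, dtype=float) @ W + np.asarray(b, dtype=float)
    z = np.exp(logits - logits.max(axis=1, keepdims=True))
    return z / z.sum(axis=1, keepdims=True)


# ---- losses ----------------------------------------------------------------


def class_weights(onehot) -> np.ndarray:
    """alpha_c = 1 - n_c / N (rarer classes get larger weight)."""
    onehot = np.asarray(onehot, dtype=float)
    if onehot.size == 0:
        raise ValidationError("empty label matrix")
    if not np.array_equal(onehot.sum(axis=1), np.ones(onehot.shape[0])):
        raise ValidationError("each one-hot row must sum to 1")
    return 1.0 - onehot.sum(axis=0) / onehot.shape[0]


def _focal_loss_t(probs: Tensor, onehot: np.ndarray, gamma: float, alpha: np.ndarray) -> Tensor:
    onehot = np.asarray(onehot, dtype=float)
    n = onehot.shape[0]
    p_true = (probs * Tensor(onehot)).sum(axis=1)  # true-class probability per sample
    if (p_true.data <= 1e-12).any():
        logger.warning("clamping %d zero predicted probabilities at true labels",
                       int((p_true.data <= 1e-12).sum()))
    p_safe = p_true.clip_min(1e-12)
    alpha_i = Tensor(onehot @ np.asarray(alpha, dtype=float))
    per_sample = alpha_i * (1.0 - p_true).power(gamma) * p_safe.log()
    return -(per_sample.sum() * (1.0 / n))


def focal_loss(probs, onehot, gamma: float, alpha=None) -> float:
    """Focal loss, -1/N sum_i alpha_{c_i} (1 - p_i)^gamma log p_i.

    With gamma=0 this is alpha-weighted cross-entropy.  `alpha` defaults to
    the class weights of Eq-style balancing (1 - class frequency).
    """
    if gamma < 0:
        raise ConfigError("gamma must be >= 0")
    if alpha is None:
        alpha = class_weights(onehot)
    return _focal_loss_t(Tensor(np.asarray(probs, dtype=float)), onehot, gamma, alpha).item()


def _kl_regularizer_t(S: Tensor, P: Tensor, A: np.ndarray) -> Tensor:
    """Mean KL over species rows between renormalised A and softmax(S P^T)."""
    A = np.asarray(A, dtype=float)
    rowsum = A.sum(axis=1)
    keep = rowsum > 0
    if not keep.all():
        logger.warning("%d all-zero abundance rows excluded from KL", int((~keep).sum()))
    A_norm = np.zeros_like(A)
    A_norm[keep] = A[keep] / rowsum[keep, None]
    logits = S @ P.T
    shift = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    log_q = shift - shift.exp().sum(axis=1, keepdims=True).log()
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(A_norm > 0, A_norm * np.log(A_norm), 0.0).sum(axis=1)  # sum a log a
    cross = (Tensor(A_norm) * log_q).sum(axis=1)
    kl_rows = Tensor(ent) - cross
    n_kept = int(keep.sum())
    return (kl_rows * Tensor(keep.astype(float))).sum() * (1.0 / n_kept)


def kl_regularizer(S_encoder, P_encoder, A) -> float:
    """KL(renormalised A rows || row-softmax of S_encoder . P_encoder^T)."""
    return _kl_regularizer_t(
        Tensor(np.asarray(S_encoder, dtype=float)),
        Tensor(np.asarray(P_encoder, dtype=float)),
        A,
    ).item()


def total_loss(focal: float, kl: float, reg_alpha: float = 0.003) -> float:
    """Loss = focal + reg_alpha * KL."""
    return focal + reg_alpha * kl


# ---- model construction and forward pass ------------------------------------


def init_params(d: int, n_classes: int, cfg: TrainConfig, rng: np.random.Generator) -> HGTParams:
    if d % cfg.heads != 0:
        raise ConfigError(f"embedding dim {d} not divisible by heads {cfg.heads}")
    dh = d // cfg.heads
    meta_relations = [
        ("species", "metabolic", "species"),
        ("species", "phylogenetic", "species"),
        ("species", "abundance", "sample"),
        ("sample", "abundance", "species"),
    ]
    layer_params = []
    for _ in range(cfg.layers):
        lp = {
            "k_lin": {nt: Tensor(_glorot(rng, d, d), requires_grad=True) for nt in NODE_TYPES},
            "q_lin": {nt: Tensor(_glorot(rng, d, d), requires_grad=True) for nt in NODE_TYPES},
            "v_lin": {nt: Tensor(_glorot(rng, d, d), requires_grad=True) for nt in NODE_TYPES},
            "w_att": {et: Tensor(_glorot(rng, dh, dh), requires_grad=True) for et in EDGE_TYPES},
            "w_msg": {et: Tensor(_glorot(rng, dh, dh), requires_grad=True) for et in EDGE_TYPES},
            # prior scalar per meta-relation, initialised at 1
            "mu": {mr: Tensor(1.0, requires_grad=True) for mr in meta_relations},
            # gate theta = sigmoid(raw); raw 0 -> theta 0.5
            "theta_raw": {nt: Tensor(0.0, requires_grad=True) for nt in NODE_TYPES},
        }
        layer_params.append(lp)
    return HGTParams(
        d=d,
        heads=cfg.heads,
        layers=cfg.layers,
        n_classes=n_classes,
        layer_params=layer_params,
        clf_W=Tensor(_glorot(rng, d, n_classes), requires_grad=True),
        clf_b=Tensor(np.zeros(n_classes), requires_grad=True),
    )


def _graph_layout(G: HeteroGraph, cfg: TrainConfig):
    """Precompute directed-edge index arrays shared by every epoch."""
    M, N = G.n_species, G.n_samples
    relations = G.meta_relations()
    if not relations:
        raise ValidationError("graph has no edges")
    etype_ix = {et: i for i, et in enumerate(EDGE_TYPES)}
    # global target ids: species 0..M-1, samples M..M+N-1
    seg_parts, rel_slices, pos = [], [], 0
    for src_t, et, tgt_t, src, tgt in relations:
        g_tgt = tgt if tgt_t == "species" else tgt + M
        if cfg.attention_softmax_scope == "per_edge_type":
            seg_parts.append(g_tgt * len(EDGE_TYPES) + etype_ix[et])
        else:
            seg_parts.append(g_tgt)
        rel_slices.append(((src_t, et, tgt_t), slice(pos, pos + len(src)), src, g_tgt))
        pos += len(src)
    seg = np.concatenate(seg_parts)
    n_seg = (M + N) * (len(EDGE_TYPES) if cfg.attention_softmax_scope == "per_edge_type" else 1)
    g_tgt_all = np.concatenate([g for (_, _, _, g) in rel_slices])
    return relations, rel_slices, seg, n_seg, g_tgt_all


def forward(params: HGTParams, G: HeteroGraph, H0_species, H0_sample, cfg: TrainConfig,
            layout=None):
    """Run L layers and the classifier.

    Returns (H_species, H_sample, probs) as Tensors plus the attention records
    (numpy) for every layer.  `layout` caches the directed-edge index arrays
    across epochs (built automatically when omitted).
    """
    M, N = G.n_species, G.n_samples
    d, h = params.d, params.heads
    dh = d // h
    relations, rel_slices, seg, n_seg, g_tgt_all = layout or _graph_layout(G, cfg)

    H = {"species": Tensor._lift(H0_species), "sample": Tensor._lift(H0_sample)}
    att_layers = []
    for lp in params.layer_params:
        K = {nt: (H[nt] @ lp["k_lin"][nt]).reshape(-1, h, dh) for nt in NODE_TYPES}
        Q = {nt: (H[nt] @ lp["q_lin"][nt]).reshape(-1, h, dh) for nt in NODE_TYPES}
        V = {nt: (H[nt] @ lp["v_lin"][nt]).reshape(-1, h, dh) for nt in NODE_TYPES}
        scores, msgs = [], []
        for src_t, et, tgt_t, src, tgt in relations:
            Ke = gather(K[src_t], src)  # (E, h, dh)
            Qe = gather(Q[tgt_t], tgt)
            raw = ((Ke @ lp["w_att"][et]) * Qe).sum(axis=2)  # (E, h)
            scores.append(raw * (lp["mu"][(src_t, et, tgt_t)] * (1.0 / math.sqrt(d))))
            msgs.append(gather(V[src_t], src) @ lp["w_msg"][et])  # (E, h, dh)
        att = segment_softmax(concat(scores), seg, n_seg)
        weighted = att.reshape(-1, h, 1) * concat(msgs)
        agg = segment_sum(weighted, g_tgt_all, M + N).reshape(M + N, d)
        if not np.all(np.isfinite(agg.data)):
            raise TrainingError("non-finite aggregated embedding update")
        new_H = {}
        for nt, rows in (("species", np.arange(M)), ("sample", np.arange(M, M + N))):
            theta = lp["theta_raw"][nt].sigmoid()
            res_w = (1.0 - theta) if cfg.residual_form == "gated" else (theta - 1.0)
            new_H[nt] = theta * gather(agg, rows).relu() + res_w * H[nt]
        H = new_H
        att_layers.append(
            {key: (src, g_tgt - (M if key[2] == "sample" else 0), att.data[sl].copy())
             for key, sl, src, g_tgt in rel_slices}
        )
    logits = H["sample"] @ params.clf_W + params.clf_b
    z = (logits - Tensor(logits.data.max(axis=1, keepdims=True))).exp()
    probs = z / z.sum(axis=1, keepdims=True)
    return H["species"], H["sample"], probs, att_layers


def train_model(
    G: HeteroGraph,
    species_emb: EmbeddingMatrix,
    sample_emb: EmbeddingMatrix,
    labels: SampleLabels,
    cfg: TrainConfig,
    params: HGTParams | None = None,
) -> TrainResult:
    """Full-batch transductive training; returns trained parameters, the
    attention tensor extracted from the trained model, predictions and the
    loss trace."""
    if labels.n_classes < 2:
        raise ConfigError("training requires at least 2 classes")
    if list(labels.sample_ids) != list(G.sample_ids):
        raise ValidationError("label sample order does not match graph sample order")
    if species_emb.values.shape[1] != sample_emb.values.shape[1]:
        raise ConfigError("species and sample embeddings must share the same dimension d")
    d = species_emb.values.shape[1]
    rng = np.random.default_rng(cfg.seed)
    if params is None:
        params = init_params(d, labels.n_classes, cfg, rng)
    alpha = class_weights(labels.onehot)
    H0s, H0p = Tensor(species_emb.values), Tensor(sample_emb.values)
    opt = Adam(params.parameters(), lr=cfg.learning_rate)
    layout = _graph_layout(G, cfg)
    trace = []
    for epoch in range(cfg.epochs):
        opt.zero_grad()
        Hs, Hp, probs, _ = forward(params, G, H0s, H0p, cfg, layout)
        loss = _focal_loss_t(probs, labels.onehot, cfg.gamma, alpha)
        if cfg.reg_alpha > 0:
            loss = loss + cfg.reg_alpha * _kl_regularizer_t(Hs, Hp, G.abundance)
        val = loss.item()
        if not math.isfinite(val):
            raise TrainingError(f"loss diverged (non-finite) at epoch {epoch}")
        trace.append(val)
        loss.backward()
        opt.step()
    Hs, Hp, probs, att_layers = forward(params, G, H0s, H0p, cfg, layout)
    attention = AttentionTensor(G.n_species, G.n_samples, cfg.heads, att_layers)
    predictions = PredictionMatrix(list(G.sample_ids), probs.data.copy())
    acc = float((predictions.predicted_indices() == labels.class_indices()).mean())
    if trace and trace[-1] > trace[0]:
        logger.warning("final loss %.4g above initial %.4g", trace[-1], trace[0])
    logger.info("training finished: loss %.4g -> %.4g, accuracy %.3f",
                trace[0] if trace else float("nan"), trace[-1] if trace else float("nan"), acc)
    return TrainResult(params, attention, predictions, trace, acc, Hs.data.copy(), Hp.data.copy())
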
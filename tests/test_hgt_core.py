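import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import microhgt as mg
from microhgt._autodiff import Tensor
from microhgt.errors import ConfigError, ValidationError
from microhgt.hgt_core import (
    TrainConfig,
    aggregate_message,
    aggregate_update,
    attention_head,
    class_weights,
    classify,
    focal_loss,
    forward,
    init_params,
    kl_regularizer,
    message_head,
    normalize_attention,
    total_loss,
    train_model,
)


# ---- single-edge reference operations ---------------------------------------


def test_attention_aligned_unit_vectors():
    d, h = 2, 1
    e1 = np.array([1.0, 0.0])
    score = attention_head(e1, e1, np.eye(d), np.eye(d), np.eye(d), 1.0, 0, h)
    assert score == pytest.approx(1.0 / math.sqrt(d))


def test_attention_mu_zero_and_linearity():
    rng = np.random.default_rng(0)
    d, h = 8, 2
    hs, ht = rng.normal(size=d), rng.normal(size=d)
    k_lin, q_lin = rng.normal(size=(d, d)), rng.normal(size=(d, d))
    w = rng.normal(size=(d // h, d // h))
    assert attention_head(hs, ht, k_lin, q_lin, w, 0.0, 1, h) == 0.0
    s1 = attention_head(hs, ht, k_lin, q_lin, w, 1.0, 1, h)
    s2 = attention_head(hs, ht, k_lin, q_lin, w, 2.0, 1, h)
    assert s2 == pytest.approx(2 * s1)


def test_normalize_single_source():
    att = normalize_attention(np.array([[3.7, -1.2]]), np.array([0]), 1)
    assert np.allclose(att, 1.0)


def test_normalize_two_equal_sources():
    att = normalize_attention(np.zeros((2, 3)), np.array([0, 0]), 1)
    assert np.allclose(att, 0.5)


def test_normalize_softmax_123():
    att = normalize_attention(np.array([[1.0], [2.0], [3.0]]), np.zeros(3, dtype=int), 1)
    assert np.allclose(att.ravel(), [0.0900, 0.2447, 0.6652], atol=1e-3)


def test_normalize_sums_to_one_per_target_per_head():
    rng = np.random.default_rng(3)
    scores = rng.normal(size=(20, 4))
    tgt = rng.integers(0, 5, size=20)
    att = normalize_attention(scores, tgt, 5)
    for t in np.unique(tgt):
        assert np.allclose(att[tgt == t].sum(axis=0), 1.0, atol=1e-12)


def test_message_identity_projection():
    d, h = 4, 2
    hs = np.array([1.0, 2.0, 3.0, 4.0])
    msg = message_head(hs, np.eye(d), np.eye(d // h), 1, h)
    assert np.allclose(msg, [3.0, 4.0])


def test_message_zero_source():
    assert np.allclose(message_head(np.zeros(4), np.eye(4), np.eye(2), 0, 2), 0.0)


def test_aggregate_message_concat_length():
    rng = np.random.default_rng(1)
    d, h = 8, 4
    out = aggregate_message(rng.normal(size=d), rng.normal(size=(d, d)),
                            rng.normal(size=(d // h, d // h)), h)
    assert out.shape == (d,)


def test_aggregate_update_theta_limits():
    rng = np.random.default_rng(2)
    att = np.array([[1.0, 1.0]])
    msg = rng.normal(size=(1, 2, 3))
    H_prev = rng.normal(size=(1, 6))
    assert np.allclose(aggregate_update(att, msg, [0], H_prev, 0.0), H_prev)
    agg = (att[:, :, None] * msg).reshape(1, 6)
    assert np.allclose(aggregate_update(att, msg, [0], H_prev, 1.0), np.maximum(agg, 0))


def test_aggregate_update_literal_form():
    H_prev = np.array([[1.0, -2.0]])
    out = aggregate_update(np.zeros((0, 1)), np.zeros((0, 1, 2)), [], H_prev, 0.0,
                           residual_form="literal")
    assert np.allclose(out, -H_prev)


def test_aggregate_update_single_source_value_projection():
    # one source, attention 1, theta=1: target update is ReLU of the message
    msg = np.array([[[0.5, 1.5]]])
    out = aggregate_update(np.array([[1.0]]), msg, [0], np.zeros((1, 2)), 1.0)
    assert np.allclose(out, [[0.5, 1.5]])


def test_classify_rows_and_closed_forms():
    H = np.array([[0.0, 0.0], [0.0, 0.0]])
    probs = classify(H, np.eye(2), np.zeros(2))
    assert np.allclose(probs, 0.5)
    probs = classify(np.array([[1.0]]), np.array([[math.log(2.0), 0.0]]), np.zeros(2))
    assert np.allclose(probs, [[2 / 3, 1 / 3]])


def test_classify_single_class_errors():
    with pytest.raises(ConfigError):
        classify(np.zeros((1, 2)), np.zeros((2, 1)), np.zeros(1))


# ---- losses ------------------------------------------------------------------


def test_class_weights_counts():
    onehot = np.array([[1, 0], [1, 0], [1, 0], [0, 1]])
    assert np.allclose(class_weights(onehot), [0.25, 0.75])


def test_class_weights_balanced():
    onehot = np.tile(np.eye(3), (4, 1))
    assert np.allclose(class_weights(onehot), 1 - 1 / 3)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(2, 6), st.integers(1, 40), st.integers(0, 10 ** 9))
def test_class_weights_sum_identity(C, N, seed):
    rng = np.random.default_rng(seed)
    onehot = np.eye(C)[rng.integers(0, C, size=N)]
    assert class_weights(onehot).sum() == pytest.approx(C - 1, abs=1e-12)


def test_focal_gamma_zero_is_weighted_cross_entropy():
    rng = np.random.default_rng(4)
    probs = rng.dirichlet(np.ones(3), size=10)
    onehot = np.eye(3)[rng.integers(0, 3, size=10)]
    alpha = class_weights(onehot)
    loss = focal_loss(probs, onehot, gamma=0.0)
    # independent oracle: alpha-weighted cross-entropy
    ce = -np.mean((onehot @ alpha) * np.log((probs * onehot).sum(axis=1)))
    assert loss == pytest.approx(ce, abs=1e-9)


def test_focal_perfect_predictions_zero():
    onehot = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert focal_loss(onehot, onehot, gamma=2.0) == pytest.approx(0.0, abs=1e-12)


def test_focal_hand_example():
    loss = focal_loss(np.array([[0.8, 0.2]]), np.array([[1.0, 0.0]]),
                      gamma=2.0, alpha=np.array([0.5, 0.5]))
    assert loss == pytest.approx(0.5 * 0.2 ** 2 * (-math.log(0.8)), abs=1e-9)
    assert loss == pytest.approx(0.004463, abs=1e-6)


def test_kl_zero_when_identical():
    # build S, P whose row-softmax equals the A row distribution
    A = np.array([[0.2, 0.8], [0.6, 0.4]])
    P = np.eye(2)
    S = np.log(A)  # softmax of log A rows = A rows (already normalized)
    assert kl_regularizer(S, P, A) == pytest.approx(0.0, abs=1e-12)


def test_kl_nonnegative_random():
    rng = np.random.default_rng(5)
    for _ in range(5):
        S, P = rng.normal(size=(6, 3)), rng.normal(size=(4, 3))
        A = rng.random((6, 4))
        assert kl_regularizer(S, P, A) >= 0


def test_kl_closed_form_single_row():
    # model row (0.9, 0.1): S.P^T = (log .9, log .1) with identity-ish P
    S = np.array([[math.log(0.9), math.log(0.1)]])
    P = np.eye(2)
    A = np.array([[0.5, 0.5]])
    expected = 0.5 * math.log(0.5 / 0.9) + 0.5 * math.log(0.5 / 0.1)
    assert kl_regularizer(S, P, A) == pytest.approx(expected, abs=1e-5)
    assert kl_regularizer(S, P, A) == pytest.approx(0.510826, abs=1e-5)


def test_total_loss():
    assert total_loss(1.0, 2.0, 0.003) == pytest.approx(1.006)
    assert total_loss(0.7, 5.0, 0.0) == 0.7
    assert total_loss(1.1, 2.0) > total_loss(1.0, 2.0)


# ---- forward pass and training ----------------------------------------------


def test_forward_matches_reference_ops(small_graph):
    """Dual route: vectorised forward vs the per-edge numpy reference ops."""
    G = small_graph
    d, h = 8, 2
    cfg = TrainConfig(heads=h, layers=1, seed=11)
    rng = np.random.default_rng(11)
    params = init_params(d, 2, cfg, rng)
    H0s = rng.normal(size=(G.n_species, d))
    H0p = rng.normal(size=(G.n_samples, d))
    _, _, _, att_layers = forward(params, G, Tensor(H0s), Tensor(H0p), cfg)

    lp = params.layer_params[0]
    H0 = {"species": H0s, "sample": H0p}
    # reference: raw score per directed edge via attention_head, then softmax
    rows, tgts, keys = [], [], []
    for src_t, et, tgt_t, src, tgt in G.meta_relations():
        for s, t in zip(src, tgt):
            rows.append([
                attention_head(
                    H0[src_t][s], H0[tgt_t][t],
                    lp["k_lin"][src_t].data, lp["q_lin"][tgt_t].data,
                    lp["w_att"][et].data, float(lp["mu"][(src_t, et, tgt_t)].data),
                    k, h,
                )
                for k in range(h)
            ])
            tgts.append(t if tgt_t == "species" else t + G.n_species)
            keys.append((src_t, et, tgt_t))
    ref_att = normalize_attention(np.array(rows), np.array(tgts), G.n_species + G.n_samples)
    pos = 0
    got = {key: dict() for key in att_layers[0]}
    for key in att_layers[0]:
        src, tgt, att = att_layers[0][key]
        got[key] = att
    for key, rec in att_layers[0].items():
        n = rec[2].shape[0]
        chunk = ref_att[[i for i, kk in enumerate(keys) if kk == key]]
        assert np.allclose(rec[2], chunk, atol=1e-10), key


def test_trained_attention_sums_to_one(small_trained, small_graph):
    # softmax scope "all": a target's sources across every edge type compete
    # in one softmax, so sums aggregate over all meta-relations
    M, N = small_graph.n_species, small_graph.n_samples
    for layer in small_trained.attention.layers:
        sums = np.zeros((M + N, small_trained.attention.heads))
        seen = np.zeros(M + N, dtype=bool)
        for (src_t, et, tgt_t), (src, tgt, att) in layer.items():
            g_tgt = tgt if tgt_t == "species" else tgt + M
            np.add.at(sums, g_tgt, att)
            seen[g_tgt] = True
        assert np.allclose(sums[seen], 1.0, atol=1e-6)


def test_prediction_rows_sum_to_one(small_trained):
    assert np.allclose(small_trained.predictions.probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(small_trained.predictions.probs >= 0)


def test_loss_trace_decreases(small_trained):
    assert small_trained.loss_trace[-1] < small_trained.loss_trace[0]


def _train_two_class(epochs, seed):
    spec = mg.SyntheticSpec(M=30, N=16, C=2, community_size=5, genus_size=3,
                            effect=50.0, sparsity=0.1, seed=seed)
    ds = mg.generate(spec)
    A = mg.preprocess_abundance(ds.abundance)
    G = mg.build_graph(A)
    from microhgt.embeddings import AutoencoderConfig, train_sample_autoencoder, train_species_autoencoder

    ae = AutoencoderConfig(hidden_dim=8, epochs=100, seed=seed)
    se, pe = train_species_autoencoder(A, ae), train_sample_autoencoder(A, ae)
    cfg = TrainConfig(heads=4, layers=2, epochs=epochs, seed=seed)
    return train_model(G, se, pe, ds.labels, cfg)


def test_two_separated_classes_perfect_accuracy():
    res = _train_two_class(epochs=300, seed=1)
    assert res.train_accuracy == 1.0


def test_training_determinism():
    a = _train_two_class(epochs=30, seed=2)
    b = _train_two_class(epochs=30, seed=2)
    assert np.array_equal(a.predictions.predicted_indices(), b.predictions.predicted_indices())
    assert np.array_equal(a.predictions.probs, b.predictions.probs)


def test_single_class_errors(small_dataset, small_graph):
    labels = mg.encode_labels(small_dataset.labels.sample_ids,
                              ["only"] * len(small_dataset.labels.sample_ids))
    from microhgt.embeddings import EmbeddingMatrix

    se = EmbeddingMatrix(list(small_graph.species_ids), np.zeros((small_graph.n_species, 4)), "species")
    pe = EmbeddingMatrix(list(small_graph.sample_ids), np.zeros((small_graph.n_samples, 4)), "sample")
    with pytest.raises(ConfigError):
        train_model(small_graph, se, pe, labels, TrainConfig(heads=2, epochs=1))


def test_h8_l2_defaults():
    cfg = TrainConfig()
    assert cfg.heads == 8 and cfg.layers == 2 and cfg.reg_alpha == 0.003


def test_init_params_requires_divisible_d():
    with pytest.raises(ConfigError):
        init_params(10, 2, TrainConfig(heads=4), np.random.default_rng(0))
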
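import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

import microhgt as mg
from microhgt.community_inference import (
    adjust_pvalues,
    call_high_contribution,
    communities_from_attention,
    compute_thresholds,
    count_contributions,
    infer_communities,
    species_pvalue,
)
from microhgt.errors import ValidationError


def _att(values):
    """Wrap a (M, N) matrix as single-head (1, M, N) attention."""
    return np.asarray(values, dtype=float)[None, :, :]


# ---- thresholds --------------------------------------------------------------


def test_threshold_hand_example():
    att = _att(np.array([[0.1], [0.2], [0.3], [0.4]]))
    thr = compute_thresholds(att, z_alpha=1.96)
    # type-7 quartiles of (0.1..0.4): Q1=0.175, Q3=0.325; band keeps (0.2, 0.3)
    sd = np.std([0.2, 0.3], ddof=1)
    assert thr.thr[0, 0] == pytest.approx(0.25 + 1.96 * sd)
    assert sd == pytest.approx(0.0707, abs=1e-4)


def test_threshold_all_equal_values():
    att = _att(np.full((5, 1), 0.2))
    thr = compute_thresholds(att)
    assert thr.thr[0, 0] == pytest.approx(0.2)
    assert call_high_contribution(att, thr).sum() == 0


def test_threshold_z_zero_is_band_mean():
    att = _att(np.array([[0.1], [0.2], [0.3], [0.4]]))
    thr = compute_thresholds(att, z_alpha=0.0)
    assert thr.thr[0, 0] == pytest.approx(0.25)


def test_threshold_undefined_for_zero_column(caplog):
    att = _att(np.array([[0.0, 0.5], [0.0, 0.5]]))
    with caplog.at_level("WARNING", logger="microhgt.community_inference"):
        thr = compute_thresholds(att)
    assert np.isnan(thr.thr[0, 0]) and np.isfinite(thr.thr[0, 1])


# ---- calls -------------------------------------------------------------------


def test_or_rule_over_heads():
    att = np.zeros((2, 3, 1))
    att[:, :, 0] = np.array([[0.1, 0.1, 0.8], [1 / 3, 1 / 3, 1 / 3]])
    thr = compute_thresholds(att)
    contrib = call_high_contribution(att, thr)
    assert contrib[2, 0] == 1  # head 0 exceeds even though head 1 does not


def test_boundary_equality_not_called():
    att = _att(np.array([[0.25], [0.25], [0.5]]))
    thr = compute_thresholds(att, z_alpha=0.0)
    # thresholds equal band mean; species at exactly thr are not called
    contrib = call_high_contribution(att, thr)
    assert contrib[0, 0] == 0 and contrib[1, 0] == 0


def test_zero_attention_never_called():
    att = _att(np.array([[0.0], [0.4], [0.6]]))
    thr = compute_thresholds(att, z_alpha=0.0)
    assert call_high_contribution(att, thr)[0, 0] == 0


# ---- counts ------------------------------------------------------------------


def test_counts_saturation():
    contrib = np.ones((4, 5), dtype=int)
    labels = mg.encode_labels([f"p{j}" for j in range(5)], ["c"] * 5)
    r = count_contributions(contrib, labels)
    assert np.all(r.T == 5) and r.U[0] == 5
    assert r.S_max[0] == 4 and r.S_min[0] == 4


def test_counts_all_zero():
    contrib = np.zeros((3, 4), dtype=int)
    labels = mg.encode_labels([f"p{j}" for j in range(4)], ["a", "a", "b", "b"])
    r = count_contributions(contrib, labels)
    assert np.all(r.T == 0) and np.all(r.S_max == 0) and np.all(r.S_min == 0)


def test_counts_hand_case():
    contrib = np.array([
        [1, 0, 1, 1],
        [0, 0, 0, 1],
        [1, 1, 1, 0],
    ])
    labels = mg.encode_labels(["p0", "p1", "p2", "p3"], ["a", "a", "b", "b"])
    r = count_contributions(contrib, labels)
    assert np.array_equal(r.T, [[1, 0, 2], [2, 1, 1]])
    assert np.array_equal(r.U, [2, 2])
    assert np.array_equal(r.S_max, [2, 2])
    assert np.array_equal(r.S_min, [1, 2])


def test_counts_empty_class_errors():
    labels = mg.encode_labels(["p0", "p1"], ["a", "a"], classes=["a", "b"])
    with pytest.raises(ValidationError):
        count_contributions(np.zeros((2, 2), dtype=int), labels)


# ---- p-values ----------------------------------------------------------------


def _pvalue_oracle(T, U, M, S_max, S_min):
    """Direct binomial-coefficient evaluation of the tail sum."""
    total = 0.0
    for t in range(T, U + 1):
        total += comb(U, t, exact=True) * (S_max / M) ** t * ((M - S_min) / M) ** (U - t)
    return min(total, 1.0)


def test_pvalue_total_probability_one():
    assert species_pvalue(0, 7, 20, 5, 5) == pytest.approx(1.0, abs=1e-12)


def test_pvalue_single_term():
    assert species_pvalue(4, 4, 10, 3, 3) == pytest.approx(0.3 ** 4, abs=1e-12)
    assert species_pvalue(4, 4, 10, 3, 3) == pytest.approx(0.0081, abs=1e-10)


def test_pvalue_exhaustive_oracle_small_instances():
    for M in range(2, 31, 4):
        for U in range(1, 11):
            for S_min in range(1, M + 1, max(1, M // 4)):
                for S_max in range(S_min, M + 1, max(1, M // 4)):
                    for T in range(U + 1):
                        got = species_pvalue(T, U, M, S_max, S_min)
                        want = _pvalue_oracle(T, U, M, S_max, S_min)
                        assert got == pytest.approx(want, abs=1e-10), (T, U, M, S_max, S_min)


def test_pvalue_monotone_in_T():
    for U in (3, 6, 10):
        vals = [species_pvalue(t, U, 25, 8, 4) for t in range(U + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))


def test_pvalue_invalid_smin_smax():
    with pytest.raises(ValidationError):
        species_pvalue(1, 4, 10, 2, 5)


# ---- adjustment and communities ---------------------------------------------


def test_bh_all_equal():
    p = np.array([0.04, 0.04, 0.04])
    assert np.allclose(adjust_pvalues(p, "bh"), 0.04)


def test_bh_step_up_hand_case():
    assert np.allclose(adjust_pvalues(np.array([0.01, 0.02, 0.03]), "bh"), 0.03)


def test_adjust_none_identity():
    p = np.array([0.2, 0.8])
    assert np.array_equal(adjust_pvalues(p, "none"), p)


def test_adjust_unknown_method():
    with pytest.raises(ValidationError):
        adjust_pvalues(np.array([0.5]), "bonferroni-ish")


def _toy_counts():
    contrib = np.array([
        [1, 1, 0, 0],
        [1, 1, 1, 1],
        [0, 0, 0, 1],
    ])
    labels = mg.encode_labels(["p0", "p1", "p2", "p3"], ["a", "a", "b", "b"])
    return count_contributions(contrib, labels), labels


def test_cutoff_one_returns_all_candidates():
    counts, labels = _toy_counts()
    res = infer_communities(counts, labels, ["s0", "s1", "s2"], cutoff=1.0 + 1e-9, adjust="none")
    sets = res.community_sets()
    assert sets["a"] == {"s0", "s1"}
    assert sets["b"] == {"s1", "s2"}


def test_candidate_superset_property():
    counts, labels = _toy_counts()
    res = infer_communities(counts, labels, ["s0", "s1", "s2"])
    for c, name in enumerate(labels.classes):
        cand = {f"s{i}" for i in np.flatnonzero(counts.T[c] >= 1)}
        assert res.community_sets()[name] <= cand


def test_empty_community_is_valid():
    labels = mg.encode_labels(["p0", "p1"], ["a", "b"])
    counts = count_contributions(np.zeros((3, 2), dtype=int), labels)
    res = infer_communities(counts, labels, ["s0", "s1", "s2"])
    assert res.community_sets() == {"a": set(), "b": set()}


def test_planted_strong_effect_all_recovered():
    spec = mg.SyntheticSpec(M=100, N=30, C=2, community_size=6, effect=500.0,
                            sparsity=0.0, genus_size=4, seed=1)
    ds = mg.generate(spec)
    A = mg.preprocess_abundance(ds.abundance)
    # abundance as attention: with this effect size every planted species is
    # called in every sample of its class, so all of them must be returned
    res = communities_from_attention(_att(A.values), ds.labels, A.species_ids)
    for name in ds.labels.classes:
        assert ds.truth[name] <= res.community_sets()[name]


def test_null_calibration_single_seed():
    att = mg.null_attention(100, 40, 4, seed=0)
    labels = mg.encode_labels([f"p{j}" for j in range(40)], ["a"] * 20 + ["b"] * 20)
    res = communities_from_attention(att, labels, [f"s{i}" for i in range(100)], adjust="none")
    frac = np.nanmean(res.pvals < 0.05)
    assert frac <= 0.2  # loose single-seed check; the averaged bound is 0.10
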
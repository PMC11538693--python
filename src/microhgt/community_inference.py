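"""From attention to class-associated microbial communities.

Pipeline: (1) per head k and sample j, a robust outlier threshold thr_kj is
the mean + z_alpha * sd of the non-zero attention values lying within the
interquartile band [Q1, Q3]; (2) species i is a high-contribution species for
sample j when its attention exceeds thr_kj in at least one head (strict
inequality); (3) per class c, T_ci counts the class samples species i
contributes to, and an approximate binomial tail probability

    P_ci ~= sum_{t=T_ci}^{U_c} C(U_c, t) (S_max/M)^t ((M - S_min)/M)^(U_c - t)

asks whether that count exceeds chance, where S_max/S_min are the largest and
smallest per-sample contribution-set sizes within the class.  Since the two
binomial ratios use different set sizes the terms need not sum to one; the
sum is computed in log space and clamped to [0, 1] (a warning is logged when
clamping actually truncates).  Species with adjusted P below the cutoff
(default 0.05) form the class community.

Quartiles use linear interpolation (numpy default), the sd is the sample
standard deviation (n-1 denominator, 0 for a single value), and z_alpha
defaults to 1.96.  Benjamini-Hochberg adjustment within each class stands in
for p-value shrinkage; raw p-values are always reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .data_io import SampleLabels
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSet",
    "ContributionResult",
    "CommunityResult",
    "compute_thresholds",
    "call_high_contribution",
    "count_contributions",
    "species_pvalue",
    "adjust_pvalues",
    "infer_communities",
]


@dataclass
class ThresholdSet:
    thr: np.ndarray  # (h, N); NaN where undefined (no non-zero attention)
    z_alpha: float
    band_mean: np.ndarray  # (h, N)
    band_sd: np.ndarray  # (h, N)
    band_count: np.ndarray  # (h, N) number of values kept in [Q1, Q3]

    def to_frame(self, sample_ids) -> pd.DataFrame:
        h, n = self.thr.shape
        rows = [
            (k, sample_ids[j], self.band_mean[k, j], self.band_sd[k, j], self.thr[k, j])
            for k in range(h)
            for j in range(n)
        ]
        return pd.DataFrame(rows, columns=["head", "sample_id", "band_mean", "band_sd", "thr"])


@dataclass
class ContributionResult:
    contrib: np.ndarray  # (M, N) binary
    T: np.ndarray  # (C, M)
    U: np.ndarray  # (C,)
    S_max: np.ndarray  # (C,)
    S_min: np.ndarray  # (C,)


@dataclass
class CommunityResult:
    """Per-class species communities with contribution counts and p-values."""

    classes: list[str]
    species_ids: list[str]
    communities: dict  # class -> list of (species_id, T_ci, p_raw, p_adjusted)
    pvals: np.ndarray  # (C, M) raw, NaN for non-candidates
    pvals_adjusted: np.ndarray  # (C, M)
    cutoff: float

    def community_sets(self) -> dict:
        return {c: {sp for sp, *_ in rows} for c, rows in self.communities.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (c, sp, t, p, padj)
            for c in self.classes
            for sp, t, p, padj in self.communities[c]
        ]
        return pd.DataFrame(rows, columns=["class", "species_id", "T", "p_raw", "p_adjusted"])


def compute_thresholds(attention: np.ndarray, z_alpha: float = 1.96) -> ThresholdSet:
    """Per-head, per-sample outlier thresholds from the IQR band of non-zero
    attention values.

    attention: dense (h, M, N) species->sample attention (0 where no edge).
    Samples with no non-zero attention in a head get an undefined (NaN)
    threshold and are skipped for that head.
    """
    h, M, N = attention.shape
    thr = np.full((h, N), np.nan)
    bmean = np.full((h, N), np.nan)
    bsd = np.full((h, N), np.nan)
    bcount = np.zeros((h, N), dtype=np.int64)
    for k in range(h):
        for j in range(N):
            vals = attention[k, :, j]
            vals = vals[vals > 0]
            if vals.size == 0:
                logger.warning("no non-zero attention for head %d, sample %d", k, j)
                continue
            q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
            band = vals[(vals >= q1) & (vals <= q3)]
            m = band.mean()
            sd = band.std(ddof=1) if band.size > 1 else 0.0
            thr[k, j] = m + z_alpha * sd
            bmean[k, j], bsd[k, j], bcount[k, j] = m, sd, band.size
    return ThresholdSet(thr, z_alpha, bmean, bsd, bcount)


def call_high_contribution(attention: np.ndarray, thr: ThresholdSet) -> np.ndarray:
    """contrib[i, j] = 1 iff attention exceeds thr_kj strictly in any head."""
    t = thr.thr[:, None, :]  # (h, 1, N)
    with np.errstate(invalid="ignore"):
        called = (attention > t) & (attention > 0)
    return called.any(axis=0).astype(np.int8)


def count_contributions(contrib: np.ndarray, labels: SampleLabels) -> ContributionResult:
    """Per-class counts T_ci and per-class extreme contribution-set sizes."""
    contrib = np.asarray(contrib)
    M, N = contrib.shape
    if N != len(labels.sample_ids):
        raise ValidationError("contribution matrix sample count does not match labels")
    C = labels.n_classes
    cls = labels.class_indices()
    T = np.zeros((C, M), dtype=np.int64)
    U = np.zeros(C, dtype=np.int64)
    S_max = np.zeros(C, dtype=np.int64)
    S_min = np.zeros(C, dtype=np.int64)
    per_sample = contrib.sum(axis=0)
    for c in range(C):
        mask = cls == c
        if not mask.any():
            raise ValidationError(f"class {labels.classes[c]!r} has no samples")
        T[c] = contrib[:, mask].sum(axis=1)
        U[c] = int(mask.sum())
        S_max[c] = int(per_sample[mask].max())
        S_min[c] = int(per_sample[mask].min())
    return ContributionResult(contrib, T, U, S_max, S_min)


def species_pvalue(T_ci, U_c, M, S_max, S_min, clamp: bool = True):
    """Approximate binomial tail probability of observing >= T_ci contributions.

    Uses the identities C(M-1, S-1)/C(M, S) = S/M and
    C(M-1, S)/C(M, S) = (M-S)/M, evaluated in log space.  Because the success
    term uses S_max and the failure term S_min, the U_c+1 terms can sum above
    one; with ``clamp=True`` (default) the result is truncated to [0, 1].
    Vectorised over T_ci.
    """
    T_arr = np.atleast_1d(np.asarray(T_ci, dtype=np.int64))
    scalar = np.isscalar(T_ci) or np.asarray(T_ci).ndim == 0
    U_c, M, S_max, S_min = int(U_c), int(M), int(S_max), int(S_min)
    if S_min > S_max:
        raise ValidationError("S_min must be <= S_max")
    if not (0 <= S_min and S_max <= M):
        raise ValidationError("contribution-set sizes must lie in [0, M]")
    if (T_arr < 0).any() or (T_arr > U_c).any():
        raise ValidationError("T must lie in [0, U_c]")
    t = np.arange(U_c + 1)
    log_comb = gammaln(U_c + 1) - gammaln(t + 1) - gammaln(U_c - t + 1)
    with np.errstate(divide="ignore"):
        log_p = np.log(S_max / M) if S_max > 0 else -np.inf
        log_q = np.log((M - S_min) / M) if S_min < M else -np.inf
    log_terms = log_comb + np.where(t > 0, t * log_p, 0.0) + np.where(U_c - t > 0, (U_c - t) * log_q, 0.0)
    # suffix logsumexp: tail from each possible T (vectorised: shift by the
    # global max, reverse-cumulate, shift back)
    finite = np.isfinite(log_terms)
    if finite.any():
        m = log_terms[finite].max()
        suffix = np.cumsum(np.exp(log_terms - m)[::-1])[::-1]
        with np.errstate(divide="ignore"):
            tails = np.where(suffix > 0, np.log(suffix) + m, -np.inf)
    else:
        tails = np.full(U_c + 1, -np.inf)
    tails = np.append(tails, -np.inf)
    out = np.exp(tails[T_arr])
    if clamp:
        over = out > 1.0
        if over.any():
            logger.warning("clamped %d tail probabilities above 1 (S_max != S_min)",
                           int(over.sum()))
        out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def adjust_pvalues(pvals, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment of a 1-D p-value collection."""
    pvals = np.asarray(pvals, dtype=float)
    if method == "none":
        return pvals.copy()
    if method == "bh":
        if pvals.size == 0:
            return pvals.copy()
        return multipletests(pvals, method="fdr_bh")[1]
    raise ValidationError(f"unknown adjustment method {method!r}")


def infer_communities(
    counts: ContributionResult,
    labels: SampleLabels,
    species_ids: list[str],
    cutoff: float = 0.05,
    adjust: str = "bh",
) -> CommunityResult:
    """Per-class species sets with adjusted tail probability below `cutoff`.

    Candidates are species with T_ci >= 1 (high contribution to at least one
    class sample); adjustment is applied within each class over candidates.
    Output rows are sorted by adjusted then raw p-value, then by T descending.
    """
    C, M = counts.T.shape
    pvals = np.full((C, M), np.nan)
    padj = np.full((C, M), np.nan)
    communities = {}
    for c in range(C):
        cand = np.flatnonzero(counts.T[c] >= 1)
        if cand.size:
            p = species_pvalue(counts.T[c, cand], counts.U[c], M, counts.S_max[c], counts.S_min[c])
            pvals[c, cand] = p
            padj[c, cand] = adjust_pvalues(p, adjust)
        rows = [
            (species_ids[i], int(counts.T[c, i]), float(pvals[c, i]), float(padj[c, i]))
            for i in cand
            if padj[c, i] < cutoff
        ]
        rows.sort(key=lambda r: (r[3], r[2], -r[1], r[0]))
        communities[labels.classes[c]] = rows
    return CommunityResult(list(labels.classes), list(species_ids), communities, pvals, padj, cutoff)


def communities_from_attention(
    attention: np.ndarray,
    labels: SampleLabels,
    species_ids: list[str],
    z_alpha: float = 1.96,
    cutoff: float = 0.05,
    adjust: str = "bh",
) -> CommunityResult:
    """Convenience wrapper: thresholds -> calls -> counts -> communities."""
    thr = compute_thresholds(attention, z_alpha)
    contrib = call_high_contribution(attention, thr)
    counts = count_contributions(contrib, labels)
    return infer_communities(counts, labels, species_ids, cutoff, adjust)
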
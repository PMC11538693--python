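"""Evaluation statistics: subsampling reproducibility, attention-rank
distributions, 1-D Wasserstein distance, and rank-concordance R^2.

The reproducibility index RJ stresses a community-inference method under
stratified subsampling: draw K datasets keeping a fraction r of samples per
class, rerun the method on each, and average the K(K-1)/2 pairwise Jaccard
similarities of the identified per-class species sets (RJ_c per class, RJ the
mean over classes).  The harness accepts any callable, so external baselines
can be plugged in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, wasserstein_distance

from .data_io import AbundanceMatrix, SampleLabels
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ReproducibilityResult",
    "RankDistribution",
    "jaccard",
    "reproducibility_index",
    "stratified_subsample",
    "subsample_experiment",
    "attention_rank_distribution",
    "wasserstein_1d",
    "rank_fit_r2",
]


@dataclass
class ReproducibilityResult:
    r: float
    K: int
    classes: list[str]
    pairwise: dict  # class -> list of K(K-1)/2 Jaccard values
    RJ_c: np.ndarray  # per-class mean
    RJ: float
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.r, self.K, c, float(v)) for c, v in zip(self.classes, self.RJ_c)]
        rows.append((self.r, self.K, "__overall__", self.RJ))
        return pd.DataFrame(rows, columns=["r", "K", "class", "RJ_c"])


@dataclass
class RankDistribution:
    """Per-species attention ranks across the samples of one class."""

    class_label: str
    species_ids: list[str]
    ranks: np.ndarray  # (M, n_class_samples); representative rank per (species, sample)

    def for_species(self, species_id: str) -> np.ndarray:
        return self.ranks[self.species_ids.index(species_id)]


def jaccard(U1, U2) -> float:
    """|U1 n U2| / |U1 u U2|; two empty sets are defined as similarity 1."""
    U1, U2 = set(U1), set(U2)
    if not U1 and not U2:
        logger.warning("Jaccard of two empty sets defined as 1")
        return 1.0
    return len(U1 & U2) / len(U1 | U2)


def reproducibility_index(feature_sets: list[dict], r: float = float("nan"),
                          seed: int | None = None) -> ReproducibilityResult:
    """Mean pairwise Jaccard of per-class species sets across K runs.

    feature_sets: K dicts mapping class -> set of identified species; all runs
    must share the same class keys.
    """
    K = len(feature_sets)
    if K < 2:
        raise ValidationError("need at least 2 runs to measure reproducibility")
    classes = sorted(feature_sets[0])
    for fs in feature_sets:
        if sorted(fs) != classes:
            raise ValidationError("runs disagree on the class list")
    pairwise = {c: [] for c in classes}
    for a in range(K):
        for b in range(a + 1, K):
            for c in classes:
                pairwise[c].append(jaccard(feature_sets[a][c], feature_sets[b][c]))
    RJ_c = np.array([np.mean(pairwise[c]) for c in classes])
    return ReproducibilityResult(r, K, classes, pairwise, RJ_c, float(RJ_c.mean()), seed)


def stratified_subsample(labels: SampleLabels, r: float, rng: np.random.Generator) -> np.ndarray:
    """Sample indices keeping round(r * U_c) samples per class (at least 1)."""
    if not 0 < r <= 1:
        raise ValidationError("subsample fraction r must be in (0, 1]")
    cls = labels.class_indices()
    keep = []
    for c in range(labels.n_classes):
        members = np.flatnonzero(cls == c)
        n_keep = max(1, int(round(r * members.size)))
        if members.size == 0:
            raise ValidationError(f"class {labels.classes[c]!r} has no samples")
        keep.append(rng.choice(members, size=n_keep, replace=False))
    return np.sort(np.concatenate(keep))


def subsample_experiment(
    A: AbundanceMatrix,
    labels: SampleLabels,
    method,
    r: float,
    K: int = 50,
    seed: int = 0,
) -> ReproducibilityResult:
    """Run `method(A_sub, labels_sub) -> {class: species set}` on K stratified
    subsamples at fraction r and aggregate the reproducibility index."""
    if K < 2:
        raise ValidationError("K must be >= 2")
    rng = np.random.default_rng(seed)
    runs = []
    for k in range(K):
        idx = stratified_subsample(labels, r, rng)
        A_sub = AbundanceMatrix(
            list(A.species_ids), [A.sample_ids[i] for i in idx], A.values[:, idx]
        )
        sub_labels = labels.subset(idx)
        out = method(A_sub, sub_labels)
        runs.append({c: set(out.get(c, set())) for c in labels.classes})
    return reproducibility_index(runs, r=r, seed=seed)


def attention_rank_distribution(
    attention: np.ndarray,
    labels: SampleLabels,
    class_label: str,
    species_ids: list[str],
    convention: str = "best",
) -> RankDistribution:
    """Rank species by attention to each class sample; keep the best head.

    Per head and sample, rank 1 is the species with the highest attention
    (ties receive their average rank).  Across heads the representative rank
    of (species, sample) is the numerically smallest rank — the head in which
    the species matters most; ``convention="worst"`` flips to the largest.
    """
    if class_label not in labels.classes:
        raise ValidationError(f"unknown class {class_label!r}")
    if convention not in ("best", "worst"):
        raise ValidationError(f"unknown rank convention {convention!r}")
    cols = np.flatnonzero(np.array(labels.labels) == class_label)
    if cols.size == 0:
        raise ValidationError(f"class {class_label!r} has no samples")
    sub = attention[:, :, cols]  # (h, M, n_c)
    # rankdata ascending -> rank 1 = highest attention after negation
    ranks = np.stack([
        np.stack([rankdata(-sub[k, :, j], method="average") for j in range(cols.size)], axis=1)
        for k in range(sub.shape[0])
    ])  # (h, M, n_c)
    rep = ranks.min(axis=0) if convention == "best" else ranks.max(axis=0)
    return RankDistribution(class_label, list(species_ids), rep)


def wasserstein_1d(x, y) -> float:
    """Wasserstein-1 distance between two empirical distributions on R.

    Computed via the closed form (the integral of |F_x - F_y|)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("Wasserstein distance needs non-empty inputs")
    return float(wasserstein_distance(x, y))


def rank_fit_r2(x, y) -> float:
    """Goodness of fit of (x, y) points against the fixed line y = x.

    R^2 = 1 - sum (y_i - x_i)^2 / sum (y_i - mean(y))^2; can be negative."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("rank vectors must have equal length >= 2")
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValidationError("zero variance in y")
    return float(1.0 - ((y - x) ** 2).sum() / ss_tot)
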
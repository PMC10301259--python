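"""Multiclass ReliefF feature ranking.

ReliefF scores each feature by how well it separates an instance from
its nearest neighbours of other classes ("misses") relative to its
nearest neighbours of the same class ("hits").  For every instance, the
k nearest hits and, per other class, the k nearest misses are found
under a Manhattan distance on range-normalised features; the weight
update penalises hit differences and rewards prior-weighted miss
differences.  All instances are used (no subsampling).

Weights are invariant to affine rescaling of any feature, because
per-feature differences are divided by the observed feature range.
A constant feature has zero range and contributes zero everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import OUTCOME_COLUMN


@dataclass
class RelieffRanking:
    """Features ordered by non-increasing ReliefF weight.

    Ties are broken by the features' input order, so a ranking is a
    deterministic function of the table.
    """

    ranking: list[tuple[str, float]]
    k_neighbors: int

    def __post_init__(self) -> None:
        weights = [w for _, w in self.ranking]
        if any(a < b for a, b in zip(weights, weights[1:])):
            raise ValueError("ranking weights must be non-increasing")
        names = [f for f, _ in self.ranking]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature in ranking")

    @property
    def features(self) -> list[str]:
        return [f for f, _ in self.ranking]

    def weight(self, feature: str) -> float:
        for f, w in self.ranking:
            if f == feature:
                return w
        raise KeyError(feature)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranking, columns=["feature", "weight"])


def split_features_labels(table: pd.DataFrame,
                          features: list[str] | None = None):
    """Feature matrix and label array from a labelled table."""
    if OUTCOME_COLUMN not in table.columns:
        raise ValueError(f"table has no {OUTCOME_COLUMN!r} column")
    if features is None:
        features = [c for c in table.columns if c != OUTCOME_COLUMN]
    X = table[features].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains missing or non-finite values")
    y = table[OUTCOME_COLUMN].to_numpy()
    return X, y, list(features)


def relieff_weights(X: np.ndarray, y: np.ndarray, k_neighbors: int = 10) -> np.ndarray:
    """Raw ReliefF weights for the columns of X (labels y)."""
    n, p = X.shape
    if n <= k_neighbors:
        raise ValueError(f"need more instances ({n}) than neighbours ({k_neighbors})")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    if np.any(counts <= k_neighbors):
        small = classes[counts <= k_neighbors]
        warnings.warn(
            f"k_neighbors={k_neighbors} >= size of class(es) {list(small)}; "
            "neighbour counts truncated to the available instances",
            stacklevel=2,
        )

    rng_range = X.max(axis=0) - X.min(axis=0)
    scale = np.where(rng_range > 0, rng_range, 1.0)  # constant feature -> diff 0
    Xn = (X - X.min(axis=0)) / scale
    Xn[:, rng_range == 0] = 0.0

    idx_by_class = {c: np.flatnonzero(y == c) for c in classes}
    W = np.zeros(p)
    for i in range(n):
        ci = y[i]
        diffs = np.abs(Xn - Xn[i])       # (n, p) normalised differences
        dist = diffs.sum(axis=1)
        # hits: k nearest same-class, excluding self
        hit_pool = idx_by_class[ci][idx_by_class[ci] != i]
        k_hit = min(k_neighbors, len(hit_pool))
        if k_hit > 0:
            order = hit_pool[np.argsort(dist[hit_pool], kind="stable")][:k_hit]
            W -= diffs[order].sum(axis=0) / (n * k_hit)
        # misses: per other class, k nearest, prior-weighted
        for c in classes:
            if c == ci:
                continue
            pool = idx_by_class[c]
            k_miss = min(k_neighbors, len(pool))
            order = pool[np.argsort(dist[pool], kind="stable")][:k_miss]
            w_c = priors[c] / (1.0 - priors[ci])
            W += w_c * diffs[order].sum(axis=0) / (n * k_miss)
    return W


def relieff_rank(table: pd.DataFrame, k_neighbors: int = 10,
                 features: list[str] | None = None) -> RelieffRanking:
    """Rank a labelled table's features by ReliefF weight.

    Ties in weight are broken by input column order (stable sort), so
    the ordering is reproducible.
    """
    X, y, features = split_features_labels(table, features)
    W = relieff_weights(X, y, k_neighbors=k_neighbors)
    order = sorted(range(len(features)), key=lambda j: (-W[j], j))
    return RelieffRanking(
        ranking=[(features[j], float(W[j])) for j in order],
        k_neighbors=k_neighbors,
    )


def select_top_fraction(ranking: RelieffRanking, fraction: float) -> list[str]:
    """Highest-weight features: round(fraction * p) with half rounded up."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    p = len(ranking.ranking)
    n_sel = int(np.floor(fraction * p + 0.5))
    n_sel = max(1, n_sel)
    return ranking.features[:n_sel]
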
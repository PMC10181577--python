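"""ReliefF feature weighting and ranking.

ReliefF scores a feature by how well it separates each instance from its
nearest neighbours of other classes ("misses") while agreeing with its
nearest same-class neighbours ("hits").  For every instance, the k nearest
hits and, for each other class, the k nearest misses are found (Manhattan
distance on range-normalised features, all instances used, no sampling —
the result is deterministic).  Weights accumulate range-normalised feature
differences, miss contributions weighted by the class prior renormalised
over the classes the instance does not belong to:

    W[f] += sum_C  P(C) / (1 - P(class(x))) * mean_miss diff_f
          - mean_hit diff_f                       (averaged over instances)

The binary Relief algorithm does not extend to the five-class task, hence
the multiclass ReliefF generalisation with k = 10 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ReliefResult", "relieff_weights"]


@dataclass
class ReliefResult:
    """Per-feature ReliefF weights plus the descending-weight ranking."""

    weights: dict[str, float]
    ranking: list[str]
    k_neighbors: int
    n_sampled: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.ranking,
                "weight": [self.weights[f] for f in self.ranking],
                "rank": np.arange(1, len(self.ranking) + 1),
            }
        )


def relieff_weights(features, labels, k_neighbors: int = 10) -> ReliefResult:
    """Multiclass ReliefF weights over all instances.

    Parameters
    ----------
    features : DataFrame or (n, p) array
        Finite feature table; column names become feature names.
    labels : sequence of length n
        Class label per row; every class needs more than ``k_neighbors``
        members so the hit neighbourhood is well defined.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite entries")
    y = np.asarray([getattr(v, "value", v) for v in labels])
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("labels and features have mismatched lengths")

    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts <= k_neighbors):
        small = classes[counts <= k_neighbors]
        raise ValueError(
            f"classes {list(small)} have <= {k_neighbors} members; "
            "use a smaller k_neighbors"
        )
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}

    rng = X.max(axis=0) - X.min(axis=0)
    scale = np.where(rng > 0, rng, 1.0)
    Z = (X - X.min(axis=0)) / scale
    Z[:, rng == 0] = 0.0

    weights = np.zeros(p)
    for i in range(n):
        diffs = np.abs(Z - Z[i])  # (n, p) range-normalised differences
        dist = diffs.sum(axis=1)
        same = y == y[i]
        hit_idx = np.where(same)[0]
        hit_idx = hit_idx[hit_idx != i]
        hits = hit_idx[np.argsort(dist[hit_idx], kind="stable")[:k_neighbors]]
        weights -= diffs[hits].mean(axis=0)
        other_prior = 1.0 - priors[y[i]]
        for c in classes:
            if c == y[i]:
                continue
            miss_idx = np.where(y == c)[0]
            misses = miss_idx[np.argsort(dist[miss_idx], kind="stable")[:k_neighbors]]
            weights += priors[c] / other_prior * diffs[misses].mean(axis=0)
    weights /= n

    wdict = {name: float(w) for name, w in zip(names, weights)}
    order = np.argsort(-weights, kind="stable")
    ranking = [names[j] for j in order]
    return ReliefResult(wdict, ranking, k_neighbors, n)
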
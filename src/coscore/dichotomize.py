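"""Dichotomize one feature's expression into UP/DOWN groups by 2-means.

The split is the globally optimal two-cluster partition under within-cluster
sum of squares.  In one dimension the optimal 2-means partition is always a
threshold partition of the sorted values, so it is found exactly by scanning
the n−1 possible split points — no random initialization, no seed dependence.
The cluster with the higher median expression is labelled UP, the other DOWN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, TieError

UP = "UP"
DOWN = "DOWN"


@dataclass(frozen=True)
class DichotomyResult:
    """Per-sample UP/DOWN labels for one feature.

    ``labels`` is aligned with the input value order.  ``threshold`` is the
    midpoint between the largest DOWN value and the smallest UP value; every
    sample strictly below it is DOWN, every sample above it is UP.
    """

    feature_id: str
    labels: np.ndarray
    median_up: float
    median_down: float
    threshold: float
    n_up: int
    n_down: int

    @property
    def is_up(self) -> np.ndarray:
        return self.labels == UP


def assign_up_down(cluster_a: np.ndarray, cluster_b: np.ndarray) -> tuple[str, str]:
    """Label two clusters by median expression.

    Returns the pair of labels ``(label_a, label_b)``.  The cluster with the
    strictly higher median becomes UP.  Equal medians leave the labels
    undefined and raise :class:`TieError`; callers skip such features.
    """
    cluster_a = np.asarray(cluster_a, dtype=float)
    cluster_b = np.asarray(cluster_b, dtype=float)
    if cluster_a.size == 0 or cluster_b.size == 0:
        raise DegenerateInputError("both clusters must be non-empty")
    med_a = float(np.median(cluster_a))
    med_b = float(np.median(cluster_b))
    if med_a == med_b:
        raise TieError(f"cluster medians are equal ({med_a}); UP/DOWN undefined")
    return (UP, DOWN) if med_a > med_b else (DOWN, UP)


def kmeans_dichotomize(
    values,
    feature_id: str = "",
    min_cluster_size: int = 1,
    seed=None,
) -> DichotomyResult:
    """Exact 1-D 2-means split of ``values`` into UP/DOWN groups.

    Candidate splits lie only between distinct sorted values, so equal values
    always share a cluster (as any distance-based assignment requires) and the
    partition is a strict threshold partition.  Within-SS ties between splits
    are broken toward the split with the larger DOWN (lower) cluster.

    ``seed`` is accepted for interface compatibility and ignored: the exact
    solution has no random component.

    Raises :class:`DegenerateInputError` for constant vectors, fewer than two
    samples, or when no split satisfies ``min_cluster_size``.
    """
    del seed
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise DegenerateInputError("expected a 1-D vector of expression values")
    if x.size < 2:
        raise DegenerateInputError(f"feature {feature_id!r}: need >= 2 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise DegenerateInputError(f"feature {feature_id!r}: non-finite expression values")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = x.size
    if xs[0] == xs[-1]:
        raise DegenerateInputError(f"feature {feature_id!r}: constant expression vector")

    # Prefix sums give within-SS of any threshold split in O(1):
    # SS(group) = sum(x^2) - (sum x)^2 / size.
    cs = np.concatenate(([0.0], np.cumsum(xs)))
    cs2 = np.concatenate(([0.0], np.cumsum(xs**2)))
    total, total2 = cs[-1], cs2[-1]

    splits = np.flatnonzero(xs[:-1] < xs[1:]) + 1  # DOWN gets xs[:i], UP gets xs[i:]
    if min_cluster_size > 1:
        splits = splits[(splits >= min_cluster_size) & (n - splits >= min_cluster_size)]
    if splits.size == 0:
        raise DegenerateInputError(
            f"feature {feature_id!r}: no admissible split with clusters of size >= {min_cluster_size}"
        )

    ss_low = cs2[splits] - cs[splits] ** 2 / splits
    hi_n = n - splits
    ss_high = (total2 - cs2[splits]) - (total - cs[splits]) ** 2 / hi_n
    ss = ss_low + ss_high
    # argmin of reversed array -> last (largest-DOWN) split among ties
    best = splits[ss.size - 1 - np.argmin(ss[::-1])]

    low_vals, high_vals = xs[:best], xs[best:]
    label_low, label_high = assign_up_down(low_vals, high_vals)
    threshold = float((xs[best - 1] + xs[best]) / 2.0)

    labels = np.empty(n, dtype=object)
    labels[order[:best]] = label_low
    labels[order[best:]] = label_high
    up_vals = low_vals if label_low == UP else high_vals
    down_vals = high_vals if label_low == UP else low_vals
    return DichotomyResult(
        feature_id=feature_id,
        labels=labels.astype("U4"),
        median_up=float(np.median(up_vals)),
        median_down=float(np.median(down_vals)),
        threshold=threshold,
        n_up=int(up_vals.size),
        n_down=int(down_vals.size),
    )
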
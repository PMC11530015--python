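"""ClusterCentroids undersampling of the majority category.

The majority category's feature vectors are replaced by k cluster centroids
computed with mini-batch k-means, where k is the target post-sampling count
(``max(1, round(ratio * N))``).  The centroids act as synthetic prototypes
carrying the majority category's label; every other category passes through
untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("premls")

DEFAULT_BATCH_SIZE = 1024
DEFAULT_MAX_ITER = 100


@dataclass
class SampleSet:
    """Paired feature vectors, one-hot label vectors and category ids."""

    features: np.ndarray  # (n, d)
    labels: np.ndarray  # (n, 4) binary
    categories: np.ndarray  # (n,) int

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.categories = np.asarray(self.categories, dtype=int)
        n = len(self.features)
        if len(self.labels) != n or len(self.categories) != n:
            raise ValueError("features, labels and categories must have equal length")

    def __len__(self) -> int:
        return len(self.features)

    def subset(self, idx) -> "SampleSet":
        return SampleSet(self.features[idx], self.labels[idx], self.categories[idx])


@dataclass
class KMeansResult:
    centroids: np.ndarray  # (k, d)
    assignments: np.ndarray  # (n,) cluster index per input point
    iterations_run: int
    distortion: float  # sum of squared distances to assigned centroids


def _assign(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # squared Euclidean distances without materializing the full outer square
    d2 = (
        np.sum(points ** 2, axis=1)[:, None]
        - 2.0 * points @ centroids.T
        + np.sum(centroids ** 2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def minibatch_kmeans(
    points: np.ndarray,
    k: int,
    batch_size: int = DEFAULT_BATCH_SIZE,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
) -> KMeansResult:
    """Mini-batch k-means clustering.

    Initial centers are k distinct data points drawn at random.  Each
    iteration samples ``batch_size`` points without replacement (capped at
    n), assigns them to the nearest centroid by Euclidean distance, and
    resets every touched centroid to the mean of its assigned batch members.
    With ``batch_size >= n`` each iteration is exactly one Lloyd step.

    A cluster left empty under the final full-data assignment is re-seeded
    to a random data point.  Deterministic given ``seed``.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if batch_size < 1 or max_iter < 1:
        raise ValueError("batch_size and max_iter must be >= 1")
    rng = np.random.default_rng(seed)

    if k == n:  # degenerate pass-through: each point its own centroid
        return KMeansResult(points.copy(), np.arange(n), 0, 0.0)

    centroids = points[rng.choice(n, size=k, replace=False)].copy()
    b = min(batch_size, n)
    for t in range(max_iter):
        batch = points[rng.choice(n, size=b, replace=False)]
        labels = _assign(batch, centroids)
        for j in np.unique(labels):
            centroids[j] = batch[labels == j].mean(axis=0)

    assignments = _assign(points, centroids)
    empty = np.setdiff1d(np.arange(k), np.unique(assignments))
    if len(empty) > 0:
        centroids[empty] = points[rng.choice(n, size=len(empty), replace=False)]
        assignments = _assign(points, centroids)
        logger.info("minibatch_kmeans: re-seeded %d empty cluster(s)", len(empty))

    distortion = float(
        np.sum((points - centroids[assignments]) ** 2)
    )
    return KMeansResult(centroids, assignments, max_iter, distortion)


def undersample_count(n_majority: int, ratio: float) -> int:
    """Post-sampling majority count: round-half-up with a floor of 1."""
    return max(1, int(np.floor(ratio * n_majority + 0.5)))


def cluster_centroids_undersample(
    data: SampleSet,
    majority_category: int,
    ratio: float,
    seed: int = 0,
    batch_size: int = DEFAULT_BATCH_SIZE,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SampleSet:
    """Replace the majority category's samples with k-means centroids.

    ``ratio`` is the post-sampling count divided by the original count, in
    (0, 1].  Ratio 1 is the identity.  Output order: non-majority samples in
    their original order, then the centroids.
    """
    if not 0 < ratio <= 1:
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    mask = data.categories == majority_category
    n_maj = int(mask.sum())
    if n_maj == 0:
        raise ValueError(f"category {majority_category} not present")
    if ratio == 1:
        return data.subset(np.arange(len(data)))

    k = undersample_count(n_maj, ratio)
    result = minibatch_kmeans(
        data.features[mask], k, batch_size=batch_size, max_iter=max_iter, seed=seed
    )
    logger.info(
        "cluster_centroids_undersample: category %d %d -> %d centroids "
        "(%d iterations, distortion %.4g)",
        majority_category, n_maj, k, result.iterations_run, result.distortion,
    )
    maj_label = data.labels[mask][0]
    rest = data.subset(~mask)
    return SampleSet(
        np.vstack([rest.features, result.centroids]),
        np.vstack([rest.labels, np.tile(maj_label, (k, 1))]),
        np.concatenate([rest.categories, np.full(k, majority_category)]),
    )


def majority_category(data: SampleSet) -> int:
    """Category id with the largest sample count (smallest id wins ties)."""
    cats, counts = np.unique(data.categories, return_counts=True)
    return int(cats[np.argmax(counts)])
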
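"""Unsupervised multispectral classification with separability-driven merging.

Each in-mask pixel is a 3-vector of preprocessed channel values
(FAF, IR 815 nm, green 532 nm). Pixels are clustered into *spectral theme
classes* by Lloyd's k-means starting from k = 16; after each fit, pairwise
class separability is measured by the transformed divergence

    D    = 1/2 tr[(Σa − Σb)(Σb⁻¹ − Σa⁻¹)]
         + 1/2 tr[(Σa⁻¹ + Σb⁻¹)(μa − μb)(μa − μb)ᵀ]
    D_T  = 2 (1 − exp(−D / 8)),   0 ≤ D_T ≤ 2,

the bounded divergence statistic of Gaussian class models standard in
remote-sensing classification. If any class pair falls below the
separability criterion (D_T ≥ 1.5 by default, associated in the remote
sensing literature with > 83% probability of correct pairwise
classification), the two least-separable classes are merged into their
pixel-count-weighted mean and k-means is re-run at k − 1 seeded from the
merged centroid set. The loop terminates when every pair meets the
criterion or k reaches the floor (2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist

from ._streams import stream
from .errors import NumericError, ValidationError

__all__ = [
    "ClusteringConfig",
    "ClassStatistics",
    "ThemeMap",
    "MultispectralStack",
    "kmeans_fit",
    "class_statistics",
    "transformed_divergence",
    "merge_least_separable",
    "cluster_with_separability",
]

_COV_EPS = 1e-6  # ridge added to covariances; 8-bit quantization can make
# within-class covariance exactly singular


@dataclass(frozen=True)
class ClusteringConfig:
    """Parameters of the classification loop.

    k_init
        Maximum (starting) number of theme classes; default 16.
    td_min
        Transformed-divergence criterion every class pair must meet;
        default 1.5.
    min_threshold
        k-means convergence threshold: the fit stops when the fraction of
        pixels changing assignment in one Lloyd iteration drops below this
        (default 0.01).
    min_class_fraction
        Optional post-fit filter dissolving classes smaller than this
        fraction of in-mask pixels into their nearest neighbours; default 0
        (off). This is an alternative reading of a "minimum threshold" in
        clustering tools, exposed but not the default interpretation.
    """

    k_init: int = 16
    td_min: float = 1.5
    min_threshold: float = 0.01
    k_floor: int = 2
    max_iter: int = 100
    seed: int = 0
    min_class_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 2 <= self.k_floor <= self.k_init:
            raise ValidationError("need 2 <= k_floor <= k_init")
        if not 0 < self.td_min <= 2:
            raise ValidationError("td_min must be in (0, 2]")
        if not 0 <= self.min_threshold < 1:
            raise ValidationError("min_threshold must be in [0, 1)")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")


@dataclass(frozen=True)
class ClassStatistics:
    """Gaussian model of one spectral theme class."""

    class_id: int
    mean: np.ndarray  # (3,) channel means
    covariance: np.ndarray  # (3, 3), ridge-regularized SPD
    pixel_count: int
    small_sample: bool = False  # < 4 pixels: covariance fell back to diagonal


@dataclass
class MultispectralStack:
    """Aligned, preprocessed channel rasters for one eye-visit.

    ``channels`` is (rows, cols, 3) ordered (FAF, IR, green); ``mask`` is the
    boolean macular mask on the same grid.
    """

    channels: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if ch.ndim != 3 or ch.shape[2] != 3:
            raise ValidationError("channels must have shape (rows, cols, 3)")
        if m.shape != ch.shape[:2]:
            raise ValidationError("mask shape must match channel grid")
        if not m.any():
            raise ValidationError("macular mask is empty")
        self.channels = ch
        self.mask = m

    @property
    def pixels(self) -> np.ndarray:
        """In-mask pixel feature matrix, (n, 3), row-major pixel order."""
        return self.channels[self.mask]


@dataclass
class ThemeMap:
    """Per-pixel theme-class labels plus per-class Gaussian statistics.

    ``labels`` covers the full grid with −1 outside the macular mask; every
    in-mask pixel carries exactly one class id from ``classes``.
    ``exit_condition`` records how the separability loop terminated:
    ``"separable"`` (all pairs met the criterion) or ``"k_floor"``.
    """

    labels: np.ndarray
    classes: list[ClassStatistics]
    mask: np.ndarray
    pairwise_td: np.ndarray | None = None
    k_trajectory: list[int] = field(default_factory=list)
    exit_condition: str = ""

    @property
    def k(self) -> int:
        return len(self.classes)

    @property
    def class_ids(self) -> list[int]:
        return [c.class_id for c in self.classes]

    def pixel_count(self, class_id: int) -> int:
        for c in self.classes:
            if c.class_id == class_id:
                return c.pixel_count
        raise ValidationError(f"unknown class id {class_id}")

    def min_pairwise_td(self) -> float:
        if self.pairwise_td is None or self.k < 2:
            return float("inf")
        iu = np.triu_indices(self.k, k=1)
        return float(self.pairwise_td[iu].min())


def _farthest_point_init(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic k-means++-style seeding: a seeded first centroid, then
    repeatedly the point farthest from the chosen set."""
    rng = stream(seed, "kmeans-init")
    n = X.shape[0]
    centroids = [X[int(rng.integers(n))]]
    d2 = np.sum((X - centroids[0]) ** 2, axis=1)
    for _ in range(1, k):
        idx = int(np.argmax(d2))
        centroids.append(X[idx])
        d2 = np.minimum(d2, np.sum((X - centroids[-1]) ** 2, axis=1))
    return np.asarray(centroids, dtype=float)


def kmeans_fit(
    stack: MultispectralStack,
    k: int,
    init_centroids: np.ndarray | None = None,
    config: ClusteringConfig | None = None,
) -> ThemeMap:
    """Lloyd's algorithm on the in-mask pixels.

    Converges when the fraction of pixels changing assignment in one
    iteration drops below ``config.min_threshold`` (or at ``max_iter``).
    Empty clusters are dropped. The within-cluster SSE is checked to be
    non-increasing across iterations; a violation raises NumericError.
    """
    config = config or ClusteringConfig()
    X = stack.pixels
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValidationError(f"k={k} out of range for {n} in-mask pixels")

    if init_centroids is None:
        centroids = _farthest_point_init(X, k, config.seed)
    else:
        centroids = np.asarray(init_centroids, dtype=float)
        if centroids.ndim != 2 or centroids.shape != (k, X.shape[1]):
            raise ValidationError("init_centroids must have shape (k, 3)")

    labels = np.full(n, -1, dtype=np.int32)
    prev_sse = np.inf
    for _ in range(config.max_iter):
        d2 = cdist(X, centroids, metric="sqeuclidean")
        new_labels = np.argmin(d2, axis=1).astype(np.int32)
        sse = float(d2[np.arange(n), new_labels].sum())
        if sse > prev_sse + 1e-9 * max(1.0, prev_sse):
            raise NumericError("within-cluster SSE increased during Lloyd iteration")
        prev_sse = sse
        changed = float(np.mean(new_labels != labels))
        labels = new_labels
        # drop empty clusters before the update step
        occupied = np.unique(labels)
        if occupied.size < centroids.shape[0]:
            remap = {int(old): i for i, old in enumerate(occupied)}
            labels = np.vectorize(remap.get, otypes=[np.int32])(labels)
            centroids = centroids[occupied]
        for j in range(centroids.shape[0]):
            centroids[j] = X[labels == j].mean(axis=0)
        if changed < config.min_threshold:
            break

    if config.min_class_fraction > 0:
        labels, centroids = _dissolve_small_classes(
            X, labels, centroids, config.min_class_fraction
        )

    full = np.full(stack.mask.shape, -1, dtype=np.int32)
    full[stack.mask] = labels
    classes = class_statistics(stack, full)
    return ThemeMap(labels=full, classes=classes, mask=stack.mask)


def _dissolve_small_classes(
    X: np.ndarray, labels: np.ndarray, centroids: np.ndarray, min_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Optional post-fit filter: reassign members of classes smaller than
    ``min_fraction`` of the pixels to the nearest surviving centroid."""
    n = X.shape[0]
    while centroids.shape[0] > 1:
        counts = np.bincount(labels, minlength=centroids.shape[0])
        small = np.flatnonzero(counts < min_fraction * n)
        if small.size == 0:
            break
        victim = int(small[np.argmin(counts[small])])
        keep = np.array([j for j in range(centroids.shape[0]) if j != victim])
        centroids = centroids[keep]
        d2 = cdist(X, centroids, metric="sqeuclidean")
        labels = np.argmin(d2, axis=1).astype(np.int32)
    return labels, centroids


def class_statistics(stack: MultispectralStack, labels: np.ndarray) -> list[ClassStatistics]:
    """Per-class channel mean and (ridge-regularized) covariance.

    Classes with fewer than 4 pixels are flagged and fall back to a
    regularized diagonal covariance.
    """
    X = stack.pixels
    lab = np.asarray(labels)[stack.mask]
    if np.any(lab < 0):
        raise ValidationError("labels must cover all in-mask pixels")
    out: list[ClassStatistics] = []
    for cid in np.unique(lab):
        members = X[lab == cid]
        count = members.shape[0]
        mean = members.mean(axis=0)
        if count < 4:
            var = members.var(axis=0) if count > 1 else np.zeros(X.shape[1])
            cov = np.diag(var) + _COV_EPS * np.eye(X.shape[1])
            small = True
        else:
            cov = np.cov(members, rowvar=False) + _COV_EPS * np.eye(X.shape[1])
            small = False
        out.append(
            ClassStatistics(
                class_id=int(cid),
                mean=mean,
                covariance=cov,
                pixel_count=int(count),
                small_sample=small,
            )
        )
    return out


def transformed_divergence(a: ClassStatistics, b: ClassStatistics) -> float:
    """Bounded [0, 2] separability of two Gaussian class models (symmetric)."""
    try:
        ia = np.linalg.inv(a.covariance)
        ib = np.linalg.inv(b.covariance)
    except np.linalg.LinAlgError as exc:
        raise NumericError(
            f"singular covariance for classes {a.class_id}/{b.class_id}"
        ) from exc
    dm = np.asarray(a.mean, float) - np.asarray(b.mean, float)
    dc = a.covariance - b.covariance
    D = 0.5 * np.trace(dc @ (ib - ia)) + 0.5 * float(dm @ (ia + ib) @ dm)
    D = max(float(D), 0.0)  # guard tiny negative round-off
    return float(2.0 * (1.0 - np.exp(-D / 8.0)))


def _pairwise_td(classes: list[ClassStatistics]) -> np.ndarray:
    k = len(classes)
    td = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        td[i, j] = td[j, i] = transformed_divergence(classes[i], classes[j])
    return td


def merge_least_separable(theme_map: ThemeMap) -> tuple[tuple[int, int], np.ndarray] | None:
    """Select the least-separable class pair and build k−1 init centroids.

    Returns ``((id_i, id_j), centroids)`` where the pair is replaced by its
    pixel-count-weighted mean and all other class means carry over, or None
    when only one class remains. Exact ties break to the lexicographically
    smallest (id_i, id_j).
    """
    if theme_map.k < 2:
        return None
    td = theme_map.pairwise_td if theme_map.pairwise_td is not None else _pairwise_td(
        theme_map.classes
    )
    classes = theme_map.classes
    best: tuple[int, int] | None = None
    best_td = np.inf
    for i, j in combinations(range(len(classes)), 2):
        pair = (classes[i].class_id, classes[j].class_id)
        if td[i, j] < best_td - 1e-15 or (
            abs(td[i, j] - best_td) <= 1e-15 and (best is None or pair < best)
        ):
            best_td = td[i, j]
            best = pair
            bi, bj = i, j
    assert best is not None
    wi, wj = classes[bi].pixel_count, classes[bj].pixel_count
    merged = (wi * classes[bi].mean + wj * classes[bj].mean) / (wi + wj)
    centroids = [merged] + [
        c.mean for idx, c in enumerate(classes) if idx not in (bi, bj)
    ]
    return best, np.asarray(centroids, dtype=float)


def cluster_with_separability(
    stack: MultispectralStack, config: ClusteringConfig | None = None
) -> ThemeMap:
    """Full classification loop: k-means, divergence check, merge, repeat.

    The returned ThemeMap carries the pairwise D_T matrix, the k trajectory
    across merges, and which exit condition fired (all pairs separable vs
    k floor reached). k strictly decreases across merges, so the loop runs
    at most ``k_init − k_floor`` times.
    """
    config = config or ClusteringConfig()
    n = stack.pixels.shape[0]
    k = min(config.k_init, n)
    theme_map = kmeans_fit(stack, k, config=config)
    trajectory = [theme_map.k]
    while True:
        theme_map.pairwise_td = _pairwise_td(theme_map.classes)
        # separability is checked first, so when both conditions hold at the
        # floor the recorded exit is the one that actually stopped the loop
        if theme_map.min_pairwise_td() >= config.td_min:
            theme_map.exit_condition = "separable"
            break
        if theme_map.k <= config.k_floor:
            theme_map.exit_condition = "k_floor"
            break
        step = merge_least_separable(theme_map)
        if step is None:  # single class: nothing left to merge
            theme_map.exit_condition = "k_floor"
            break
        _, centroids = step
        theme_map = kmeans_fit(
            stack, centroids.shape[0], init_centroids=centroids, config=config
        )
        trajectory.append(theme_map.k)
    theme_map.k_trajectory = trajectory
    return theme_map
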
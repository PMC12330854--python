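"""Grouping of event activation maps.

Selected-event ``dR2*`` maps are grouped with k-means under the squared
Euclidean objective; the number of clusters is chosen by consensus
clustering (repeated k-means on 80% subsamples, k = 2..15, 100 iterations
per k), and each cluster is summarised by a spatially Z-normalised mean map,
sign-flipped so that positive values mean positive BOLD, and binarised at
Z >= 3.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "ActivationMapStack",
    "ConsensusReport",
    "ClusterZMaps",
    "consensus_select_k",
    "kmeans_maps",
    "cluster_zmaps",
]


@dataclass
class ActivationMapStack:
    """N event maps over a shared voxel index space (N x V)."""

    maps: np.ndarray
    provenance: list | None = None  # (run, timepoint) per map

    def __post_init__(self):
        self.maps = np.asarray(self.maps, float)
        if self.maps.ndim != 2:
            raise ValueError("stack must be 2D (maps x voxels)")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @classmethod
    def from_event_maps(cls, maps_4d: np.ndarray, mask: np.ndarray, provenance=None):
        """Flatten (N,) + grid maps to N x V using a voxel mask."""
        m = np.asarray(mask, bool)
        return cls(maps=np.stack([vol[m] for vol in maps_4d]), provenance=provenance)


@dataclass
class ConsensusReport:
    consensus: dict               # k -> mean co-clustering proportion
    chosen_k: int
    skipped: list = field(default_factory=list)


@dataclass
class ClusterZMaps:
    mean_maps: np.ndarray         # (k, V)
    z_maps: np.ndarray            # spatially normalised
    flipped_z: np.ndarray         # x -1 (positive = positive BOLD)
    binary_maps: np.ndarray       # flipped Z >= threshold
    threshold: float


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [X[rng.integers(len(X))]]
    for _ in range(1, k):
        d2 = cdist(X, np.asarray(centers)).min(axis=1) ** 2
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(len(X))])
            continue
        centers.append(X[rng.choice(len(X), p=d2 / total)])
    return np.asarray(centers)


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100) -> np.ndarray:
    """Single-restart Lloyd k-means (squared Euclidean); returns labels.

    Used inside the consensus subsampling loop where many thousands of small
    fits are needed; the definitive clustering (:func:`kmeans_maps`) uses
    scikit-learn's k-means with restarts, against which this routine is
    cross-checked in the test suite.
    """
    centers = _kmeanspp_init(X, k, rng)
    labels = np.full(len(X), -1)
    for _ in range(max_iter):
        new = cdist(X, centers).argmin(axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
        for j in range(k):
            pts = X[labels == j]
            centers[j] = pts.mean(axis=0) if len(pts) else X[rng.integers(len(X))]
    return labels


def consensus_select_k(
    stack: ActivationMapStack,
    k_range=range(2, 16),
    subsample: float = 0.8,
    iters: int = 100,
    seed: int | None = 0,
) -> ConsensusReport:
    """Choose k by consensus over k-means on random 80% subsamples.

    For each k, ``iters`` k-means runs on ``ceil(subsample*N)``-map subsamples
    accumulate a consensus matrix: the proportion of co-sampled runs in which
    each pair of maps was assigned to the same cluster.  The consensus value
    of k is the average of those pairwise proportions within the clusters of
    a reference partition at that k (the average proportion of times the
    pairs that end up clustered together were indeed assigned together).  A
    stable k keeps this near 1; at the wrong k the subsampled runs disagree
    on how to merge or split the groups and the value drops.  The chosen k
    attains the maximum consensus (ties go to the smaller k); k values with
    too few maps are skipped and logged.

    The maps are first projected onto their principal axes (an isometry for
    pairwise Euclidean distances), which makes the many small k-means fits
    cheap without changing the objective.
    """
    X = stack.maps
    N = X.shape[0]
    n_sub = int(np.ceil(subsample * N))
    rng = np.random.default_rng(seed)
    # distance-preserving rotation: at most N nontrivial principal axes
    Xc = X - X.mean(axis=0)
    if X.shape[1] > N:
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        Xr = Xc @ Vt.T
    else:
        Xr = Xc
    consensus, skipped = {}, []
    for k in k_range:
        if n_sub <= k or N <= k:
            skipped.append(k)
            logger.info("consensus: skipping k=%d (only %d maps)", k, N)
            continue
        together = np.zeros((N, N))
        co_sampled = np.zeros((N, N))
        for _ in range(iters):
            idx = rng.choice(N, size=n_sub, replace=False)
            labels = _lloyd(Xr[idx], k, rng)
            co_sampled[np.ix_(idx, idx)] += 1
            same = labels[:, None] == labels[None, :]
            together[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            p = np.where(co_sampled > 0, together / np.maximum(co_sampled, 1), 0.0)
        # reference partition at this k (best of a few restarts)
        ref = min(
            (_lloyd(Xr, k, np.random.default_rng(rng.integers(2**31))) for _ in range(5)),
            key=lambda lab: _inertia(Xr, lab),
        )
        cluster_means = []
        for j in np.unique(ref):
            members = np.flatnonzero(ref == j)
            if len(members) < 2:
                continue
            sub_p = p[np.ix_(members, members)]
            sub_n = co_sampled[np.ix_(members, members)]
            iu = np.triu_indices(len(members), k=1)
            valid = sub_n[iu] > 0
            if valid.any():
                cluster_means.append(float(sub_p[iu][valid].mean()))
        if cluster_means:
            consensus[k] = float(np.mean(cluster_means))
    if not consensus:
        raise ValueError("no k in range could be evaluated")
    best = max(consensus.values())
    chosen = min(k for k, v in consensus.items() if v == best)
    return ConsensusReport(consensus=consensus, chosen_k=chosen, skipped=skipped)


def _inertia(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for j in np.unique(labels):
        pts = X[labels == j]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def kmeans_maps(
    stack: ActivationMapStack,
    k: int,
    restarts: int = 50,
    seed: int | None = 0,
):
    """Definitive k-means: best of ``restarts`` centroid seeds by inertia.

    Returns ``(assignments, centroids)``; deterministic given ``seed``.
    """
    N = stack.n_maps
    if not 2 <= k <= N - 1:
        raise ValueError(f"k={k} outside accepted range [2, {N - 1}]")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(stack.maps)
    return labels, km.cluster_centers_


def cluster_zmaps(
    stack: ActivationMapStack,
    assignments: np.ndarray,
    threshold: float = 3.2,
) -> ClusterZMaps:
    """Per-cluster spatially Z-normalised mean maps with BOLD sign flip.

    Each cluster's member maps are averaged voxelwise; the mean map is
    Z-normalised in space (subtract spatial mean, divide by spatial sd),
    multiplied by -1 because the estimates are ``dR2*`` changes (negative
    ``dR2*`` = positive BOLD), and binarised at ``Z >= threshold``.
    """
    assignments = np.asarray(assignments)
    ks = np.unique(assignments)
    means, zs = [], []
    for j in ks:
        members = stack.maps[assignments == j]
        if len(members) == 0:
            raise ValueError(f"cluster {j} is empty")
        mean = members.mean(axis=0)
        sd = mean.std()
        if sd < 1e-15:
            raise ValueError(f"cluster {j} mean map has zero spatial variance")
        means.append(mean)
        zs.append((mean - mean.mean()) / sd)
    mean_maps = np.stack(means)
    z_maps = np.stack(zs)
    flipped = -z_maps
    return ClusterZMaps(
        mean_maps=mean_maps,
        z_maps=z_maps,
        flipped_z=flipped,
        binary_maps=flipped >= threshold,
        threshold=threshold,
    )
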
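"""Third-level clustering: group-level configurations across runs/subjects.

The dominant second-level states of every run are represented by their
centroid-agent distance matrices, vectorized (off-diagonal entries only) and
weighted by their occurrence times.  Weighted k-means in this feature space
pools them into group-level configurations; the configuration with the largest
total occurrence weight is the dominant one, and each cluster is summarized by
the member agent closest to its centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import silhouette_samples

from .containers import InvalidArgumentError


@dataclass
class AgentSet:
    """Vectorized agent distance matrices with occurrence-time weights."""

    vectors: np.ndarray  # (n_agents, R*(R-1))
    weights: np.ndarray  # (n_agents,) positive
    provenance: list[tuple[str, int]] = field(default_factory=list)  # (run id, state id)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.vectors.shape[0] != self.weights.shape[0]:
            raise InvalidArgumentError("one weight per agent vector is required")
        if np.any(self.weights < 1):
            raise InvalidArgumentError("weights must be >= 1 (occurrence counts)")
        if not self.provenance:
            self.provenance = [("run0", i) for i in range(self.vectors.shape[0])]

    @property
    def n_agents(self) -> int:
        return self.vectors.shape[0]


@dataclass
class Level3Result:
    labels: np.ndarray
    centroids: np.ndarray
    k: int
    objective: float
    cluster_weights: dict[int, float]
    cluster_members: dict[int, list[int]]
    dominant_cluster: int
    agent_indices: dict[int, int]  # cluster -> member index of its agent


def vectorize_agent(matrix: np.ndarray) -> np.ndarray:
    """Row-major off-diagonal entries of a zero-diagonal distance matrix."""
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise InvalidArgumentError("agent matrix must be square")
    if np.any(np.diag(mat) != 0):
        raise InvalidArgumentError("agent matrix must have a zero diagonal")
    mask = ~np.eye(mat.shape[0], dtype=bool)
    return mat[mask]  # row-major order over (i, j != i)


def devectorize_agent(vector: np.ndarray, n_regions: int) -> np.ndarray:
    """Inverse of :func:`vectorize_agent` given the region count."""
    vec = np.asarray(vector, dtype=float).ravel()
    if vec.size != n_regions * (n_regions - 1):
        raise InvalidArgumentError("vector length must be R*(R-1)")
    out = np.zeros((n_regions, n_regions))
    out[~np.eye(n_regions, dtype=bool)] = vec
    return out


def _weighted_kmeanspp(
    x: np.ndarray, w: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Weight-aware k-means++ seeding."""
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    probs = w / w.sum()
    centers[0] = x[rng.choice(n, p=probs)]
    d2 = np.sum((x - centers[0]) ** 2, axis=1)
    for c in range(1, k):
        scores = w * d2
        total = scores.sum()
        if total <= 0:
            centers[c] = x[rng.integers(n)]
        else:
            centers[c] = x[rng.choice(n, p=scores / total)]
        d2 = np.minimum(d2, np.sum((x - centers[c]) ** 2, axis=1))
    return centers


def _lloyd(
    x: np.ndarray,
    w: np.ndarray,
    centers: np.ndarray,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    k = centers.shape[0]
    prev_obj = np.inf
    labels = np.zeros(x.shape[0], dtype=int)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        obj = float(np.sum(w * d2[np.arange(x.shape[0]), labels]))
        # the weighted objective must never increase across Lloyd iterations
        assert obj <= prev_obj + 1e-9 * max(1.0, abs(prev_obj)), "k-means objective increased"
        for c in range(k):
            mask = labels == c
            if not np.any(mask):
                # re-seed an empty cluster at the point farthest from its centroid
                far = int(np.argmax(w * d2[np.arange(x.shape[0]), labels]))
                centers[c] = x[far]
                continue
            centers[c] = np.average(x[mask], axis=0, weights=w[mask])
        if abs(prev_obj - obj) <= 1e-12 * max(1.0, abs(obj)):
            prev_obj = obj
            break
        prev_obj = obj
    d2 = ((x[:, None, :] - centers[None]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    obj = float(np.sum(w * d2[np.arange(x.shape[0]), labels]))
    return labels, centers, obj


def weighted_kmeans(
    agents: AgentSet,
    k: int,
    seed: int = 0,
    restarts: int = 10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations with weighted centroid updates; best of ``restarts`` seeds.

    Returns (labels, centroids, weighted within-cluster sum of squares).
    Equivalent to unweighted k-means on a dataset where each vector is
    replicated ``weight`` times.
    """
    if k > agents.n_agents:
        raise InvalidArgumentError("k cannot exceed the number of agents")
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        centers = _weighted_kmeanspp(agents.vectors, agents.weights, k, rng)
        labels, centers, obj = _lloyd(agents.vectors, agents.weights, centers.copy())
        if best is None or obj < best[2]:
            best = (labels, centers, obj)
    return best


def select_k_silhouette(
    agents: AgentSet,
    k_range: list[int],
    seed: int = 0,
    weighted: bool = True,
) -> int:
    """k maximizing the (weight-averaged) mean silhouette; ties toward smaller k."""
    if len(k_range) == 0:
        raise InvalidArgumentError("k_range must be nonempty")
    if len(k_range) == 1:
        return int(k_range[0])
    if any(k < 2 or k > agents.n_agents - 1 for k in k_range):
        raise InvalidArgumentError("k_range must lie within [2, n_agents-1]")
    best_k, best_score = None, -np.inf
    for k in sorted(k_range):
        labels, _, _ = weighted_kmeans(agents, k, seed=seed)
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_samples(agents.vectors, labels)
        score = (
            float(np.average(sil, weights=agents.weights)) if weighted else float(sil.mean())
        )
        if score > best_score:
            best_k, best_score = k, score
    if best_k is None:
        raise InvalidArgumentError("silhouette undefined for every k in k_range")
    return int(best_k)


def level3_agent(member_vectors: np.ndarray, centroid: np.ndarray) -> int:
    """Index of the member closest (Euclidean) to the centroid; ties to lowest index."""
    vecs = np.atleast_2d(np.asarray(member_vectors, dtype=float))
    if vecs.shape[0] == 0:
        raise InvalidArgumentError("cluster must be nonempty")
    d2 = np.sum((vecs - np.asarray(centroid, dtype=float)) ** 2, axis=1)
    return int(np.argmin(d2))


def cluster_level3(
    agents: AgentSet,
    k: int | None = None,
    k_range: list[int] | None = None,
    seed: int = 0,
    restarts: int = 10,
) -> Level3Result:
    """Weighted k-means over pooled agents; dominant cluster = largest total weight."""
    if k is None:
        if k_range is None:
            k_range = list(range(2, min(10, agents.n_agents - 1) + 1))
        k = select_k_silhouette(agents, k_range, seed=seed)
    labels, centroids, obj = weighted_kmeans(agents, k, seed=seed, restarts=restarts)
    cluster_weights = {}
    cluster_members = {}
    agent_indices = {}
    for c in range(k):
        members = np.nonzero(labels == c)[0]
        cluster_members[c] = members.tolist()
        cluster_weights[c] = float(agents.weights[members].sum())
        if members.size:
            local = level3_agent(agents.vectors[members], centroids[c])
            agent_indices[c] = int(members[local])
    dominant = max(cluster_weights, key=cluster_weights.get)
    return Level3Result(
        labels=labels,
        centroids=centroids,
        k=k,
        objective=obj,
        cluster_weights=cluster_weights,
        cluster_members=cluster_members,
        dominant_cluster=int(dominant),
        agent_indices=agent_indices,
    )
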
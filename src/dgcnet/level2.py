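"""Second-level clustering: recurring network configurations within a run.

The per-time partitions from the first level are compared with a greedy
label-matching distance (the number of regions whose labels disagree after the
best-overlap clusters of the two partitions have been greedily matched), then
grouped by average-linkage hierarchical clustering with the number of states
chosen by the silhouette criterion.  Each state is summarized by a centroid
"agent": the member time point whose distance matrix is closest (entrywise
Euclidean) to the state's mean distance matrix.  Dwell-time statistics and the
occurrence-count dominance threshold are computed from the state sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .containers import InvalidArgumentError
from .distance import DistMatrixSeries
from .level1 import PartitionSeries


@dataclass
class Level2Result:
    """State sequence and per-state summaries for one run."""

    state_labels: np.ndarray  # (T,) 1-based state ids, numbered by first appearance
    n_states: int
    agents: dict[int, tuple[int, np.ndarray]]  # state -> (agent time index, agent matrix)
    occurrence_times: dict[int, int]
    dwell_segments: list[int]
    dominant_states: list[int]
    dominance_threshold: float
    silhouette: float | None = None
    tr_seconds: float = 1.0

    @property
    def n_time(self) -> int:
        return self.state_labels.shape[0]


def partition_distance(p1: np.ndarray, p2: np.ndarray) -> int:
    """Number of regions labeled differently after greedy cluster matching.

    The cluster pair (one from each partition) sharing the most regions is
    repeatedly matched and given a fresh common label; once the maximal overlap
    hits zero every remaining cluster receives its own fresh label.  Ties in
    overlap break toward the lowest cluster index in the first partition, then
    in the second.
    """
    a = np.asarray(p1).ravel()
    b = np.asarray(p2).ravel()
    if a.shape != b.shape:
        raise InvalidArgumentError("partitions must have equal length")
    _, inv_a = np.unique(a, return_inverse=True)
    _, inv_b = np.unique(b, return_inverse=True)
    n_a = inv_a.max() + 1
    n_b = inv_b.max() + 1
    overlap = np.zeros((n_a, n_b), dtype=int)
    np.add.at(overlap, (inv_a, inv_b), 1)

    label_a = np.full(n_a, -1)
    label_b = np.full(n_b, -1)
    work = overlap.astype(float)
    fresh = 0
    for _ in range(min(n_a, n_b)):
        idx = int(np.argmax(work))  # row-major argmax = lowest (row, col) on ties
        i, j = divmod(idx, n_b)
        if work[i, j] <= 0:
            break
        label_a[i] = fresh
        label_b[j] = fresh
        fresh += 1
        work[i, :] = -1
        work[:, j] = -1
    for i in range(n_a):
        if label_a[i] < 0:
            label_a[i] = fresh
            fresh += 1
    for j in range(n_b):
        if label_b[j] < 0:
            label_b[j] = fresh
            fresh += 1
    return int(np.sum(label_a[inv_a] != label_b[inv_b]))


def partition_distance_matrix(partitions: PartitionSeries) -> np.ndarray:
    """Pairwise greedy label-matching distances between all time points."""
    labels = partitions.labels
    t_total = labels.shape[0]
    # deduplicate identical partitions: typically few unique ones per run
    uniq, inverse = np.unique(labels, axis=0, return_inverse=True)
    n_u = uniq.shape[0]
    d_u = np.zeros((n_u, n_u))
    for i in range(n_u):
        for j in range(i + 1, n_u):
            d_u[i, j] = d_u[j, i] = partition_distance(uniq[i], uniq[j])
    return d_u[np.ix_(inverse, inverse)]


def centroid_agent(member_times: list[int], dist_series: DistMatrixSeries) -> int:
    """Member whose distance matrix is entrywise closest to the members' mean.

    Ties break toward the earliest time index.
    """
    if len(member_times) == 0:
        raise InvalidArgumentError("member list must be nonempty")
    members = sorted(int(t) for t in member_times)
    mats = dist_series.matrices[members]
    mean = mats.mean(axis=0)
    sq = np.sum((mats - mean) ** 2, axis=(1, 2))
    return members[int(np.argmin(sq))]


def dominance_threshold(
    occurrence_counts: list[int] | np.ndarray, bin_width: int = 5
) -> tuple[float, list[int]]:
    """Histogram-gap threshold separating dominant from non-dominant states.

    A histogram of occurrence counts is scanned (starting after its first
    nonempty bin) for the first empty bin that is followed by another empty
    bin — a value of zero whose first difference is also zero.  The left edge
    of that bin is the threshold; counts above it are dominant.  Returns
    ``(threshold, indices of dominant entries)``.
    """
    counts = np.asarray(occurrence_counts)
    if counts.size == 0:
        raise InvalidArgumentError("occurrence counts must be nonempty")
    cmax = int(counts.max())
    edges = np.arange(0, cmax + 3 * bin_width, bin_width)
    hist, _ = np.histogram(counts, bins=edges)
    nonzero = np.nonzero(hist)[0]
    first_occupied = int(nonzero[0])
    last_occupied = int(nonzero[-1])
    threshold = None
    for k in range(first_occupied + 1, last_occupied):
        if hist[k] == 0 and hist[k + 1] == 0:
            threshold = float(edges[k])
            break
    if threshold is None:
        warnings.warn(
            "no two consecutive empty histogram bins below the maximum count: "
            "no dominant states",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(cmax), []
    dominant = np.nonzero(counts > threshold)[0]
    return threshold, [int(i) for i in dominant]


def dwell_segments(state_labels: np.ndarray) -> list[int]:
    """Lengths of maximal runs of a constant state label."""
    labels = np.asarray(state_labels).ravel()
    if labels.size == 0:
        return []
    change = np.nonzero(np.diff(labels))[0]
    bounds = np.concatenate(([-1], change, [labels.size - 1]))
    return list(np.diff(bounds).astype(int))


def dwell_stats(
    state_labels: np.ndarray, tr_seconds: float = 1.0
) -> tuple[float, float, list[float]]:
    """Mean/std (population convention) dwell time in seconds, and per-state
    total times sorted descending."""
    labels = np.asarray(state_labels).ravel()
    if labels.size < 1:
        raise InvalidArgumentError("state sequence must be nonempty")
    segs = np.array(dwell_segments(labels), dtype=float) * tr_seconds
    totals = np.array(
        [np.sum(labels == s) * tr_seconds for s in np.unique(labels)], dtype=float
    )
    return float(segs.mean()), float(segs.std()), sorted(totals.tolist(), reverse=True)


def dwell_vs_k_regression(per_run_stats: list[tuple[int, float, float]]) -> dict:
    """Least-squares lines of mean and std dwell time against state count.

    ``per_run_stats`` holds (n_states, mean_dwell, std_dwell) per run. Returns
    slopes, intercepts and two-sided p-values for both regressions.
    """
    if len(per_run_stats) < 3:
        raise InvalidArgumentError("need at least 3 runs for the regression")
    arr = np.asarray(per_run_stats, dtype=float)
    out = {}
    for name, col in (("mean", 1), ("std", 2)):
        fit = stats.linregress(arr[:, 0], arr[:, col])
        out[name] = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "p_value": float(fit.pvalue),
        }
    return out


def _renumber_by_first_appearance(labels: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cluster_level2(
    partitions: PartitionSeries,
    dist_series: DistMatrixSeries,
    k_range: list[int] | None = None,
    tr_seconds: float = 1.0,
    bin_width: int = 5,
) -> Level2Result:
    """Group the per-time partitions of one run into recurring states."""
    t_total = partitions.n_time
    if t_total < 3:
        raise InvalidArgumentError("need at least 3 time points")
    if dist_series.n_time != t_total:
        raise InvalidArgumentError("distance series and partitions disagree in length")
    dmat = partition_distance_matrix(partitions)

    if np.all(dmat == 0):
        warnings.warn(
            "all partitions identical: a single state covers the run",
            RuntimeWarning,
            stacklevel=2,
        )
        state_labels = np.ones(t_total, dtype=int)
        best_k, best_sil = 1, None
    else:
        if k_range is None:
            k_range = list(range(2, min(20, t_total - 1) + 1))
        if any(k < 2 or k > t_total - 1 for k in k_range):
            raise InvalidArgumentError("k_range must lie within [2, T-1]")
        condensed = squareform(dmat, checks=False)
        tree = linkage(condensed, method="average")
        best_k, best_sil, best_labels = None, -np.inf, None
        for k in k_range:
            labels = fcluster(tree, t=k, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            sil = silhouette_score(dmat, labels, metric="precomputed")
            if sil > best_sil:
                best_k, best_sil, best_labels = k, float(sil), labels
        if best_labels is None:
            warnings.warn(
                "silhouette selection degenerate: falling back to 2 states",
                RuntimeWarning,
                stacklevel=2,
            )
            best_labels = fcluster(tree, t=2, criterion="maxclust")
            best_k, best_sil = len(np.unique(best_labels)), None
        state_labels = _renumber_by_first_appearance(best_labels)
        best_k = len(np.unique(state_labels))

    states = np.unique(state_labels)
    agents = {}
    occurrence = {}
    for s in states:
        members = np.nonzero(state_labels == s)[0].tolist()
        occurrence[int(s)] = len(members)
        idx = centroid_agent(members, dist_series)
        agents[int(s)] = (idx, dist_series.matrices[idx].copy())
    counts = [occurrence[int(s)] for s in states]
    if len(states) > 1:
        thr, dom_idx = dominance_threshold(counts, bin_width=bin_width)
        dominant = [int(states[i]) for i in dom_idx]
    else:
        thr, dominant = float(counts[0]), [int(states[0])]
    segs = dwell_segments(state_labels)
    return Level2Result(
        state_labels=state_labels,
        n_states=int(len(states)),
        agents=agents,
        occurrence_times=occurrence,
        dwell_segments=segs,
        dominant_states=dominant,
        dominance_threshold=thr,
        silhouette=best_sil,
        tr_seconds=tr_seconds,
    )
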
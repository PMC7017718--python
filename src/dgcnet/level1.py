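"""First-level clustering: evolving partitions of regions over time.

At every time point the regions are grouped by agglomerative (average-linkage)
clustering of the distance matrix.  Temporal coherence is obtained by
exponentially smoothing the distance matrices before clustering, with a
forgetting factor alpha controlling how much the recent past matters:
``S_t = alpha * S_{t-1} + (1 - alpha) * D_t``.  alpha = 0 reduces to
independent per-time clustering; larger alpha yields more slowly evolving
partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import InvalidArgumentError, default_region_names
from .distance import DistMatrixSeries

DEFAULT_N_CLUSTERS = 6
DEFAULT_ALPHA_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class PartitionSeries:
    """Per-time cluster labels of the regions; labels are 1-based and
    canonicalized within each time point (cluster containing the lowest region
    index gets label 1, and so on).  Identity across time points is only
    meaningful up to relabeling."""

    labels: np.ndarray  # (T, R) integers
    n_clusters: int
    alpha: float
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise InvalidArgumentError("labels must be a (T, R) integer matrix")
        if not self.region_names:
            self.region_names = default_region_names(self.labels.shape[1])

    @property
    def n_time(self) -> int:
        return self.labels.shape[0]

    @property
    def n_regions(self) -> int:
        return self.labels.shape[1]


def smooth_distances(series: DistMatrixSeries, alpha: float) -> DistMatrixSeries:
    """Exponential smoothing S_t = alpha*S_{t-1} + (1-alpha)*D_t, S_1 = D_1."""
    if not (0.0 <= alpha < 1.0):
        raise InvalidArgumentError("alpha must lie in [0, 1)")
    mats = series.matrices
    out = np.empty_like(mats)
    out[0] = mats[0]
    for t in range(1, mats.shape[0]):
        out[t] = alpha * out[t - 1] + (1.0 - alpha) * mats[t]
    return DistMatrixSeries(
        matrices=out, region_names=list(series.region_names), params=series.params
    )


def alpha_objective(series: DistMatrixSeries, alpha: float) -> float:
    """One-step-ahead prediction error of the smoothed series.

    sum_t || S_{t-1}(alpha) - D_t ||_F^2: the smoothed matrix at t-1 is used as
    the forecast of the raw matrix at t.
    """
    smoothed = smooth_distances(series, alpha).matrices
    diffs = smoothed[:-1] - series.matrices[1:]
    return float(np.sum(diffs**2))


def select_alpha(series: DistMatrixSeries, grid=DEFAULT_ALPHA_GRID) -> float:
    """Grid value minimizing the one-step-ahead prediction error (ties: first)."""
    if len(grid) == 0:
        raise InvalidArgumentError("alpha grid must be nonempty")
    objectives = [alpha_objective(series, a) for a in grid]
    return float(grid[int(np.argmin(objectives))])


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Relabel so clusters are numbered 1.. in order of their smallest member."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for lab in labels:  # first occurrence order == smallest-member order
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    for i, lab in enumerate(labels):
        out[i] = mapping[lab]
    return out


def cluster_level1(
    series: DistMatrixSeries,
    n_clusters: int = DEFAULT_N_CLUSTERS,
    alpha: float = 0.0,
) -> PartitionSeries:
    """Cluster regions at every time point from smoothed distance matrices."""
    n_regions = series.n_regions
    if not (2 <= n_clusters <= n_regions - 1):
        raise InvalidArgumentError(
            f"n_clusters must lie in [2, R-1] = [2, {n_regions - 1}]"
        )
    smoothed = smooth_distances(series, alpha)
    labels = np.empty((series.n_time, n_regions), dtype=int)
    for t in range(series.n_time):
        mat = smoothed.matrices[t]
        if np.allclose(mat, 0.0):
            warnings.warn(
                f"degenerate all-zero distance matrix at t={t}: single cluster",
                RuntimeWarning,
                stacklevel=2,
            )
            labels[t] = 1
            continue
        condensed = squareform((mat + mat.T) / 2.0, checks=False)
        tree = linkage(condensed, method="average")
        labels[t] = _canonicalize(fcluster(tree, t=n_clusters, criterion="maxclust"))
    return PartitionSeries(
        labels=labels,
        n_clusters=n_clusters,
        alpha=alpha,
        region_names=list(series.region_names),
    )
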
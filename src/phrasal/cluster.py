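"""Nonparametric cluster-based permutation test over channel x freq x time.

Controls the familywise error of mass-univariate paired comparisons by
clustering adjacent super-threshold bins (spatial adjacency from a channel
neighbor graph; spectral and temporal adjacency between consecutive bins),
summing the t values within each cluster, and comparing each cluster mass
against the permutation distribution of the maximum absolute cluster mass
obtained by randomly exchanging the paired conditions within subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats

__all__ = [
    "AdjacencySpec",
    "Cluster",
    "ClusterResult",
    "grid_adjacency",
    "channel_adjacency_from_positions",
    "cluster_test",
]


@dataclass
class AdjacencySpec:
    """Channel neighbor lists; time/frequency adjacency is consecutive bins."""

    neighbors: dict  # channel index -> iterable of neighbor indices

    def __post_init__(self):
        clean = {}
        for ch, nbrs in self.neighbors.items():
            clean[int(ch)] = sorted({int(n) for n in nbrs} - {int(ch)})
        # enforce symmetry
        for ch, nbrs in list(clean.items()):
            for n in nbrs:
                lst = clean.setdefault(n, [])
                if ch not in lst:
                    lst.append(ch)
                    lst.sort()
        self.neighbors = clean

    @classmethod
    def none(cls, n_channels: int) -> "AdjacencySpec":
        """No spatial adjacency (each channel its own island)."""
        return cls({c: [] for c in range(n_channels)})


def channel_adjacency_from_positions(
    positions: np.ndarray, k: int = 4
) -> AdjacencySpec:
    """Symmetric k-nearest-neighbor adjacency from 2-D montage coordinates."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    neighbors = {i: list(np.argsort(d[i])[: min(k, n - 1)]) for i in range(n)}
    return AdjacencySpec(neighbors)


def grid_adjacency(shape: tuple, adjacency: AdjacencySpec) -> sparse.csr_matrix:
    """Sparse adjacency over flattened (channel, freq, time) bins.

    Bins are neighbors when they share a channel and differ by one step in
    frequency OR time, or share the (freq, time) position on neighboring
    channels.
    """
    n_ch, n_f, n_t = shape
    idx = np.arange(n_ch * n_f * n_t).reshape(shape)
    rows, cols = [], []

    def link(a, b):
        rows.append(a.ravel())
        cols.append(b.ravel())

    if n_t > 1:
        link(idx[:, :, :-1], idx[:, :, 1:])
    if n_f > 1:
        link(idx[:, :-1, :], idx[:, 1:, :])
    for ch, nbrs in adjacency.neighbors.items():
        for n in nbrs:
            if n > ch:
                link(idx[ch], idx[n])
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
    data = np.ones(len(rows), dtype=np.int8)
    n = n_ch * n_f * n_t
    mat = sparse.coo_matrix((data, (rows, cols)), shape=(n, n))
    return (mat + mat.T).tocsr()


@dataclass
class Cluster:
    bins: np.ndarray  # flat indices into (channel, freq, time)
    mass: float  # sum of t values
    sign: int
    p: float = np.nan


@dataclass
class ClusterResult:
    clusters: list
    null_max_mass: np.ndarray
    t_map: np.ndarray
    threshold: float
    n_perm: int
    shape: tuple

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p <= alpha]


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Paired t over axis 0 of (n_subjects, n_bins); constant-zero bins -> 0."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    # constant differences: 0 when truly null, a large finite t otherwise
    return np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * 1e9), t)


def _clusters_from_t(t_flat, thresh, adj_csr):
    """Sign-split connected components of super-threshold bins."""
    out = []
    for sign in (1, -1):
        mask = (sign * t_flat) > thresh
        if not mask.any():
            continue
        sub = adj_csr[mask][:, mask]
        n_comp, labels = sparse.csgraph.connected_components(sub, directed=False)
        flat_idx = np.flatnonzero(mask)
        for c in range(n_comp):
            bins = flat_idx[labels == c]
            out.append(Cluster(bins, float(t_flat[bins].sum()), sign))
    return out


def cluster_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: AdjacencySpec | None = None,
    alpha_entry: float = 0.05,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Paired cluster-based permutation test.

    ``cond_a`` and ``cond_b`` are (subject, channel, freq, time). Per bin a
    dependent t statistic is computed; bins with two-sided p < alpha_entry
    form clusters separately by sign under the adjacency; cluster mass is
    the sum of t values. The null exchanges the condition labels within
    random subsets of subjects (sign flips of the paired differences) and
    records the maximum absolute cluster mass per permutation. Cluster
    p values use the (count + 1) / (n_perm + 1) convention.
    """
    cond_a, cond_b = np.asarray(cond_a, float), np.asarray(cond_b, float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("conditions must have identical shapes")
    if cond_a.ndim != 4:
        raise ValueError("expected (subject, channel, freq, time) arrays")
    n_sub = cond_a.shape[0]
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    shape = cond_a.shape[1:]
    if adjacency is None:
        adjacency = AdjacencySpec.none(shape[0])
    adj = grid_adjacency(shape, adjacency)
    diff = (cond_a - cond_b).reshape(n_sub, -1)
    thresh = stats.t.isf(alpha_entry / 2.0, df=n_sub - 1)

    t_obs = _paired_t(diff)
    clusters = _clusters_from_t(t_obs, thresh, adj)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_sub)[:, None]
        t_perm = _paired_t(diff * flips)
        perm_clusters = _clusters_from_t(t_perm, thresh, adj)
        null[p] = max((abs(c.mass) for c in perm_clusters), default=0.0)
    for c in clusters:
        c.p = (np.sum(null >= abs(c.mass)) + 1.0) / (n_perm + 1.0)
    return ClusterResult(clusters, null, t_obs.reshape(shape), thresh, n_perm, shape)
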
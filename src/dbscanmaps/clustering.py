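"""DBSCAN parameter-grid scans and cluster-parameter maps.

The characterization method implemented here runs DBSCAN over a grid of its
two input parameters — the neighborhood radius epsilon (nm) and the minimum
point count N — and records, for every (epsilon, N) pair, five statistics of
the resulting clusters: average and standard deviation of the convex-hull
cluster area, average and standard deviation of the per-cluster localization
number, and the number of clusters.  Stacked over the grid these form five
"cluster-parameter maps" that characterize a point cloud without knowing the
ground truth, and whose gradients expose the sensitivity of the clustering
output to its inputs.

DBSCAN convention
-----------------
* A point is a *core* point iff its closed epsilon-neighborhood (including
  itself) contains at least N points.
* Clusters are maximal sets of core points connected through core-core
  distances <= epsilon; a non-core point within epsilon of at least one core
  point is a *border* point, assigned deterministically to the cluster of the
  lowest-index core point in its neighborhood.  All remaining points are
  noise.

The lowest-index border rule removes the expansion-order dependence of
textbook DBSCAN, so every run is reproducible and comparable against a
brute-force reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree

from ._fast import HAVE_NUMBA, sweep_labels
from .localization_io import LocalizationTable

__all__ = [
    "GridSpec",
    "ClusterRecord",
    "ClusterSummary",
    "MapStack",
    "dbscan_partition",
    "hull_area",
    "cluster_records",
    "summarize_clusters",
    "scan_grid",
    "scan_grid_multi",
    "MEASURED_GRID",
    "SIMULATION_GRID",
]

NOISE = -1


@dataclass(frozen=True)
class GridSpec:
    """Ordered (epsilon, N) parameter grid.

    epsilons are strictly increasing lengths in nm; Ns are strictly
    increasing integers >= 2.
    """

    epsilons: np.ndarray
    Ns: np.ndarray

    def __post_init__(self):
        eps = np.asarray(self.epsilons, dtype=float)
        ns = np.asarray(self.Ns, dtype=int)
        if eps.ndim != 1 or eps.size == 0 or ns.ndim != 1 or ns.size == 0:
            raise ValueError("epsilons and Ns must be nonempty 1-D sequences")
        if np.any(eps <= 0) or np.any(np.diff(eps) <= 0):
            raise ValueError("epsilons must be positive and strictly increasing")
        if np.any(ns < 2) or np.any(np.diff(ns) <= 0):
            raise ValueError("Ns must be >= 2 and strictly increasing")
        object.__setattr__(self, "epsilons", eps)
        object.__setattr__(self, "Ns", ns)

    @classmethod
    def from_ranges(cls, eps_min, eps_max, eps_step, n_min, n_max, n_step) -> "GridSpec":
        eps = np.arange(eps_min, eps_max + eps_step / 2, eps_step, dtype=float)
        ns = np.arange(n_min, n_max + 1, n_step, dtype=int)
        return cls(epsilons=eps, Ns=ns)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.epsilons.size, self.Ns.size)


#: Default grid for measured dSTORM data: localization precision limits the
#: useful epsilon resolution, so coarse steps are used.
MEASURED_GRID = GridSpec.from_ranges(10, 90, 10, 2, 20, 2)

#: Default fine grid for simulated data (more precise, fewer localizations).
SIMULATION_GRID = GridSpec.from_ranges(1, 90, 1, 2, 20, 1)


@dataclass(frozen=True)
class ClusterRecord:
    """One DBSCAN cluster: its id, size, convex-hull area and members."""

    cluster_id: int
    n_loc: int
    hull_area: float
    member_indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.member_indices, dtype=int)
        object.__setattr__(self, "member_indices", idx)
        if self.n_loc != idx.size:
            raise ValueError("n_loc must equal the number of member indices")
        if self.hull_area < 0:
            raise ValueError("hull_area must be >= 0")


@dataclass(frozen=True)
class ClusterSummary:
    """Per-(epsilon, N) cluster statistics.

    av/sd fields are NaN when no clusters were found; SD is the population
    standard deviation (divisor n), so a single-cluster cell reports 0.
    """

    epsilon: float
    N: int
    n_clusters: int
    av_area: float
    sd_area: float
    av_nloc: float
    sd_nloc: float


@dataclass
class MapStack:
    """The five cluster-parameter maps over a :class:`GridSpec`.

    ``maps[metric]`` has shape ``(len(epsilons), len(Ns))``; cells with zero
    clusters are NaN in the four statistic maps and 0 in ``n_clusters``.
    """

    METRICS = ("av_area", "sd_area", "av_nloc", "sd_nloc", "n_clusters")

    grid: GridSpec
    maps: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for metric in self.METRICS:
            if metric not in self.maps:
                raise ValueError(f"missing map {metric!r}")
            m = np.asarray(self.maps[metric], dtype=float)
            if m.shape != self.grid.shape:
                raise ValueError(
                    f"map {metric!r} shape {m.shape} != grid shape {self.grid.shape}"
                )
            self.maps[metric] = m
        nc = self.maps["n_clusters"]
        if np.any(np.isnan(nc)) or np.any(nc < 0) or np.any(nc != np.round(nc)):
            raise ValueError("n_clusters map must be nonnegative integers")

    def copy(self) -> "MapStack":
        return MapStack(
            grid=self.grid,
            maps={k: v.copy() for k, v in self.maps.items()},
            metadata=dict(self.metadata),
        )


def hull_area(points: np.ndarray) -> float:
    """Convex-hull area (nm^2) of a 2D point set.

    Returns 0 for fewer than 3 points or collinear sets; raises
    :class:`ValueError` for an empty set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("hull_area of an empty point set is undefined")
    pts = pts.reshape(-1, 2)
    if pts.shape[0] < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # collinear / duplicate-degenerate input
        return 0.0
    return float(hull.volume)  # in 2D, qhull "volume" is the polygon area


def _neighbor_pairs(xy: np.ndarray, eps_max: float):
    """All index pairs (i < j) within eps_max, sorted by distance."""
    tree = cKDTree(xy)
    pairs = tree.query_pairs(eps_max, output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=np.intp), np.empty(0)
    d = np.sqrt(((xy[pairs[:, 0]] - xy[pairs[:, 1]]) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")
    return pairs[order], d[order]


def _labels_one_n(n_points, edges, counts, N, u_sorted, v_sorted):
    """Cluster labels (-1 = noise) for one (epsilon, N) cell.

    ``edges`` are undirected pairs within epsilon, ``counts`` the closed
    neighborhood sizes, ``u_sorted``/``v_sorted`` the directed edge list
    sorted lexicographically by (u, v) for lowest-index border assignment.
    """
    core = counts >= N
    labels = np.full(n_points, NOISE, dtype=np.intp)
    if not core.any():
        return labels
    if edges.size:
        cc_mask = core[edges[:, 0]] & core[edges[:, 1]]
        ce = edges[cc_mask]
    else:
        ce = edges
    graph = coo_matrix(
        (np.ones(ce.shape[0], dtype=np.int8), (ce[:, 0], ce[:, 1])),
        shape=(n_points, n_points),
    )
    _, comp = connected_components(graph, directed=False)
    labels[core] = comp[core]
    if u_sorted.size:
        bmask = (~core[u_sorted]) & core[v_sorted]
        if bmask.any():
            bu = u_sorted[bmask]
            bv = v_sorted[bmask]
            # first occurrence per border point = lowest-index core neighbor
            uniq, first = np.unique(bu, return_index=True)
            labels[uniq] = comp[bv[first]]
    # compact cluster ids to 0..K-1 in order of first appearance by component id
    clustered = labels >= 0
    if clustered.any():
        uniq = np.unique(labels[clustered])
        remap = np.full(uniq.max() + 1, -1, dtype=np.intp)
        remap[uniq] = np.arange(uniq.size)
        labels[clustered] = remap[labels[clustered]]
    return labels


def dbscan_partition(points: LocalizationTable, epsilon: float, N: int) -> np.ndarray:
    """DBSCAN cluster labels per localization; noise points are labeled -1.

    Follows the module's deterministic convention (closed neighborhood
    counting the point itself; lowest-index-core border assignment).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if N < 2:
        raise ValueError("N must be >= 2")
    n = points.count
    if n == 0:
        return np.empty(0, dtype=np.intp)
    xy = points.xy
    edges, _ = _neighbor_pairs(xy, epsilon)
    counts = np.ones(n, dtype=np.intp)
    if edges.size:
        counts += np.bincount(edges[:, 0], minlength=n)
        counts += np.bincount(edges[:, 1], minlength=n)
    u = np.concatenate([edges[:, 0], edges[:, 1]])
    v = np.concatenate([edges[:, 1], edges[:, 0]])
    order = np.lexsort((v, u))
    return _labels_one_n(n, edges, counts, int(N), u[order], v[order])


def cluster_records(points: LocalizationTable, labels: np.ndarray) -> list[ClusterRecord]:
    """Build :class:`ClusterRecord` objects (with hull areas) from a labeling."""
    xy = points.xy
    records = []
    for cid in np.unique(labels[labels >= 0]):
        idx = np.nonzero(labels == cid)[0]
        records.append(
            ClusterRecord(
                cluster_id=int(cid),
                n_loc=int(idx.size),
                hull_area=hull_area(xy[idx]),
                member_indices=idx,
            )
        )
    return records


def summarize_clusters(
    records: Sequence[ClusterRecord], epsilon: float, N: int
) -> ClusterSummary:
    """Mean/SD of cluster area and localization number for one grid cell."""
    k = len(records)
    if k == 0:
        return ClusterSummary(epsilon, int(N), 0, np.nan, np.nan, np.nan, np.nan)
    areas = np.array([r.hull_area for r in records], dtype=float)
    nlocs = np.array([r.n_loc for r in records], dtype=float)
    return ClusterSummary(
        epsilon=float(epsilon),
        N=int(N),
        n_clusters=k,
        av_area=float(areas.mean()),
        sd_area=float(areas.std(ddof=0)),
        av_nloc=float(nlocs.mean()),
        sd_nloc=float(nlocs.std(ddof=0)),
    )


def _cell_cluster_stats(xy, labels, hull_cache):
    """Per-cluster (hull_area, n_loc) arrays for one cell's labeling.

    ``hull_cache`` maps a cluster's member-index byte string to its hull
    area: across a grid scan the same member sets recur in many cells, so
    caching avoids recomputing identical hulls.
    """
    clustered = labels >= 0
    if not clustered.any():
        return np.empty(0), np.empty(0)
    lab = labels[clustered]
    order = np.argsort(lab, kind="stable")
    sorted_lab = lab[order]
    pts_idx = np.nonzero(clustered)[0][order]
    # run boundaries; label values may be arbitrary (e.g. union-find roots)
    starts = np.concatenate(
        [[0], np.nonzero(np.diff(sorted_lab))[0] + 1, [sorted_lab.size]]
    )
    areas = []
    nlocs = []
    for lo, hi in zip(starts[:-1], starts[1:]):
        members = pts_idx[lo:hi]
        if hi - lo < 3:
            a = 0.0
        else:
            key = members.tobytes()
            a = hull_cache.get(key)
            if a is None:
                a = hull_area(xy[members])
                hull_cache[key] = a
        areas.append(a)
        nlocs.append(hi - lo)
    return np.asarray(areas, dtype=float), np.asarray(nlocs, dtype=float)


def _summary_from_stats(areas, nlocs, epsilon, N, min_area):
    if min_area is not None and min_area > 0:
        keep = areas >= min_area
        areas, nlocs = areas[keep], nlocs[keep]
    if areas.size == 0:
        return ClusterSummary(epsilon, int(N), 0, np.nan, np.nan, np.nan, np.nan)
    return ClusterSummary(
        epsilon=float(epsilon),
        N=int(N),
        n_clusters=int(areas.size),
        av_area=float(areas.mean()),
        sd_area=float(areas.std(ddof=0)),
        av_nloc=float(nlocs.mean()),
        sd_nloc=float(nlocs.std(ddof=0)),
    )


def scan_grid_multi(
    points: LocalizationTable,
    grid: GridSpec = SIMULATION_GRID,
    min_areas: Sequence[Optional[float]] = (None,),
    metadata: Optional[dict] = None,
) -> list[MapStack]:
    """One DBSCAN grid scan summarized under several cluster-area filters.

    Returns one :class:`MapStack` per entry of ``min_areas`` (nm^2; None or
    0 disables the filter).  The clustering work is shared: this is how a
    filtered and an unfiltered stack of the same dataset are obtained at the
    cost of a single scan.
    """
    eps = grid.epsilons
    ns = grid.Ns
    shape = grid.shape
    stacks = []
    for ma in min_areas:
        maps = {m: np.full(shape, np.nan) for m in MapStack.METRICS}
        maps["n_clusters"] = np.zeros(shape)
        meta = dict(metadata or {})
        meta["min_area_nm2"] = ma
        stacks.append(MapStack(grid=grid, maps=maps, metadata=meta))
    n = points.count
    if n == 0:
        return stacks

    xy = points.xy
    pairs, dists = _neighbor_pairs(xy, float(eps[-1]))
    hull_cache: dict = {}
    prefix = np.searchsorted(dists, eps, side="right")

    def _fill_cell(i, j, e, N, labels):
        areas, nlocs = _cell_cluster_stats(xy, labels, hull_cache)
        for stack, ma in zip(stacks, min_areas):
            s = _summary_from_stats(areas, nlocs, float(e), int(N), ma)
            stack.maps["n_clusters"][i, j] = s.n_clusters
            stack.maps["av_area"][i, j] = s.av_area
            stack.maps["sd_area"][i, j] = s.sd_area
            stack.maps["av_nloc"][i, j] = s.av_nloc
            stack.maps["sd_nloc"][i, j] = s.sd_nloc

    if HAVE_NUMBA:
        ei = np.ascontiguousarray(pairs[:, 0], dtype=np.int64)
        ej = np.ascontiguousarray(pairs[:, 1], dtype=np.int64)
        deg = np.zeros(n + 1, dtype=np.int64)
        np.add.at(deg, ei + 1, 1)
        np.add.at(deg, ej + 1, 1)
        indptr = np.cumsum(deg)
        for j, N in enumerate(ns):
            lab_mat = sweep_labels(n, ei, ej, prefix.astype(np.int64), int(N), indptr)
            for i, e in enumerate(eps):
                _fill_cell(i, j, e, N, lab_mat[i])
    else:
        for i, e in enumerate(eps):
            edges = pairs[: prefix[i]]
            counts = np.ones(n, dtype=np.int64)
            if edges.size:
                counts += np.bincount(edges[:, 0], minlength=n)
                counts += np.bincount(edges[:, 1], minlength=n)
            u = np.concatenate([edges[:, 0], edges[:, 1]])
            v = np.concatenate([edges[:, 1], edges[:, 0]])
            order = np.lexsort((v, u))
            u_s, v_s = u[order], v[order]
            for j, N in enumerate(ns):
                labels = _labels_one_n(n, edges, counts, int(N), u_s, v_s)
                _fill_cell(i, j, e, N, labels)
    return stacks


def scan_grid(
    points: LocalizationTable,
    grid: GridSpec = SIMULATION_GRID,
    min_area: Optional[float] = None,
    metadata: Optional[dict] = None,
) -> MapStack:
    """Run DBSCAN over the (epsilon, N) grid and assemble the five maps.

    When ``min_area`` (nm^2) is given, clusters with convex-hull area below
    it are removed before the statistics are taken — this affects all five
    maps, including the cluster count.

    The scan shares one neighbor-pair computation (at the largest epsilon)
    across all grid cells; the per-cell partitions are identical to calling
    :func:`dbscan_partition` cell by cell.
    """
    return scan_grid_multi(points, grid, min_areas=(min_area,), metadata=metadata)[0]
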
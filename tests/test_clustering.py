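"""Clustering oracle and property tests.

The brute-force reference here implements the package's deterministic DBSCAN
convention (closed neighborhood; lowest-index-core border assignment) from
scratch with dense O(n^2) distances, and the hull oracle builds the convex
polygon by an independent monotone-chain construction and applies the
shoelace formula.
"""

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from scipy.spatial.distance import cdist

from dbscanmaps import (
    GridSpec,
    LocalizationTable,
    cluster_records,
    dbscan_partition,
    hull_area,
    scan_grid,
    scan_grid_multi,
    summarize_clusters,
    PatternConfig,
    simulate_pattern,
)
from conftest import make_table


# ------------------------------------------------------------- oracles

def brute_dbscan(xy, eps, N):
    """Dense-matrix reference DBSCAN with the same deterministic convention."""
    n = len(xy)
    if n == 0:
        return np.empty(0, dtype=int)
    D = cdist(xy, xy)
    within = D <= eps
    core = within.sum(axis=1) >= N  # closed neighborhood includes self
    labels = np.full(n, -1, dtype=int)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            p = stack.pop()
            for q in np.nonzero(within[p] & core)[0]:
                if labels[q] < 0:
                    labels[q] = cid
                    stack.append(q)
        cid += 1
    for i in range(n):
        if core[i] or labels[i] >= 0:
            continue
        neigh_cores = np.nonzero(within[i] & core)[0]
        if neigh_cores.size:
            labels[i] = labels[neigh_cores.min()]
    return labels


def shoelace_hull_area(xy):
    """Monotone-chain hull + shoelace formula, independent of qhull."""
    pts = sorted(map(tuple, np.asarray(xy, dtype=float)))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    poly = lower[:-1] + upper[:-1]
    if len(poly) < 3:
        return 0.0
    area = 0.0
    for (x1, y1), (x2, y2) in zip(poly, poly[1:] + poly[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def canonical_partition(labels):
    """Partition as a frozenset of frozensets plus the noise set."""
    clusters = frozenset(
        frozenset(np.nonzero(labels == c)[0].tolist()) for c in set(labels) if c >= 0
    )
    noise = frozenset(np.nonzero(labels < 0)[0].tolist())
    return clusters, noise


# ------------------------------------------------------- dbscan_partition

class TestDbscanPartition:
    def test_single_dense_blob(self):
        xy = np.array([[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1]], dtype=float)
        labels = dbscan_partition(make_table(xy), epsilon=2.5, N=5)
        assert set(labels) == {0}

    def test_two_separated_blobs(self, rng):
        a = rng.normal(scale=5, size=(10, 2))
        b = rng.normal(scale=5, size=(10, 2)) + [1000, 0]
        labels = dbscan_partition(make_table(np.vstack([a, b])), epsilon=50, N=5)
        assert len(set(labels) - {-1}) == 2

    def test_empty_table(self):
        t = LocalizationTable(x=np.empty(0), y=np.empty(0))
        assert dbscan_partition(t, 10, 2).size == 0

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("eps,N", [(20, 3), (40, 5), (60, 10), (15, 2)])
    def test_matches_brute_force_oracle(self, seed, eps, N):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 400, size=(200, 2))
        got = dbscan_partition(make_table(xy), eps, N)
        want = brute_dbscan(xy, eps, N)
        np.testing.assert_array_equal(got, want)

    def test_matches_sklearn_on_core_structure(self, rng):
        """Independent cross-check: noise set and core partition agree with
        scikit-learn's DBSCAN (border ties aside, which sklearn resolves by
        expansion order)."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        xy = rng.uniform(0, 300, size=(250, 2))
        eps, N = 25, 4
        ours = dbscan_partition(make_table(xy), eps, N)
        sk = sklearn_cluster.DBSCAN(eps=eps, min_samples=N).fit(xy)
        assert set(np.nonzero(ours < 0)[0]) == set(np.nonzero(sk.labels_ < 0)[0])
        core = np.zeros(len(xy), dtype=bool)
        core[sk.core_sample_indices_] = True
        ours_core = canonical_partition(np.where(core, ours, -1))[0]
        sk_core = canonical_partition(np.where(core, sk.labels_, -1))[0]
        assert ours_core == sk_core

    def test_noise_set_shrinks_with_epsilon(self, random_table):
        prev = None
        for eps in [10, 20, 40, 80]:
            labels = dbscan_partition(random_table, eps, 4)
            noise = set(np.nonzero(labels < 0)[0])
            if prev is not None:
                assert noise <= prev
            prev = noise

    def test_core_set_shrinks_with_n(self, random_table):
        xy = random_table.xy
        D = cdist(xy, xy)
        prev = None
        for N in [2, 4, 8, 16]:
            core = set(np.nonzero((D <= 30).sum(axis=1) >= N)[0])
            labels = dbscan_partition(random_table, 30, N)
            clustered = set(np.nonzero(labels >= 0)[0])
            assert core <= clustered | set()
            if prev is not None:
                assert core <= prev
            prev = core

    def test_rigid_motion_invariance(self, rng):
        xy = rng.uniform(0, 300, size=(150, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = xy @ R.T + [12345.0, -678.0]
        a = dbscan_partition(make_table(xy), 30, 4)
        b = dbscan_partition(make_table(moved), 30, 4)
        # partitions agree as set families (cluster ids may permute)
        assert canonical_partition(a) == canonical_partition(b)


# ------------------------------------------------------------ hull_area

class TestHullArea:
    def test_unit_square(self):
        assert hull_area(np.array([[0, 0], [1, 0], [1, 1], [0, 1]])) == pytest.approx(1.0)

    def test_collinear_is_zero(self):
        assert hull_area(np.array([[0, 0], [1, 1], [2, 2]])) == 0.0

    def test_fewer_than_three_points(self):
        assert hull_area(np.array([[0, 0], [5, 5]])) == 0.0
        assert hull_area(np.array([[3, 4]])) == 0.0

    def test_empty_is_domain_error(self):
        with pytest.raises(ValueError):
            hull_area(np.empty((0, 2)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_shoelace_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 100, size=(50, 2))
        got = hull_area(xy)
        assert got == pytest.approx(shoelace_hull_area(xy), rel=1e-9)
        # and against qhull's own area
        assert got == pytest.approx(ConvexHull(xy).volume, rel=1e-9)


# ------------------------------------------------------ summarize_clusters

class TestSummarizeClusters:
    def _records(self, table, eps, N):
        return cluster_records(table, dbscan_partition(table, eps, N))

    def test_single_cluster_sd_zero(self):
        xy = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        recs = self._records(make_table(xy), 2.0, 3)
        s = summarize_clusters(recs, 2.0, 3)
        assert s.n_clusters == 1
        assert s.sd_area == 0.0 and s.sd_nloc == 0.0

    def test_two_item_population_sd(self, rng):
        a = rng.normal(scale=2, size=(10, 2))
        b = rng.normal(scale=2, size=(20, 2)) + [1000, 0]
        recs = self._records(make_table(np.vstack([a, b])), 20, 5)
        s = summarize_clusters(recs, 20, 5)
        assert s.n_clusters == 2
        assert s.av_nloc == pytest.approx(15.0)
        assert s.sd_nloc == pytest.approx(5.0)

    def test_empty_cell_is_nan(self):
        s = summarize_clusters([], 10, 5)
        assert s.n_clusters == 0
        assert np.isnan(s.av_area) and np.isnan(s.sd_nloc)

    def test_matches_direct_recomputation(self, rng):
        xy = rng.uniform(0, 600, size=(300, 2))
        recs = self._records(make_table(xy), 40, 4)
        s = summarize_clusters(recs, 40, 4)
        areas = np.array([r.hull_area for r in recs])
        nlocs = np.array([r.n_loc for r in recs])
        assert s.av_area == pytest.approx(areas.mean())
        assert s.sd_area == pytest.approx(areas.std())
        assert s.av_nloc == pytest.approx(nlocs.mean())
        assert s.sd_nloc == pytest.approx(nlocs.std())


# ------------------------------------------------------------- scan_grid

SMALL_GRID = GridSpec(epsilons=np.array([10.0, 25.0, 40.0, 60.0]), Ns=np.array([2, 4, 8]))


class TestScanGrid:
    def test_empty_table(self):
        t = LocalizationTable(x=np.empty(0), y=np.empty(0))
        stack = scan_grid(t, SMALL_GRID)
        assert np.all(stack.maps["n_clusters"] == 0)
        for m in ("av_area", "sd_area", "av_nloc", "sd_nloc"):
            assert np.all(np.isnan(stack.maps[m]))

    def test_zero_min_area_is_identity(self, random_table):
        a = scan_grid(random_table, SMALL_GRID, min_area=0)
        b = scan_grid(random_table, SMALL_GRID)
        for m in a.maps:
            np.testing.assert_array_equal(a.maps[m], b.maps[m])

    def test_multi_matches_separate_scans(self, random_table):
        unf, filt = scan_grid_multi(random_table, SMALL_GRID, min_areas=(None, 500.0))
        ref = scan_grid(random_table, SMALL_GRID, min_area=500.0)
        for m in ref.maps:
            np.testing.assert_array_equal(filt.maps[m], ref.maps[m])
        ref_u = scan_grid(random_table, SMALL_GRID)
        for m in ref_u.maps:
            np.testing.assert_array_equal(unf.maps[m], ref_u.maps[m])

    @pytest.mark.parametrize("seed", range(3))
    def test_statistics_equal_brute_force_pipeline(self, seed):
        """Full-stack oracle: every cell's five statistics equal the dense
        brute-force DBSCAN + shoelace-hull pipeline exactly."""
        rng = np.random.default_rng(100 + seed)
        xy = rng.uniform(0, 500, size=(250, 2))
        stack = scan_grid(make_table(xy), SMALL_GRID)
        for i, eps in enumerate(SMALL_GRID.epsilons):
            for j, N in enumerate(SMALL_GRID.Ns):
                labels = brute_dbscan(xy, eps, N)
                cids = sorted(set(labels) - {-1})
                areas = np.array(
                    [shoelace_hull_area(xy[labels == c]) for c in cids]
                )
                assert stack.maps["n_clusters"][i, j] == len(cids)
                if cids:
                    assert stack.maps["av_area"][i, j] == pytest.approx(areas.mean(), rel=1e-9)
                    assert stack.maps["sd_area"][i, j] == pytest.approx(areas.std(), rel=1e-9, abs=1e-9)
                    nlocs = np.array([(labels == c).sum() for c in cids])
                    assert stack.maps["av_nloc"][i, j] == pytest.approx(nlocs.mean())
                    assert stack.maps["sd_nloc"][i, j] == pytest.approx(nlocs.std())
                else:
                    assert np.isnan(stack.maps["av_area"][i, j])

    def test_av_nloc_at_least_n(self, random_table):
        stack = scan_grid(random_table, SMALL_GRID)
        for j, N in enumerate(SMALL_GRID.Ns):
            col = stack.maps["av_nloc"][:, j]
            assert np.all(col[np.isfinite(col)] >= N)

    def test_regime_structure_on_synthetic_pattern(self):
        """Cluster number along epsilon at moderate N rises, falls, then
        plateaus as DBSCAN resolves the nanofoci (regimes A/B/C)."""
        cfg = PatternConfig(seed=5)
        table, truth = simulate_pattern(cfg)
        grid = GridSpec.from_ranges(4, 88, 4, 2, 20, 2)
        stack = scan_grid(table, grid)
        j = list(grid.Ns).index(12)
        nc = stack.maps["n_clusters"][:, j]
        peak = int(np.argmax(nc))
        assert 0 < peak < nc.size - 5
        assert nc[peak] > nc[0]
        tail = nc[-5:]
        assert nc[peak] > tail.mean() * 1.5
        # plateau: flat tail compared to the rise/fall amplitude
        assert tail.std() < 0.15 * nc[peak]
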
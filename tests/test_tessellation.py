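"""Site estimation and Voronoi/quadratic partitioning of dense clouds."""

import numpy as np
import pytest

from aqvt import (
    CellSliceSet,
    Ellipsoid,
    QuadraticSiteSet,
    ShapeError,
    ValidationError,
    assign_euclidean,
    assign_quadratic,
    cell_hulls,
    estimate_centroid_sites,
    fit_mvee,
    fit_quadratic_sites,
)

OCTAHEDRON = np.array(
    [[2, 0, 0], [-2, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 3], [0, 0, -3]],
    dtype=float,
)


def _random_sites(rng, k, d=3):
    return [(i + 1, rng.uniform(0, 10, d)) for i in range(k)]


class TestCentroidSites:
    def test_arithmetic_mean(self):
        cell = CellSliceSet(1, np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 4]], float))
        [(cid, c)] = estimate_centroid_sites([cell])
        assert cid == 1
        np.testing.assert_allclose(c, [1, 1, 1])

    def test_single_point(self):
        [(_, c)] = estimate_centroid_sites([CellSliceSet(2, np.array([[5.0, 5, 5]]))])
        np.testing.assert_allclose(c, [5, 5, 5])

    def test_empty_cell_names_id(self):
        with pytest.raises(ValidationError, match="7"):
            estimate_centroid_sites([CellSliceSet(7, np.empty((0, 3)))])

    def test_order_preserved(self, rng):
        cells = [CellSliceSet(i, rng.normal(size=(4, 3))) for i in (9, 2, 5)]
        assert [cid for cid, _ in estimate_centroid_sites(cells)] == [9, 2, 5]


class TestFitQuadraticSites:
    def test_matches_fit_mvee_on_full_rank_cell(self):
        sites = fit_quadratic_sites([CellSliceSet(1, OCTAHEDRON)], tol=1e-6)
        direct = fit_mvee(OCTAHEDRON, tol=1e-6)
        np.testing.assert_allclose(sites[1].center, direct.ellipsoid.center, atol=1e-9)
        np.testing.assert_allclose(sites[1].shape, direct.ellipsoid.shape, atol=1e-9)
        assert not sites.degenerate_ids

    def test_single_slice_cell_is_jittered_and_flagged(self, rng):
        xy = rng.uniform(0, 4, size=(20, 2))
        pts = np.column_stack([xy, np.full(20, 3.0)])  # all in plane z=3
        eps = 0.3
        sites = fit_quadratic_sites([CellSliceSet(5, pts)], plane_epsilon=eps)
        assert sites.degenerate_ids == {5}
        lams, vecs = np.linalg.eigh(sites[5].shape)
        assert lams.min() > 0  # SPD
        # smallest semi-axis ~ plane_epsilon, aligned with z
        smallest_axis = 1 / np.sqrt(lams.max())
        assert eps * 0.9 <= smallest_axis <= 2.0 * eps
        z_dir = np.abs(vecs[:, np.argmax(lams)])
        assert z_dir[2] > 0.99

    def test_single_point_cell(self):
        sites = fit_quadratic_sites([CellSliceSet(3, np.array([[1.0, 2, 3]]))])
        assert sites.degenerate_ids == {3}
        np.testing.assert_allclose(sites[3].center, [1, 2, 3], atol=1e-6)

    def test_empty_cell_error_names_cell(self):
        cells = [CellSliceSet(1, OCTAHEDRON), CellSliceSet(4, np.empty((0, 3)))]
        with pytest.raises(ValidationError, match="4"):
            fit_quadratic_sites(cells)


class TestAssignEuclidean:
    def test_nearest_site_wins(self):
        sites = [(1, np.zeros(3)), (2, np.array([2.0, 0, 0]))]
        t = assign_euclidean(np.array([[0.9, 0, 0]]), sites)
        assert t.labels.tolist() == [1]

    def test_tie_breaks_to_smallest_id(self):
        sites = [(2, np.array([2.0, 0, 0])), (1, np.zeros(3))]
        t = assign_euclidean(np.array([[1.0, 0, 0]]), sites)
        assert t.labels.tolist() == [1]

    def test_matches_brute_force(self, rng):
        sites = _random_sites(rng, 5)
        cloud = rng.uniform(0, 10, size=(200, 3))
        t = assign_euclidean(cloud, sites)
        d = np.stack([np.sum((cloud - s) ** 2, axis=1) for _, s in sites])
        expected = np.array([sites[i][0] for i in np.argmin(d, axis=0)])
        assert np.array_equal(t.labels, expected)

    def test_duplicate_sites_rejected(self):
        sites = [(1, np.zeros(3)), (2, np.zeros(3))]
        with pytest.raises(ValidationError):
            assign_euclidean(np.array([[1.0, 0, 0]]), sites)

    def test_regions_are_convex_midpoint_property(self, rng):
        """For random same-label pairs, the midpoint shares the label."""
        sites = _random_sites(rng, 8)
        cloud = rng.uniform(0, 10, size=(4000, 3))
        t = assign_euclidean(cloud, sites)
        i = rng.integers(0, cloud.shape[0], 10_000)
        j = rng.integers(0, cloud.shape[0], 10_000)
        same = t.labels[i] == t.labels[j]
        mids = 0.5 * (cloud[i[same]] + cloud[j[same]])
        t_mid = assign_euclidean(mids, sites)
        assert np.array_equal(t_mid.labels, t.labels[i[same]])


class TestAssignQuadratic:
    def _sites(self, rng, k, iso=False):
        entries = []
        for i in range(k):
            if iso:
                M = np.eye(3)
            else:
                A = rng.normal(size=(3, 3))
                M = A @ A.T + 0.5 * np.eye(3)
            entries.append((i + 1, Ellipsoid(center=rng.uniform(0, 10, 3), shape=M)))
        return QuadraticSiteSet(entries=entries)

    def test_identity_metric_reduces_to_euclidean(self, rng):
        """With all shape matrices equal to I the quadratic diagram is the
        Euclidean Voronoi diagram; checked on 100 random instances."""
        for _ in range(100):
            ss = self._sites(rng, 4, iso=True)
            cloud = rng.uniform(0, 10, size=(50, 3))
            tq = assign_quadratic(cloud, ss)
            te = assign_euclidean(cloud, [(c, e.center) for c, e in ss.entries])
            assert np.array_equal(tq.labels, te.labels)

    def test_direct_distance_example(self):
        ss = QuadraticSiteSet(entries=[
            (1, Ellipsoid(center=np.zeros(3), shape=4 * np.eye(3))),
            (2, Ellipsoid(center=np.array([1.0, 0, 0]), shape=np.eye(3))),
        ])
        t = assign_quadratic(np.array([[0.4, 0, 0]]), ss)
        assert t.labels.tolist() == [2]  # d1 = 0.64 > d2 = 0.36

    @pytest.mark.parametrize("scale", [0.1, 0.5, 2.0, 7.0, 123.0])
    def test_global_metric_scaling_invariance(self, rng, scale):
        """Scaling all metrics by one positive scalar cannot change any
        argmin, so the tessellation is invariant — the fixed point of
        uniform ellipsoid deformation."""
        ss = self._sites(rng, 6)
        cloud = rng.uniform(0, 10, size=(500, 3))
        scaled = QuadraticSiteSet(entries=[
            (c, Ellipsoid(center=e.center, shape=scale * e.shape))
            for c, e in ss.entries
        ])
        assert np.array_equal(
            assign_quadratic(cloud, ss).labels,
            assign_quadratic(cloud, scaled).labels,
        )

    def test_partition_and_determinism(self, rng):
        ss = self._sites(rng, 5)
        cloud = rng.uniform(0, 10, size=(1000, 3))
        t1 = assign_quadratic(cloud, ss)
        t2 = assign_quadratic(cloud, ss)
        assert np.array_equal(t1.labels, t2.labels)  # bit-for-bit
        assert t1.labels.shape == (1000,)
        assert set(np.unique(t1.labels)) <= set(ss.cell_ids)

    def test_dimension_mismatch(self, rng):
        ss = self._sites(rng, 2)
        with pytest.raises(ShapeError):
            assign_quadratic(rng.uniform(size=(5, 2)), ss)

    def test_volumes_from_counts(self, rng):
        ss = self._sites(rng, 3)
        cloud = rng.uniform(0, 10, size=(300, 3))
        t = assign_quadratic(cloud, ss, point_volume=2.0)
        assert sum(t.per_cell_volume.values()) == pytest.approx(600.0)


class TestCellHulls:
    CUBE = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)],
                    dtype=float)

    def _tess(self, pts, labels):
        return __import__("aqvt").Tessellation(
            cloud=pts, labels=np.asarray(labels), site_set=[]
        )

    def test_unit_cube_hull(self):
        t = self._tess(self.CUBE, [1] * 8)
        meshes, failures = cell_hulls(t)
        assert not failures
        assert meshes[1]["volume"] == pytest.approx(1.0)
        assert meshes[1]["vertices"].shape[0] == 8

    def test_interior_point_does_not_change_hull(self):
        pts = np.vstack([self.CUBE, [0.5, 0.5, 0.5]])
        meshes, _ = cell_hulls(self._tess(pts, [1] * 9))
        assert meshes[1]["volume"] == pytest.approx(1.0)
        assert meshes[1]["vertices"].shape[0] == 8

    def test_underdetermined_cell_reported_not_dropped(self):
        pts = np.vstack([self.CUBE, np.eye(3)[:, :3][:3] * 0.1 + 5.0])
        labels = [1] * 8 + [2] * 3
        meshes, failures = cell_hulls(self._tess(pts, labels))
        assert 1 in meshes and 2 not in meshes
        assert 2 in failures
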
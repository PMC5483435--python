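"""Octree queries, mesh predicates and progressive selection correctness."""

import numpy as np
import pytest

import tractokit as tk
from tractokit.selection import _point_triangle_distances


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestPointIndex:
    def test_single_point(self, ref10):
        t = tk.Tractogram.from_arrays([[[1, 1, 1], [1, 1, 2]]], ref10)
        idx = tk.build_point_index(t)
        sids, pidx = idx.query_box([0, 0, 0], [3, 3, 3])
        assert sorted(zip(sids, pidx)) == [(0, 0), (0, 1)]

    def test_disjoint_box_empty(self, ref10):
        t = tk.Tractogram.from_arrays([[[1, 1, 1], [2, 2, 2]]], ref10)
        idx = tk.build_point_index(t)
        sids, _ = idx.query_box([5, 5, 5], [6, 6, 6])
        assert len(sids) == 0

    def test_matches_brute_force_on_random_boxes(self, rng):
        ref = tk.SpatialReference.isotropic((100, 100, 100), 1.0)
        pts = rng.uniform(0, 90, (10_000, 3))
        streamlines = [pts[i : i + 2] for i in range(0, 10_000, 2)]
        t = tk.Tractogram.from_arrays(streamlines, ref)
        idx = tk.build_point_index(t, leaf_capacity=32)
        flat = np.vstack(streamlines)
        for _ in range(100):
            lo = rng.uniform(0, 80, 3)
            hi = lo + rng.uniform(1, 20, 3)
            sids, pidx = idx.query_box(lo, hi)
            got = {(int(s), int(p)) for s, p in zip(sids, pidx)}
            inside = np.all((flat >= lo) & (flat <= hi), axis=1)
            expected = {(i // 2, i % 2) for i in np.flatnonzero(inside)}
            assert got == expected

    def test_every_point_indexed_once(self, phantom_suite):
        t = phantom_suite["arc"]
        idx = tk.build_point_index(t)
        assert idx.n_points == t.total_points
        sids, pidx = idx.query_box([-1e6] * 3, [1e6] * 3)
        assert len(set(zip(sids, pidx))) == t.total_points


class TestRoiConstruction:
    def test_unit_cube_aabb_and_triangles(self, unit_cube):
        np.testing.assert_allclose(unit_cube.aabb, [[-0.5] * 3, [0.5] * 3])
        assert len(unit_cube.triangles) == 12

    def test_5mm_cubic_roi(self):
        roi = tk.box_roi((10, 10, 10), (2.5, 2.5, 2.5))
        np.testing.assert_allclose(roi.aabb, [[7.5] * 3, [12.5] * 3])

    def test_unit_sphere_vertices_on_surface(self):
        roi = tk.ellipsoid_roi((1, 2, 3), (1, 1, 1))
        d = np.linalg.norm(roi.vertices - [1, 2, 3], axis=1)
        np.testing.assert_allclose(d, 1.0, atol=1e-6)

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(ValueError):
            tk.box_roi((0, 0, 0), (1, 1, 1), rotation=np.diag([2.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            tk.box_roi((0, 0, 0), (1, 1, 1), rotation=np.diag([-1.0, 1.0, 1.0]))

    def test_open_mesh_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        tris = np.array([[0, 1, 2], [0, 1, 3]])  # two faces only: not closed
        with pytest.raises(ValueError, match="watertight"):
            tk.RoiMesh(verts, tris)


class TestPointInMesh:
    def test_cube_inside_outside_boundary(self, unit_cube):
        assert tk.point_in_mesh((0, 0, 0), unit_cube)
        assert not tk.point_in_mesh((2, 0, 0), unit_cube)
        assert tk.point_in_mesh((0.5, 0.0, 0.0), unit_cube)  # face contact

    def test_matches_analytic_box_test(self, rng):
        rot = _random_rotation(rng)
        center = np.array([2.0, -1.0, 3.0])
        he = np.array([1.5, 0.8, 2.0])
        roi = tk.box_roi(center, he, rot)
        pts = center + rng.uniform(-3, 3, (1000, 3))
        got = tk.points_in_mesh(pts, roi)
        local = (pts - center) @ rot
        expected = np.all(np.abs(local) <= he + 1e-9, axis=1)
        np.testing.assert_array_equal(got, expected)

    def test_matches_analytic_ellipsoid_test(self, rng):
        roi = tk.ellipsoid_roi((0, 0, 0), (2.0, 1.0, 1.5), subdivisions=4)
        pts = rng.uniform(-2.5, 2.5, (500, 3))
        got = tk.points_in_mesh(pts, roi)
        q = np.sum((pts / [2.0, 1.0, 1.5]) ** 2, axis=1)
        # The icosphere is inscribed; ignore points within one facet's sagitta
        # of the surface where the polyhedral and analytic answers differ.
        clear = np.abs(q - 1.0) > 0.02
        np.testing.assert_array_equal(got[clear], (q <= 1.0)[clear])


def _segment_box_oracle(p0, p1, lo, hi):
    """Liang–Barsky slab clip: closed segment vs axis-aligned box."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if d[ax] == 0:
            if p0[ax] < lo[ax] - 1e-9 or p0[ax] > hi[ax] + 1e-9:
                return False
            continue
        ta = (lo[ax] - p0[ax]) / d[ax]
        tb = (hi[ax] - p0[ax]) / d[ax]
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
    return t0 <= t1 + 1e-9


class TestSegmentIntersectsMesh:
    def test_crossing_and_contained_segments(self, unit_cube):
        assert tk.segment_intersects_mesh((-1, 0, 0), (2, 0, 0), unit_cube)
        assert tk.segment_intersects_mesh((-0.1, 0, 0), (0.1, 0, 0), unit_cube)
        assert not tk.segment_intersects_mesh((2, 2, 2), (3, 3, 3), unit_cube)

    def test_degenerate_segment_rejected(self, unit_cube):
        with pytest.raises(ValueError):
            tk.segment_intersects_mesh((1, 1, 1), (1, 1, 1), unit_cube)

    def test_matches_slab_oracle_on_random_segments(self, rng):
        lo, hi = np.array([1.0, 2.0, 0.5]), np.array([3.0, 3.5, 2.5])
        roi = tk.box_roi((lo + hi) / 2, (hi - lo) / 2)
        p0 = rng.uniform(-1, 5, (2000, 3))
        p1 = rng.uniform(-1, 5, (2000, 3))
        got = tk.segments_intersect_mesh(p0, p1, roi)
        expected = np.array(
            [_segment_box_oracle(a, b, lo, hi) for a, b in zip(p0, p1)]
        )
        # Skip grazing cases where the answers may differ within tolerance.
        robust = np.ones(len(p0), dtype=bool)
        for i in np.flatnonzero(got != expected):
            mid_ok = _segment_box_oracle(p0[i], p1[i], lo - 1e-6, hi + 1e-6) != \
                _segment_box_oracle(p0[i], p1[i], lo + 1e-6, hi - 1e-6)
            robust[i] = not mid_ok
        np.testing.assert_array_equal(got[robust], expected[robust])


def _random_roi(rng, center):
    jitter = rng.uniform(-5, 5, 3)
    if rng.random() < 0.5:
        return tk.box_roi(center + jitter, rng.uniform(1.5, 4.0, 3), _random_rotation(rng))
    return tk.ellipsoid_roi(center + jitter, rng.uniform(1.5, 4.0, 3), _random_rotation(rng))


class TestProgressiveSelection:
    def test_point_phase_finds_interior_point(self, ref10):
        t = tk.Tractogram.from_arrays([[[0.5, 0.5, 0.5], [0.6, 0.5, 0.5]]], ref10)
        roi = tk.box_roi((0.5, 0.5, 0.5), (0.5, 0.5, 0.5))
        res = tk.select_progressive(t, tk.build_point_index(t), roi, 5.0)
        assert res.phase1_ids == {0} and not res.phase2_ids

    def test_segment_phase_catches_spanning_streamline(self, ref10):
        # No point inside the cube [0,1]^3, but the segment crosses it.
        t = tk.Tractogram.from_arrays([[[-1, 0.5, 0.5], [2, 0.5, 0.5]]], ref10)
        roi = tk.box_roi((0.5, 0.5, 0.5), (0.5, 0.5, 0.5))
        res = tk.select_progressive(t, tk.build_point_index(t), roi, 5.0)
        assert res.phase2_ids == {0} and not res.phase1_ids

    def test_complete_mode_matches_brute_force(self, rng, phantom_suite):
        params = tk.LinearizationParams(met=0.3, mld=10.0)
        for t in phantom_suite.values():
            compressed, _ = tk.linearize_tractogram(t, params)
            center = np.vstack(t.streamlines).mean(axis=0)
            for tract in (t, compressed):
                roi = _random_roi(rng, center)
                idx = tk.build_point_index(tract)
                res = tk.select_progressive(tract, idx, roi, "complete")
                assert res.selected == frozenset(tk.brute_force_select(tract, roi))
                assert res.phase1_ids <= res.selected

    def test_heuristic_never_exceeds_complete_and_monotone_in_L(self, rng, phantom_suite):
        t, _ = tk.linearize_tractogram(
            phantom_suite["random_walk"], tk.LinearizationParams(met=0.3, mld=10.0)
        )
        idx = tk.build_point_index(t)
        center = np.vstack(t.streamlines).mean(axis=0)
        stats = tk.segment_stats(t)
        for _ in range(5):
            roi = _random_roi(rng, center)
            heur = tk.select_progressive(t, idx, roi, "heuristic")
            comp = tk.select_progressive(t, idx, roi, "complete")
            assert heur.selected <= comp.selected
            prev = heur.selected
            for L in np.linspace(stats.mean_len, stats.max_len, 4):
                cur = tk.select_progressive(t, idx, roi, float(L)).selected
                assert prev <= cur
                prev = cur

    def test_phase_counters_respect_boxes(self, phantom_suite):
        t = phantom_suite["straight"]
        idx = tk.build_point_index(t)
        center = np.vstack(t.streamlines).mean(axis=0)
        roi = tk.box_roi(center, (2.5, 2.5, 2.5))
        res = tk.select_progressive(t, idx, roi, "complete")
        lo, hi = roi.aabb
        flat = np.vstack(t.streamlines)
        n_in_roi_box = int(np.all((flat >= lo) & (flat <= hi), axis=1).sum())
        L = res.neighborhood_mm
        n_in_ext = int(np.all((flat >= lo - L) & (flat <= hi + L), axis=1).sum())
        assert res.n_points_phase1 == n_in_roi_box
        assert res.n_points_phase2 <= n_in_ext  # already-selected excluded

    def test_compression_disagreements_lie_near_surface(self, rng, phantom_suite):
        # Streamlines where selection on original vs linearized tractograms
        # disagree must pass within met of the ROI surface.
        met = 0.3
        params = tk.LinearizationParams(met=met, mld=10.0)
        for t in phantom_suite.values():
            compressed, _ = tk.linearize_tractogram(t, params)
            center = np.vstack(t.streamlines).mean(axis=0)
            roi = _random_roi(rng, center)
            orig_sel = tk.brute_force_select(t, roi)
            comp_sel = tk.select_progressive(
                compressed, tk.build_point_index(compressed), roi, "complete"
            ).selected
            for sid in orig_sel ^ comp_sel:
                s = t.streamlines[sid]
                # densely resample the original polyline and take the min
                # distance to the mesh surface
                dense = []
                for a, b in zip(s[:-1], s[1:]):
                    dense.append(a + np.linspace(0, 1, 20)[:, None] * (b - a))
                dense = np.vstack(dense)
                dmin = _point_triangle_distances(dense, roi).min()
                assert dmin <= met + 0.05  # resampling slack

    def test_explicit_nonpositive_L_rejected(self, ref10):
        t = tk.Tractogram.from_arrays([[[1, 1, 1], [2, 2, 2]]], ref10)
        with pytest.raises(ValueError):
            tk.select_progressive(t, tk.build_point_index(t),
                                  tk.box_roi((0, 0, 0), (1, 1, 1)), 0.0)


class TestBruteForce:
    def test_empty_and_all_inside(self, ref10):
        roi = tk.box_roi((5, 5, 5), (4, 4, 4))
        assert tk.brute_force_select(tk.Tractogram([], ref10), roi) == set()
        t = tk.Tractogram.from_arrays(
            [[[4, 4, 4], [5, 5, 5]], [[6, 6, 6], [7, 7, 7]]], ref10
        )
        assert tk.brute_force_select(t, roi) == {0, 1}


class TestMissedFraction:
    @pytest.mark.parametrize(
        "point,complete,expected",
        [(1527, 1548, 1.36), (1605, 1655, 3.02), (1076, 1562, 31.11), (7, 7, 0.0)],
    )
    def test_values(self, point, complete, expected):
        assert tk.missed_fraction(point, complete) == pytest.approx(expected)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            tk.missed_fraction(5, 0)
        with pytest.raises(ValueError):
            tk.missed_fraction(10, 5)
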
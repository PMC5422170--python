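"""Unit and oracle tests for the contour/key-point geometry stage."""

import numpy as np
import pytest
from skimage.draw import polygon as draw_polygon

from conftest import ellipse_mask, random_seed_spec
from paddyid import geometry as geo
from paddyid import synthetic as syn
from paddyid.errors import ConcavityError, ContourError, GeometryError


def brute_force_diameter(points):
    """All-pairs oracle for the longest chord (exact integer arithmetic)."""
    pts = np.unique(np.asarray(points, dtype=np.int64), axis=0)
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    best = d2.max()
    pairs = []
    for i, j in zip(*np.nonzero(d2 == best)):
        a, b = pts[i], pts[j]
        if (a[0], a[1]) > (b[0], b[1]):
            a, b = b, a
        pairs.append((a[0], a[1], b[0], b[1]))
    r0, c0, r1, c1 = min(pairs)
    return np.array([r0, c0]), np.array([r1, c1]), float(np.sqrt(best))


def brute_force_hull_vertices(points):
    """O(n^3) oracle: support-line test for every point pair.

    A pair spans a support line if all points lie on one side; of the
    points collinear on that line only the two extremes are hull
    vertices (matching the collinear-exclusion contract).
    """
    pts = np.unique(np.asarray(points, dtype=np.int64), axis=0)
    n = len(pts)
    verts = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            e = pts[j] - pts[i]
            d = pts - pts[i]
            cross = e[0] * d[:, 1] - e[1] * d[:, 0]
            if (cross >= 0).all() or (cross <= 0).all():
                on_line = pts[cross == 0]
                proj = on_line @ e
                verts.add(tuple(on_line[np.argmin(proj)]))
                verts.add(tuple(on_line[np.argmax(proj)]))
    return verts


class TestTraceContour:
    def test_solid_square_boundary_in_order(self):
        c = geo.trace_contour(np.ones((3, 3), dtype=bool))
        assert c.tolist() == [
            [0, 0], [0, 1], [0, 2], [1, 2], [2, 2], [2, 1], [2, 0], [1, 0],
        ]

    def test_single_pixel(self):
        m = np.zeros((3, 3), dtype=bool)
        m[1, 1] = True
        assert geo.trace_contour(m).tolist() == [[1, 1]]

    def test_thin_bar_out_and_back(self):
        m = np.zeros((3, 7), dtype=bool)
        m[1, 1:6] = True
        c = geo.trace_contour(m)
        # closed out-and-back trace visiting each end exactly once
        assert c.tolist() == [
            [1, 1], [1, 2], [1, 3], [1, 4], [1, 5], [1, 4], [1, 3], [1, 2],
        ]

    def test_neighbors_and_closure(self, default_silhouette):
        mask, _ = default_silhouette
        c = geo.trace_contour(mask)
        steps = np.abs(np.diff(np.vstack([c, c[:1]]), axis=0)).max(axis=1)
        assert (steps == 1).all()  # consecutive points are 8-neighbours
        rows, cols = np.nonzero(mask)
        assert tuple(c[0]) == (rows[0], cols[0])  # topmost-then-leftmost start

    def test_empty_and_multi_component_raise(self):
        with pytest.raises(ContourError):
            geo.trace_contour(np.zeros((4, 4), bool))
        m = np.zeros((8, 8), bool)
        m[0, 0] = m[5, 5] = True
        with pytest.raises(ContourError):
            geo.trace_contour(m)


class TestLongestChord:
    def test_three_four_five_triangle(self):
        pts = np.array([[0, 0], [3, 4]])
        A, B, length = geo.longest_chord(pts)
        assert length == 5.0
        assert A.tolist() == [0, 0] and B.tolist() == [3, 4]

    @pytest.mark.parametrize("a,b,expected", [(60, 25, 120.0), (40, 40, 80.0)])
    def test_digitized_ellipse_diameter(self, a, b, expected):
        c = geo.trace_contour(ellipse_mask(a, b))
        _, _, length = geo.longest_chord(c)
        oa, ob, olen = brute_force_diameter(c)
        assert length == olen  # oracle equivalence, exact
        assert abs(length - expected) <= 1.0

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_brute_force_on_random_point_sets(self, trial):
        rng = np.random.default_rng(trial)
        pts = rng.integers(0, 60, size=(50, 2))
        A, B, length = geo.longest_chord(pts)
        oa, ob, olen = brute_force_diameter(pts)
        assert length == olen
        assert A.tolist() == oa.tolist() and B.tolist() == ob.tolist()

    def test_single_point_raises(self):
        with pytest.raises(GeometryError):
            geo.longest_chord(np.array([[2, 2], [2, 2]]))


class TestPerpendicularChord:
    def test_ellipse_minor_axis(self):
        c = geo.trace_contour(ellipse_mask(60, 25))
        A, B, _ = geo.longest_chord(c)
        _, _, length = geo.perpendicular_chord(c, A, B, 0.5)
        assert abs(length - 50.0) <= 1.0

    def test_circle_bisector_is_diameter(self):
        c = geo.trace_contour(ellipse_mask(40, 40))
        A, B, _ = geo.longest_chord(c)
        _, _, length = geo.perpendicular_chord(c, A, B, 0.5)
        assert abs(length - 80.0) <= 1.0

    def test_ellipse_fifth_position_chord(self):
        # chord of the ellipse at x = -0.6 a: 2 b sqrt(1 - 0.36)
        c = geo.trace_contour(ellipse_mask(60, 25))
        A, B, _ = geo.longest_chord(c)
        _, _, length = geo.perpendicular_chord(c, A, B, 0.2)
        assert abs(length - 2 * 25 * 0.8) <= 1.0

    def test_coincident_endpoints_raise(self):
        c = geo.trace_contour(ellipse_mask(20, 10))
        with pytest.raises(GeometryError):
            geo.perpendicular_chord(c, np.array([0, 0]), np.array([0, 0]), 0.5)


class TestConvexHull:
    def test_square_with_edge_midpoints(self):
        pts = np.array(
            [[0, 0], [0, 4], [4, 4], [4, 0], [0, 2], [2, 4], [4, 2], [2, 0]]
        )
        hull = geo.convex_hull(pts)
        assert {tuple(p) for p in hull} == {(0, 0), (0, 4), (4, 4), (4, 0)}

    def test_clockwise_order_in_image_coordinates(self):
        hull = geo.convex_hull(np.array([[0, 0], [0, 4], [4, 4], [4, 0]]))
        # shoelace in (row, col) is positive for clockwise-on-screen order
        p = hull.astype(float)
        q = np.roll(p, -1, axis=0)
        area2 = np.sum(p[:, 1] * q[:, 0] - q[:, 1] * p[:, 0])
        assert area2 > 0

    @pytest.mark.parametrize("trial", range(6))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        pts = rng.integers(0, 40, size=(50, 2))
        hull = geo.convex_hull(pts)
        assert {tuple(p) for p in hull} == brute_force_hull_vertices(pts)

    def test_collinear_points_degenerate_hull(self):
        pts = np.array([[1, 1], [2, 2], [3, 3], [5, 5]])
        hull = geo.convex_hull(pts)
        assert {tuple(p) for p in hull} == {(1, 1), (5, 5)}

    def test_contains_all_points(self, default_silhouette):
        mask, _ = default_silhouette
        c = geo.trace_contour(mask)
        hull = geo.convex_hull(c).astype(float)
        q = np.roll(hull, -1, axis=0)
        for p, pn in zip(hull, q):
            e = pn - p
            d = c - p
            cross = e[0] * d[:, 1] - e[1] * d[:, 0]
            assert (cross >= -1e-9).all() or (cross <= 1e-9).all()


def rect_with_notches(depths):
    """Rectangle whose top edge carries notches of the given depths.

    The notch shoulders follow a strictly convex arch so each shoulder
    is a convex-hull vertex and each notch gets its own hull bridge; the
    apex of each notch sits at the exact perpendicular depth below its
    bridge chord.
    """
    width = 60.0 * len(depths)

    def shoulder(x):
        # strictly convex arch, highest mid-span
        return np.array([x, -3.0 - 0.002 * x * (width - x)])

    verts = [np.array([0.0, 0.0])]
    for i, d in enumerate(depths):
        s1 = shoulder(60.0 * i + 15.0)
        s2 = shoulder(60.0 * i + 45.0)
        e = s2 - s1
        n = np.array([-e[1], e[0]]) / np.linalg.norm(e)
        if n[1] < 0:
            n = -n  # into the rectangle
        verts += [s1, (s1 + s2) / 2 + d * n, s2]
    verts += [np.array([width, 0.0]), np.array([width, 40.0]), np.array([0.0, 40.0])]
    verts = np.array(verts)
    rows = verts[:, 1] + 25.0
    cols = verts[:, 0] + 5.0
    mask = np.zeros((72, int(width) + 12), dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=mask.shape)
    mask[rr, cc] = True
    return mask


class TestConcaves:
    def test_convex_shape_has_no_concavities(self):
        c = geo.trace_contour(ellipse_mask(60, 25))
        with pytest.raises(ConcavityError):
            geo.find_concaves(c)

    def test_constructed_depths_recovered(self):
        mask, gt = syn.make_silhouette(
            syn.SyntheticSeedSpec(notch_depth_K=8.0, notch_depth_L=5.0)
        )
        g = geo.build_seed_geometry(mask)
        assert abs(g.d_K - 8.0) <= 0.75
        assert abs(g.d_L - 5.0) <= 0.75

    def test_third_shallow_notch_ignored(self):
        mask = rect_with_notches([9, 2, 6])
        c = geo.trace_contour(mask)
        rk, rl = geo.find_concaves(c)
        assert abs(rk.depth - 9) <= 0.75
        assert abs(rl.depth - 6) <= 0.75

    def test_depth_ordering_invariant(self):
        mask, _ = syn.make_silhouette(
            syn.SyntheticSeedSpec(notch_depth_K=5.0, notch_depth_L=8.0)
        )
        g = geo.build_seed_geometry(mask)
        assert g.d_K >= g.d_L  # K is the deeper concavity regardless of input order


class TestConcaveDepth:
    def test_point_to_line_distance(self):
        r = geo.ConcaveRegion(
            hull_start=np.array([0, 0]),
            hull_end=np.array([0, 10]),
            apex=np.array([-4, 5]),
            depth=4.0,
            arc=np.array([[0, 0], [-4, 5], [0, 10]]),
        )
        assert geo.concave_depth(r) == pytest.approx(4.0)

    def test_apex_on_edge_gives_zero(self):
        r = geo.ConcaveRegion(
            hull_start=np.array([0, 0]),
            hull_end=np.array([0, 10]),
            apex=np.array([0, 5]),
            depth=0.0,
            arc=np.array([[0, 0], [0, 5], [0, 10]]),
        )
        assert geo.concave_depth(r) == 0.0

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_max(self, trial):
        rng = np.random.default_rng(trial)
        arc = rng.normal(size=(30, 2)) * 5
        r = geo.ConcaveRegion(
            hull_start=arc[0], hull_end=arc[-1], apex=arc[0], depth=0.0, arc=arc
        )
        a, b = arc[0], arc[-1]
        e = b - a
        expected = max(
            abs(e[0] * (p - a)[1] - e[1] * (p - a)[0]) / np.linalg.norm(e)
            for p in arc
        )
        assert geo.concave_depth(r) == pytest.approx(expected)


class TestTipMetrics:
    def test_apex_distance_is_tip_width(self, default_geometry):
        g = default_geometry
        assert g.length_LK == pytest.approx(
            float(np.linalg.norm(g.region_K.apex - g.region_L.apex))
        )

    def test_three_four_five_apexes(self):
        K = np.array([6, 8])
        L = np.array([0, 0])
        assert float(np.linalg.norm(K - L)) == 10.0  # the metric used by LK

    @pytest.mark.parametrize(
        "v1,v2,expected",
        [((1, 0), (0, 1), 90.0), ((1, 0), (-1, 0), 180.0), ((1, 0), (1, 1), 45.0)],
    )
    def test_interior_angle_between_directions(self, v1, v2, expected):
        rk = geo.ConcaveRegion(
            hull_start=np.zeros(2), hull_end=np.array(v1, float),
            apex=np.zeros(2), depth=1.0, arc=np.zeros((1, 2)),
        )
        rl = geo.ConcaveRegion(
            hull_start=np.zeros(2), hull_end=np.array(v2, float),
            apex=np.zeros(2), depth=1.0, arc=np.zeros((1, 2)),
        )
        assert geo.interior_angle(rk, rl) == pytest.approx(expected)

    def test_zero_length_vector_raises(self):
        r = geo.ConcaveRegion(
            hull_start=np.zeros(2), hull_end=np.zeros(2),
            apex=np.zeros(2), depth=0.0, arc=np.zeros((1, 2)),
        )
        with pytest.raises(GeometryError):
            geo.interior_angle(r, r)


class TestBuildSeedGeometry:
    def test_feature_invariants(self, default_geometry):
        g = default_geometry
        assert g.length_CD <= g.length_AB
        assert g.d_K >= g.d_L >= 0
        assert g.h_c >= 0
        assert 0 <= g.phi <= 180
        assert np.allclose(g.O, (np.asarray(g.A, float) + np.asarray(g.B, float)) / 2)

    def test_tip_end_orientation(self, default_geometry):
        g = default_geometry
        tip_mid = (np.asarray(g.region_K.apex, float)
                   + np.asarray(g.region_L.apex, float)) / 2
        assert np.linalg.norm(g.A - tip_mid) <= np.linalg.norm(g.B - tip_mid)

    def test_ellipse_fails_at_concavity_stage(self):
        with pytest.raises(ConcavityError):
            geo.build_seed_geometry(ellipse_mask(60, 25))

    def test_rotation_and_translation_invariance(self, default_silhouette):
        mask, _ = default_silhouette
        ref = geo.build_seed_geometry(mask)
        ref_vals = np.array([ref.length_AB, ref.length_CD, ref.length_LK,
                             ref.h_c, ref.d_K, ref.d_L])
        for k in (1, 2, 3):
            rot = geo.build_seed_geometry(np.rot90(mask, k))
            vals = np.array([rot.length_AB, rot.length_CD, rot.length_LK,
                             rot.h_c, rot.d_K, rot.d_L])
            assert np.abs(vals - ref_vals).max() <= 0.5
            assert abs(rot.phi - ref.phi) <= 1.0
        shifted = geo.build_seed_geometry(np.pad(mask, ((7, 0), (3, 0))))
        assert shifted.length_AB == ref.length_AB
        assert shifted.d_K == ref.d_K and shifted.phi == ref.phi

    def test_geometry_dict_export_is_complete(self, default_geometry):
        d = default_geometry.to_dict()
        for key in ("A", "B", "C", "D", "K", "L", "K_u", "K_d", "L_u", "L_d",
                    "length_AB", "length_CD", "length_LK", "h_c", "d_K", "d_L",
                    "phi", "length_P1P2", "length_P3P4"):
            assert key in d

    def test_recovers_generator_ground_truth(self):
        rng = np.random.default_rng(77)
        spec = random_seed_spec(rng)
        mask, gt = syn.make_silhouette(spec)
        g = geo.build_seed_geometry(mask)
        assert abs(g.length_AB - gt.len_AB) <= 2.0
        assert abs(g.length_CD - gt.len_CD) <= 2.0
        assert abs(g.length_LK - gt.len_LK) <= 2.5
        assert abs(g.h_c - gt.h_c) <= 2.5
        assert abs(g.d_K - gt.d_K) <= 2.5
        assert abs(g.d_L - gt.d_L) <= 2.5
        assert abs(g.phi - gt.phi) <= 6.0
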
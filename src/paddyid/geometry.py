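"""Key-point morphometrics of a single-seed silhouette.

The silhouette contour is traced pixel by pixel, and a small set of key
lines and key points is derived from it:

* ``AB`` — the longest chord of the contour (the silhouette diameter),
  with midpoint ``O``;
* ``CD`` — the chord perpendicular to ``AB`` through ``O`` (the
  perpendicular bisector); auxiliary perpendicular chords ``P1P2`` and
  ``P3P4`` at the 1/5 and 4/5 positions along ``AB``;
* the convex hull of the contour and the two deepest concave regions
  (convexity defects) flanking the chaff tip, each described by its
  hull bridge (``K_u``–``K_d`` / ``L_u``–``L_d``), its apex (``K`` /
  ``L``) and its perpendicular depth (``d_K`` / ``d_L``);
* the chaff-tip width ``LK`` (apex-to-apex), the tip height ``h_c``
  above the ``LK`` line, and the interior angle ``phi`` between the
  directions ``K→K_d`` and ``L→L_d``.

All coordinates are 0-based ``(row, col)`` with pixel centres at integer
coordinates; lengths are Euclidean in pixel units and angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import ConcavityError, ContourError, GeometryError

__all__ = [
    "GeometryConfig",
    "ConcaveRegion",
    "SeedGeometry",
    "trace_contour",
    "longest_chord",
    "perpendicular_chord",
    "convex_hull",
    "find_concaves",
    "concave_depth",
    "chaff_tip_metrics",
    "interior_angle",
    "build_seed_geometry",
]

@dataclass
class GeometryConfig:
    """Tunables of the geometric feature extraction."""

    #: Minimum convexity-defect depth (pixels) for a contour region to
    #: count as one of the chaff-tip concavities; suppresses
    #: rasterization jitter along smooth hull arcs.
    min_concavity_depth: float = 1.0


@dataclass
class ConcaveRegion:
    """One concave region of the contour (a convexity defect).

    ``hull_start``/``hull_end`` are the two consecutive convex-hull
    vertices bridging the region (the ``u`` and ``d`` crucial points),
    ``apex`` is the contour point of maximum perpendicular deficiency
    from the bridge, and ``depth`` that maximum distance.
    """

    hull_start: np.ndarray
    hull_end: np.ndarray
    apex: np.ndarray
    depth: float
    #: full contour arc between the bridge endpoints, inclusive
    arc: np.ndarray = field(repr=False)
    #: contour index of the arc start (used only for tie-breaking)
    start_index: int = 0


@dataclass
class SeedGeometry:
    """All key points, key lines and scalar features of one silhouette."""

    contour: np.ndarray = field(repr=False)
    A: np.ndarray = None
    B: np.ndarray = None
    O: np.ndarray = None
    length_AB: float = 0.0
    C: np.ndarray = None
    D: np.ndarray = None
    length_CD: float = 0.0
    #: unlabeled half-lengths |CO| and |DO| (which half crosses the lemma
    #: vs. the palea is not decidable from the silhouette alone)
    half_CO: float = 0.0
    half_DO: float = 0.0
    P1: np.ndarray = None
    P2: np.ndarray = None
    length_P1P2: float = 0.0
    P3: np.ndarray = None
    P4: np.ndarray = None
    length_P3P4: float = 0.0
    hull: np.ndarray = field(default=None, repr=False)
    region_K: ConcaveRegion = None
    region_L: ConcaveRegion = None
    length_LK: float = 0.0
    h_c: float = 0.0
    d_K: float = 0.0
    d_L: float = 0.0
    phi: float = 0.0

    def to_dict(self) -> dict:
        """JSON-serializable record of the named points and scalars."""

        def pt(p):
            return None if p is None else [float(p[0]), float(p[1])]

        return {
            "A": pt(self.A),
            "B": pt(self.B),
            "O": pt(self.O),
            "C": pt(self.C),
            "D": pt(self.D),
            "P1": pt(self.P1),
            "P2": pt(self.P2),
            "P3": pt(self.P3),
            "P4": pt(self.P4),
            "K": pt(self.region_K.apex),
            "K_u": pt(self.region_K.hull_start),
            "K_d": pt(self.region_K.hull_end),
            "L": pt(self.region_L.apex),
            "L_u": pt(self.region_L.hull_start),
            "L_d": pt(self.region_L.hull_end),
            "length_AB": float(self.length_AB),
            "length_CD": float(self.length_CD),
            "half_CO": float(self.half_CO),
            "half_DO": float(self.half_DO),
            "length_P1P2": float(self.length_P1P2),
            "length_P3P4": float(self.length_P3P4),
            "length_LK": float(self.length_LK),
            "h_c": float(self.h_c),
            "d_K": float(self.d_K),
            "d_L": float(self.d_L),
            "phi": float(self.phi),
        }


def trace_contour(m: np.ndarray) -> np.ndarray:
    """Trace the closed outer boundary of a single-component mask.

    Moore-neighbour tracing with Jacob's stopping criterion, starting at
    the topmost-then-leftmost boundary pixel and proceeding clockwise in
    image coordinates.  One-pixel-wide spurs are traversed out and back,
    so points may repeat.  Returns an ``(N, 2)`` integer array of
    ``(row, col)`` points.
    """
    from scipy import ndimage

    m = np.asarray(m, dtype=bool)
    if not m.any():
        raise ContourError("empty mask")
    _, n = ndimage.label(m, structure=np.ones((3, 3), dtype=bool))
    if n != 1:
        raise ContourError(f"mask has {n} components, expected exactly 1")

    rows, cols = np.nonzero(m)
    # padded copy removes bounds checks from the hot loop
    mp = np.zeros((m.shape[0] + 2, m.shape[1] + 2), dtype=bool)
    mp[1:-1, 1:-1] = m
    grid = mp.tolist()
    offsets = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    dir_index = {d: i for i, d in enumerate(offsets)}

    start = (int(rows[0]) + 1, int(cols[0]) + 1)  # row-major first, padded coords
    backtrack0 = (start[0], start[1] - 1)  # entered heading east
    contour = [start]
    current, backtrack = start, backtrack0
    first_move = None
    max_steps = 4 * len(rows) + 8
    for _ in range(max_steps):
        i = dir_index[(backtrack[0] - current[0], backtrack[1] - current[1])]
        prev = backtrack
        nxt = None
        for k in range(1, 9):
            dr, dc = offsets[(i + k) % 8]
            q = (current[0] + dr, current[1] + dc)
            if grid[q[0]][q[1]]:
                nxt = q
                break
            prev = q
        if nxt is None:  # isolated single pixel
            break
        if first_move is None:
            first_move = nxt
        elif current == start and nxt == first_move:
            break  # the directed edge repeats: the closed trace is complete
        current, backtrack = nxt, prev
        contour.append(current)
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return np.array(contour, dtype=np.int64) - 1


def _unique_points(points: np.ndarray) -> np.ndarray:
    return np.unique(np.asarray(points), axis=0)


def longest_chord(c: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Longest chord (diameter) over all pairs of contour points.

    Returns ``(A, B, length)``.  Among ties, the lexicographically
    smallest ordered pair ``(A, B)`` with ``A <= B`` in row-major order
    is chosen.  The search is restricted to convex-hull vertices, which
    always contain every diameter endpoint; tests verify equivalence
    with the all-pairs brute force.
    """
    pts = _unique_points(c)
    if len(pts) < 2:
        raise GeometryError("contour has fewer than 2 distinct points", stage="longest_chord")
    cand = convex_hull(pts)
    if len(cand) < 2:
        cand = pts
    cand = cand.astype(np.int64)
    diff = cand[:, None, :] - cand[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)  # exact integer squared distances
    best = d2.max()
    ii, jj = np.nonzero(d2 == best)
    pairs = []
    for i, j in zip(ii, jj):
        a, b = cand[i], cand[j]
        if (a[0], a[1]) > (b[0], b[1]):
            a, b = b, a
        pairs.append((a[0], a[1], b[0], b[1]))
    r0, c0, r1, c1 = min(pairs)
    A = np.array([r0, c0], dtype=np.int64)
    B = np.array([r1, c1], dtype=np.int64)
    return A, B, float(np.sqrt(best))


def perpendicular_chord(
    c: np.ndarray, A: np.ndarray, B: np.ndarray, frac: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Chord of the contour polygon perpendicular to AB at a fraction of AB.

    The line through ``A + frac * (B - A)``, perpendicular to ``AB``, is
    intersected with the closed contour polygon; the maximal-span pair of
    intersection points and their distance are returned.  ``frac = 1/2``
    yields the perpendicular bisector chord ``CD``.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if np.allclose(A, B):
        raise GeometryError("A and B coincide", stage="perpendicular_chord")
    pts = np.asarray(c, dtype=np.float64)
    u = (B - A) / np.linalg.norm(B - A)          # along AB
    v = np.array([-u[1], u[0]])                  # perpendicular direction
    p0 = A + frac * (B - A)
    s = (pts - p0) @ u                           # signed offset along AB from the cut line
    nxt = np.roll(np.arange(len(pts)), -1)
    crossings: list[np.ndarray] = []
    for i, j in zip(range(len(pts)), nxt):
        si, sj = s[i], s[j]
        if si == 0.0:
            crossings.append(pts[i])
        elif (si < 0 < sj) or (sj < 0 < si):
            t = si / (si - sj)
            crossings.append(pts[i] + t * (pts[j] - pts[i]))
    if len(crossings) < 2:
        raise GeometryError("cut line does not cross the contour twice",
                            stage="perpendicular_chord")
    q = np.array(crossings)
    tproj = (q - p0) @ v
    lo, hi = int(np.argmin(tproj)), int(np.argmax(tproj))
    length = float(tproj[hi] - tproj[lo])
    if length <= 0.0:
        raise GeometryError("degenerate perpendicular chord", stage="perpendicular_chord")
    return q[lo], q[hi], length


def convex_hull(c: np.ndarray) -> np.ndarray:
    """Convex-hull vertices of the contour, clockwise in image coordinates.

    Collinear points interior to hull edges are excluded.  Degenerate
    inputs (all points equal or collinear) return the extreme point(s).
    The vertex sequence starts at the topmost-then-leftmost vertex.
    """
    pts = _unique_points(c).astype(np.float64)
    if len(pts) == 1:
        return pts.astype(np.int64) if np.allclose(pts, np.rint(pts)) else pts
    xy = pts[:, ::-1]  # (x=col, y=row); qhull order is then clockwise on screen
    try:
        hull = ConvexHull(xy)
        verts = pts[hull.vertices]
    except QhullError:  # collinear: return the two extreme points
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        verts = pts[order[[0, -1]]]
        if np.allclose(verts[0], verts[-1]):
            verts = verts[:1]
    # canonical start: topmost-then-leftmost vertex
    k = int(np.lexsort((verts[:, 1], verts[:, 0]))[0])
    verts = np.roll(verts, -k, axis=0)
    if np.allclose(verts, np.rint(verts)):
        verts = np.rint(verts).astype(np.int64)
    return verts


def _point_line_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Perpendicular distances from points to the line through a and b."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    e = b - a
    n = np.linalg.norm(e)
    if n == 0.0:
        return np.linalg.norm(np.asarray(points, dtype=np.float64) - a, axis=1)
    d = np.asarray(points, dtype=np.float64) - a
    return np.abs(d[:, 0] * e[1] - d[:, 1] * e[0]) / n


def find_concaves(
    c: np.ndarray, hull: np.ndarray | None = None, min_depth: float = 1.0
) -> tuple[ConcaveRegion, ConcaveRegion]:
    """Locate the two deepest concave regions of the contour.

    For every pair of consecutive convex-hull vertices the maximum
    perpendicular deficiency of the intervening contour arc from the
    hull bridge is computed; the two regions with the largest
    deficiencies are returned, the deeper one first (``R_K``).  Ties are
    broken toward the earlier contour position; the apex is the earliest
    arc point attaining the maximum.

    Raises :class:`ConcavityError` if fewer than two regions exceed
    ``min_depth``.
    """
    c = np.asarray(c)
    if hull is None:
        hull = convex_hull(c)
    # map each hull vertex to its first occurrence on the contour
    first_index: dict[tuple, int] = {}
    for idx, p in enumerate(map(tuple, c)):
        if p not in first_index:
            first_index[p] = idx
    try:
        hull_idx = sorted(first_index[tuple(p)] for p in np.asarray(hull, dtype=np.int64))
    except KeyError as exc:
        raise ConcavityError(f"hull vertex {exc} not on contour") from exc
    n = len(c)
    regions: list[ConcaveRegion] = []
    for a_i, b_i in zip(hull_idx, hull_idx[1:] + [hull_idx[0] + n]):
        span = np.arange(a_i, b_i + 1) % n
        if len(span) <= 2:
            continue
        arc = c[span]
        d = _point_line_distance(arc, arc[0], arc[-1])
        apex_k = int(np.argmax(d))
        depth = float(d[apex_k])
        if depth > min_depth:
            regions.append(
                ConcaveRegion(
                    hull_start=np.array(arc[0]),
                    hull_end=np.array(arc[-1]),
                    apex=np.array(arc[apex_k]),
                    depth=depth,
                    arc=arc,
                    start_index=int(a_i),
                )
            )
    if len(regions) < 2:
        raise ConcavityError("concavities not found")
    regions.sort(key=lambda r: (-r.depth, r.start_index))
    return regions[0], regions[1]


def concave_depth(r: ConcaveRegion) -> float:
    """Maximum perpendicular distance of the arc from the hull bridge."""
    d = _point_line_distance(r.arc, r.hull_start, r.hull_end)
    return float(d.max()) if len(d) else 0.0


def _polygon_centroid(c: np.ndarray) -> np.ndarray:
    """Centroid of the closed contour polygon (shoelace formula)."""
    p = np.asarray(c, dtype=np.float64)
    q = np.roll(p, -1, axis=0)
    cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
    area6 = 3.0 * cross.sum()
    if abs(area6) < 1e-9:  # degenerate (zero-area) polygon
        return p.mean(axis=0)
    return ((p + q) * cross[:, None]).sum(axis=0) / area6


def chaff_tip_metrics(
    c: np.ndarray, region_K: ConcaveRegion, region_L: ConcaveRegion
) -> tuple[float, float]:
    """Chaff-tip width ``LK`` and height ``h_c``.

    ``LK`` is the distance between the two concavity apexes.  ``h_c`` is
    the maximum perpendicular distance from the tip arc to the line
    ``LK``, where the tip arc is the contour arc between the apexes
    whose points lie on the opposite side of line ``LK`` from the
    silhouette centroid.
    """
    K = np.asarray(region_K.apex, dtype=np.float64)
    L = np.asarray(region_L.apex, dtype=np.float64)
    if np.allclose(K, L):
        raise GeometryError("concavity apexes coincide", stage="chaff_tip_metrics")
    lk_len = float(np.linalg.norm(K - L))

    pts = np.asarray(c, dtype=np.float64)
    e = K - L
    nvec = np.array([-e[1], e[0]]) / np.linalg.norm(e)
    offset = (pts - L) @ nvec
    centroid_side = float((_polygon_centroid(c) - L) @ nvec)
    if centroid_side > 0:  # make positive offsets point away from the body
        offset = -offset

    def first_index(p):
        return int(np.nonzero((c == np.rint(p).astype(c.dtype)).all(axis=1))[0][0])

    i, j = first_index(K), first_index(L)
    n = len(pts)
    arc1 = np.arange(i, j + 1) % n if j >= i else np.arange(i, j + n + 1) % n
    arc2 = np.arange(j, i + 1) % n if i >= j else np.arange(j, i + n + 1) % n
    h1 = offset[arc1].max() if len(arc1) else 0.0
    h2 = offset[arc2].max() if len(arc2) else 0.0
    h_c = float(max(h1, h2, 0.0))
    return lk_len, h_c


def interior_angle(region_K: ConcaveRegion, region_L: ConcaveRegion) -> float:
    """Angle in degrees between directions ``K→K_d`` and ``L→L_d``.

    ``K_d``/``L_d`` are the ``hull_end`` bridge points of the regions
    (the endpoints away from the chaff tip once the regions have been
    oriented).  The result is folded into [0, 180].
    """
    vk = np.asarray(region_K.hull_end, dtype=np.float64) - np.asarray(
        region_K.apex, dtype=np.float64
    )
    vl = np.asarray(region_L.hull_end, dtype=np.float64) - np.asarray(
        region_L.apex, dtype=np.float64
    )
    nk, nl = np.linalg.norm(vk), np.linalg.norm(vl)
    if nk == 0.0 or nl == 0.0:
        raise GeometryError("zero-length direction vector", stage="interior_angle")
    cosang = np.clip(vk @ vl / (nk * nl), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _orient_region_toward(r: ConcaveRegion, tip: np.ndarray) -> ConcaveRegion:
    """Label bridge endpoints so hull_start (u) is nearer the tip end."""
    d_start = np.linalg.norm(np.asarray(r.hull_start, float) - tip)
    d_end = np.linalg.norm(np.asarray(r.hull_end, float) - tip)
    if d_end < d_start:
        r = ConcaveRegion(
            hull_start=r.hull_end,
            hull_end=r.hull_start,
            apex=r.apex,
            depth=r.depth,
            arc=r.arc[::-1],
            start_index=r.start_index,
        )
    return r


def build_seed_geometry(m: np.ndarray, cfg: GeometryConfig | None = None) -> SeedGeometry:
    """Run the full geometric pipeline on a single-seed binary mask.

    Stages: contour trace, longest chord, perpendicular chords at 1/2,
    1/5 and 4/5, convex hull, concavity search, chaff-tip metrics and
    interior angle.  ``A`` is oriented to the chord endpoint nearer the
    chaff tip (the midpoint of the two concavity apexes), and the
    ``P1P2``/``P3P4`` auxiliary chords are labelled from that end.
    """
    cfg = cfg or GeometryConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (GeometryError, ConcavityError, ContourError):
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise GeometryError(str(exc), stage=name) from exc

    contour = stage("trace_contour", trace_contour, m)
    A, B, len_ab = stage("longest_chord", longest_chord, contour)
    hull = stage("convex_hull", convex_hull, contour)
    try:
        rk, rl = find_concaves(contour, hull, min_depth=cfg.min_concavity_depth)
    except ConcavityError as exc:
        raise ConcavityError(f"[find_concaves] {exc}") from exc

    tip_mid = (np.asarray(rk.apex, float) + np.asarray(rl.apex, float)) / 2.0
    if np.linalg.norm(B - tip_mid) < np.linalg.norm(A - tip_mid):
        A, B = B, A
    O = (np.asarray(A, float) + np.asarray(B, float)) / 2.0

    C, D, len_cd = stage("perpendicular_chord", perpendicular_chord, contour, A, B, 0.5)
    P1, P2, len_p12 = stage("perpendicular_chord", perpendicular_chord, contour, A, B, 0.2)
    P3, P4, len_p34 = stage("perpendicular_chord", perpendicular_chord, contour, A, B, 0.8)

    rk = _orient_region_toward(rk, np.asarray(A, float))
    rl = _orient_region_toward(rl, np.asarray(A, float))

    lk_len, h_c = stage("chaff_tip_metrics", chaff_tip_metrics, contour, rk, rl)
    phi = stage("interior_angle", interior_angle, rk, rl)

    return SeedGeometry(
        contour=contour,
        A=np.asarray(A),
        B=np.asarray(B),
        O=O,
        length_AB=len_ab,
        C=C,
        D=D,
        length_CD=len_cd,
        half_CO=float(np.linalg.norm(C - O)),
        half_DO=float(np.linalg.norm(D - O)),
        P1=P1,
        P2=P2,
        length_P1P2=len_p12,
        P3=P3,
        P4=P4,
        length_P3P4=len_p34,
        hull=hull,
        region_K=rk,
        region_L=rl,
        length_LK=lk_len,
        h_c=h_c,
        d_K=rk.depth,
        d_L=rl.depth,
        phi=phi,
    )
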
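"""Synthetic seed silhouettes and renderings with known ground truth.

No public image set exists for the three paddy varieties the method was
developed on, so testing relies on a constructed silhouette family that
realizes every structure the geometry stage measures while keeping
closed-form ground truth:

* an **ellipse body** (semi-axes ``body_semi_major`` / ``body_semi_minor``);
* a **trapezoidal chaff tip** protruding ``tip_length`` beyond the body
  apex, with outer width ``tip_width``;
* two **flank concavities** between the tip corners and raised
  "shoulder" vertices on the body, each carrying a sharp V at its
  deepest point whose apex sits at an exact perpendicular depth below
  the convex-hull bridge chord — so the concavity depths ``d_K``/``d_L``,
  the tip width ``LK`` and height ``h_c`` and the interior angle ``phi``
  are known exactly from the construction.  The silhouette diameter
  ``AB`` and bisector chord ``CD`` are measured on the continuous
  polygon.  Tip corners, shoulders and V apexes are pronounced corners,
  so every key point stays localized to sub-pixel jitter after
  rasterization.

This family is a geometric stand-in, not a claim about real seed shape:
it emulates the lemma/palea body with its protruding chaff tip flanked
by two concavities, at the scale of a 640 x 480 single-seed image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon as ShapelyPolygon
from skimage.draw import polygon as draw_polygon

from .errors import PaddyIdError, SyntheticError
from .features import FEATURE_NAMES
from .geometry import GeometryConfig, build_seed_geometry, perpendicular_chord
from .features import extract_features

__all__ = [
    "SyntheticSeedSpec",
    "GroundTruth",
    "VarietySpec",
    "PopulationSample",
    "make_silhouette",
    "embed_mask",
    "render_image",
    "sample_population",
    "default_varieties",
]

_ARC_POINTS = 180  # ellipse-arc sampling density (chord sagitta < 0.02 px)


@dataclass
class SyntheticSeedSpec:
    """Parameters of one synthetic silhouette (pixels and degrees)."""

    body_semi_major: float = 150.0
    body_semi_minor: float = 55.0
    tip_length: float = 25.0
    tip_width: float = 30.0
    notch_depth_K: float = 9.0
    notch_depth_L: float = 6.0
    #: ellipse parameter degrees between the tip tangency point and the
    #: raised shoulder vertex that ends each flank concavity
    notch_angle: float = 6.0
    rotation: float = 0.0
    center: tuple[float, float] | None = None
    rng_seed: int = 0

    def validate(self) -> None:
        if not self.body_semi_major > self.body_semi_minor > 0:
            raise SyntheticError("need body_semi_major > body_semi_minor > 0")
        if self.notch_depth_K < 0 or self.notch_depth_L < 0:
            raise SyntheticError("notch depths must be >= 0")
        if self.tip_length < 0 or self.tip_length >= self.body_semi_major:
            raise SyntheticError("need 0 <= tip_length < body_semi_major")
        if not 4.0 <= self.notch_angle <= 40.0:
            raise SyntheticError("notch_angle must be in [4, 40] degrees")


@dataclass
class GroundTruth:
    """Continuous-geometry feature values implied by the construction."""

    len_AB: float
    len_CD: float
    len_LK: float | None
    h_c: float | None
    d_K: float | None
    d_L: float | None
    phi: float | None

    def features_array(self) -> np.ndarray:
        vals = [self.len_AB, self.len_CD, self.len_LK, self.h_c,
                self.d_K, self.d_L, self.phi]
        return np.array([np.nan if v is None else v for v in vals], dtype=np.float64)


def _tangency_angle(a: float, b: float, tip: np.ndarray) -> float:
    """Parameter angle of the upper tangent point on the ellipse from an
    external point (closed form via the unit-circle transform)."""
    u = np.array([tip[0] / a, tip[1] / b])
    r = np.linalg.norm(u)
    if r <= 1.0 + 1e-12:  # tip on or inside the body: degenerate, no setback
        return math.atan2(abs(u[1]), u[0])
    alpha = math.atan2(u[1], u[0])
    beta = math.acos(1.0 / r)
    return alpha + beta


#: outward offset (pixels) of the shoulder vertices above the ellipse;
#: large against pixel jitter, small against the concavity depths
_SHOULDER_BUMP = 2.5
#: half-width (pixels) and maximum rise of the sharp V at each
#: concavity apex; the V walls are steep so the apex pixel is unique
_V_HALF_WIDTH = 4.5
_V_RISE = 6.0
#: minimum sag (pixels) of the V-shoulder connectors below the bridge
#: chord, so rasterization jitter cannot push contour pixels outside
#: the chord and split the hull bridge
_V_MIN_SAG = 1.5
#: position of the concavity apex along the bridge chord (fraction from
#: the shoulder end)
_APEX_FRACTION = 0.5


def _build_polygon(spec: SyntheticSeedSpec) -> tuple[np.ndarray, dict]:
    """Construct the silhouette outline (counterclockwise, local x-y frame).

    The chaff tip is a trapezoid protruding beyond the body apex.  On
    each side, a concave region runs from the tip corner to a shoulder
    vertex raised ``_SHOULDER_BUMP`` px above the ellipse just behind
    the tangency point; the region descends to a sharp V whose apex
    lies at the specified perpendicular depth below the bridge chord
    (tip corner - shoulder), which the construction guarantees to be a
    convex-hull edge.  Returns the polygon vertices and the named
    construction points.
    """
    a, b = spec.body_semi_major, spec.body_semi_minor
    has_tip = spec.tip_length > 0 or spec.tip_width > 0

    if not has_tip and spec.notch_depth_K == 0 and spec.notch_depth_L == 0:
        theta = np.linspace(0.0, 2.0 * math.pi, _ARC_POINTS, endpoint=False)
        verts = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
        return verts, {}

    T_K = np.array([a + spec.tip_length, spec.tip_width / 2.0])
    T_L = np.array([a + spec.tip_length, -spec.tip_width / 2.0])
    tb = _tangency_angle(a, b, T_K) + math.radians(spec.notch_angle)
    if tb >= math.radians(120.0):
        raise SyntheticError("shoulder angle extends too far around the body")
    base = np.array([a * math.cos(tb), b * math.sin(tb)])
    out_n = np.array([b * math.cos(tb), a * math.sin(tb)])
    out_n = out_n / np.linalg.norm(out_n)  # outward ellipse normal
    S_K = base + _SHOULDER_BUMP * out_n
    S_L = S_K * np.array([1.0, -1.0])

    def notch_path(shoulder, corner, depth):
        """Vertices from shoulder to corner descending into the sharp V."""
        if depth <= 0:
            return [shoulder, corner], (shoulder + corner) / 2.0
        e = corner - shoulder
        c = np.linalg.norm(e)
        u = e / c
        n = np.array([-e[1], e[0]]) / c
        if n @ (-(shoulder + corner) / 2.0) < 0:
            n = -n  # point toward the body interior
        foot = shoulder + _APEX_FRACTION * c * u
        apex = foot + depth * n
        sag = max(depth - _V_RISE, min(_V_MIN_SAG, 0.5 * depth))
        p1 = foot - _V_HALF_WIDTH * u + sag * n
        p2 = foot + _V_HALF_WIDTH * u + sag * n
        return [shoulder, p1, apex, p2, corner], apex

    path_K, K = notch_path(S_K, T_K, spec.notch_depth_K)
    path_L, L = notch_path(S_L, T_L, spec.notch_depth_L)

    two_pi = 2.0 * math.pi
    theta = np.linspace(tb, two_pi - tb, _ARC_POINTS)[1:-1]
    arc = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
    # ccw: shoulder S_K, over the top and back to S_L, down the lower
    # concavity to T_L, across the tip edge to T_K, and back up the
    # upper concavity to S_K
    verts = np.vstack([S_K[None, :], arc] + [p[None, :] for p in path_L]
                      + [p[None, :] for p in path_K[::-1]])
    keep = np.ones(len(verts), dtype=bool)  # drop consecutive duplicates
    keep[1:] = np.linalg.norm(np.diff(verts, axis=0), axis=1) > 1e-9
    if np.linalg.norm(verts[0] - verts[-1]) <= 1e-9:
        keep[-1] = False
    verts = verts[keep]
    points = {"T_K": T_K, "T_L": T_L, "S_K": S_K, "S_L": S_L, "K": K, "L": L,
              "path_K": path_K, "path_L": path_L}
    return verts, points


def _polygon_diameter(verts: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    hull = ConvexHull(verts)
    hv = verts[hull.vertices]
    diff = hv[:, None, :] - hv[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    return float(math.sqrt(d2[i, j])), hv[i], hv[j]


def _check_construction(verts: np.ndarray, pts: dict, spec: SyntheticSeedSpec) -> None:
    poly = ShapelyPolygon(verts)
    if not poly.is_valid:
        raise SyntheticError("non-simple polygon from extreme parameters")
    if not pts:
        return
    hull = ConvexHull(verts)
    order = [tuple(np.round(verts[i], 9)) for i in hull.vertices]
    hv = set(order)

    def key(p):
        return tuple(np.round(p, 9))

    for name in ("T_K", "T_L", "S_K", "S_L"):
        if key(pts[name]) not in hv:
            raise SyntheticError(f"key corner {name} is not a hull vertex")
    n = len(order)
    adj = {frozenset((order[i], order[(i + 1) % n])) for i in range(n)}
    for sn, tn, an, depth in (("S_K", "T_K", "K", spec.notch_depth_K),
                              ("S_L", "T_L", "L", spec.notch_depth_L)):
        if depth <= 0:
            continue
        if key(pts[an]) in hv:
            raise SyntheticError(f"concavity apex {an} lies on the hull")
        if frozenset((key(pts[sn]), key(pts[tn]))) not in adj:
            raise SyntheticError(f"bridge {sn}-{tn} is not a hull edge")


def _ground_truth(verts: np.ndarray, pts: dict, spec: SyntheticSeedSpec) -> GroundTruth:
    len_ab, pa, pb = _polygon_diameter(verts)
    _, _, len_cd = perpendicular_chord(verts, pa, pb, 0.5)

    if not pts or (spec.notch_depth_K == 0 and spec.notch_depth_L == 0):
        return GroundTruth(len_AB=len_ab, len_CD=len_cd, len_LK=None,
                           h_c=None, d_K=None, d_L=None, phi=None)

    # K is the deeper concavity by convention
    if spec.notch_depth_K >= spec.notch_depth_L:
        K, S_K, dK = pts["K"], pts["S_K"], spec.notch_depth_K
        L, S_L, dL = pts["L"], pts["S_L"], spec.notch_depth_L
        tip_chain = [pts["path_K"][-2], pts["T_K"], pts["T_L"], pts["path_L"][-2]]
    else:
        K, S_K, dK = pts["L"], pts["S_L"], spec.notch_depth_L
        L, S_L, dL = pts["K"], pts["S_K"], spec.notch_depth_K
        tip_chain = [pts["path_L"][-2], pts["T_L"], pts["T_K"], pts["path_K"][-2]]

    len_lk = float(np.linalg.norm(K - L))
    # tip height: the chain K -> V wall -> tip corners -> V wall -> L is
    # piecewise linear, so the maximum distance from line LK is at a vertex
    e = K - L
    nvec = np.array([-e[1], e[0]]) / np.linalg.norm(e)
    centroid = np.asarray(ShapelyPolygon(verts).centroid.coords[0])
    sign = -1.0 if (centroid - L) @ nvec > 0 else 1.0
    cand = np.array([K, *tip_chain, L])
    h_c = max(0.0, float((sign * ((cand - L) @ nvec)).max()))

    # interior angle between the apex-to-shoulder directions (the
    # shoulders are the bridge endpoints away from the tip)
    vk, vl = S_K - K, S_L - L
    cosang = np.clip(vk @ vl / (np.linalg.norm(vk) * np.linalg.norm(vl)), -1.0, 1.0)
    phi = float(np.degrees(np.arccos(cosang)))
    return GroundTruth(len_AB=len_ab, len_CD=len_cd, len_LK=len_lk,
                       h_c=float(h_c), d_K=float(dK), d_L=float(dL), phi=phi)


def make_silhouette(spec: SyntheticSeedSpec) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize a silhouette and return it with its ground truth.

    The outline polygon is built in a local frame, checked for validity
    (simple polygon, notch bridges are hull edges), rotated and placed
    on a canvas just covering the shape (or around ``spec.center`` if
    given), and rasterized at pixel centres.  Ground truth is computed
    on the continuous polygon and is unaffected by rasterization.
    """
    spec.validate()
    verts, pts = _build_polygon(spec)
    _check_construction(verts, pts, spec)
    gt = _ground_truth(verts, pts, spec)

    rot = math.radians(spec.rotation)
    R = np.array([[math.cos(rot), -math.sin(rot)], [math.sin(rot), math.cos(rot)]])
    xy = verts @ R.T
    # map local (x, y) onto image (row, col) axes
    rc = np.column_stack([xy[:, 1], xy[:, 0]])
    margin = 5.0
    if spec.center is None:
        offset = margin - rc.min(axis=0)
    else:
        offset = np.asarray(spec.center, dtype=np.float64) - rc.mean(axis=0)
    rc = rc + offset
    shape = tuple(int(math.ceil(v)) + int(margin) for v in rc.max(axis=0))
    rr, cc = draw_polygon(rc[:, 0], rc[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    if not mask.any():
        raise SyntheticError("rasterization produced an empty mask")
    return mask, gt


def embed_mask(mask: np.ndarray, shape: tuple[int, int] = (480, 640)) -> np.ndarray:
    """Centre a silhouette mask on a larger canvas (default 640 x 480)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] > shape[0] or mask.shape[1] > shape[1]:
        raise PaddyIdError(f"mask {mask.shape} does not fit canvas {shape}")
    out = np.zeros(shape, dtype=bool)
    r0 = (shape[0] - mask.shape[0]) // 2
    c0 = (shape[1] - mask.shape[1]) // 2
    out[r0:r0 + mask.shape[0], c0:c0 + mask.shape[1]] = mask
    return out


def render_image(
    mask: np.ndarray,
    seed_color: tuple[int, int, int] = (150, 100, 50),
    bg_color: tuple[int, int, int] = (40, 60, 160),
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Paint a mask as a two-tone RGB image with optional Gaussian noise.

    Foreground pixels take ``seed_color``, background ``bg_color``
    (defaults emulate a brown seed on a blue stage); independent
    per-channel Gaussian noise of standard deviation ``noise_sd`` is
    added and the result clipped to [0, 255].
    """
    if tuple(seed_color) == tuple(bg_color):
        raise PaddyIdError("seed and background colors must differ")
    mask = np.asarray(mask, dtype=bool)
    img = np.empty(mask.shape + (3,), dtype=np.float64)
    img[mask] = seed_color
    img[~mask] = bg_color
    if noise_sd > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass
class VarietySpec:
    """Population distribution over silhouette parameters for one variety.

    Each entry of ``means``/``sds`` keys a :class:`SyntheticSeedSpec`
    field; parameters are drawn independently normal and clipped to the
    spec's validity bounds.  Stands in for a real seed population.
    """

    name: str
    means: dict[str, float]
    sds: dict[str, float] = field(default_factory=dict)

    def draw(self, rng: np.random.Generator) -> SyntheticSeedSpec:
        kwargs = {}
        for key, mu in self.means.items():
            sd = self.sds.get(key, 0.0)
            if sd < 0:
                raise SyntheticError("standard deviations must be >= 0")
            kwargs[key] = float(rng.normal(mu, sd)) if sd > 0 else float(mu)
        kwargs.setdefault("rotation", float(rng.uniform(0.0, 360.0)))
        return SyntheticSeedSpec(**kwargs)


@dataclass
class PopulationSample:
    """Labeled feature vectors sampled from variety populations."""

    features: np.ndarray  # (n, 7)
    labels: list[str]
    resampled: int = 0  # silhouettes that failed geometry and were redrawn

    def pairs(self):
        return list(zip(self.features, self.labels))


def sample_population(
    vs: VarietySpec, n: int, rng_seed: int | np.random.Generator = 0,
    geometry_cfg: GeometryConfig | None = None,
) -> PopulationSample:
    """Draw ``n`` silhouettes from a variety and extract their features.

    Silhouettes whose geometry fails (for example no detectable
    concavity) are redrawn, with the count reported; a failure rate
    above 50% raises ``degenerate variety spec``.
    """
    if n < 1:
        raise PaddyIdError("n must be >= 1")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    feats = np.empty((n, len(FEATURE_NAMES)))
    failures = 0
    got = 0
    while got < n:
        if failures > max(n, 10):
            raise SyntheticError("degenerate variety spec: failure rate > 50%")
        spec = vs.draw(rng)
        try:
            mask, _ = make_silhouette(spec)
            geom = build_seed_geometry(mask, geometry_cfg)
        except PaddyIdError:
            failures += 1
            continue
        feats[got] = extract_features(geom)
        got += 1
    return PopulationSample(features=feats, labels=[vs.name] * n, resampled=failures)


def default_varieties() -> list[VarietySpec]:
    """Three well-separated synthetic variety populations.

    Parameter means differ between varieties by many within-class
    standard deviations (class-mean separation >= 6 SDs in feature
    space), emulating the cleanly distinguishable populations the
    training regime assumes; the per-parameter SDs model biological
    spread plus measurement jitter at the pixel scale.
    """
    common_sds = {
        "body_semi_major": 1.5,
        "body_semi_minor": 1.0,
        "tip_length": 1.0,
        "tip_width": 1.0,
        "notch_depth_K": 0.25,
        "notch_depth_L": 0.25,
        "notch_angle": 0.4,
    }
    return [
        VarietySpec(
            name="variety-a",
            means={"body_semi_major": 150, "body_semi_minor": 55, "tip_length": 25,
                   "tip_width": 30, "notch_depth_K": 9.0, "notch_depth_L": 6.0,
                   "notch_angle": 6},
            sds=dict(common_sds),
        ),
        VarietySpec(
            name="variety-b",
            means={"body_semi_major": 165, "body_semi_minor": 50, "tip_length": 32,
                   "tip_width": 24, "notch_depth_K": 12.0, "notch_depth_L": 8.0,
                   "notch_angle": 8},
            sds=dict(common_sds),
        ),
        VarietySpec(
            name="variety-c",
            means={"body_semi_major": 140, "body_semi_minor": 62, "tip_length": 20,
                   "tip_width": 36, "notch_depth_K": 6.5, "notch_depth_L": 4.0,
                   "notch_angle": 5},
            sds=dict(common_sds),
        ),
    ]
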
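"""Worm-body canonicalization by inscribed tangent circles.

A bent worm silhouette is reduced to a chain of circles inscribed between its
two body edges.  Each circle carries a rigid (rotation + translation) map that
sends its centre onto the x-axis at the circle's cumulative midline arc
length; a neuron is mapped by every circle whose xy-projection contains it and
the images are averaged.  The vertical (z) dimension passes through unchanged
until a final isotropic rescale puts the body axis on x ∈ [0, 800] μm.

The construction: for edge curves r₋(s) and r₊(s′) (cubic splines through the
hull boundary, parameterized by normalized arc length), the signed gap between
a circle of radius t tangent to r₋ at s and the opposite edge is

    d(s, s′, t) = |r₋(s) + n̂₋(s) t − r₊(s′)| − t,

with n̂₋ the unit inward normal.  Minimizing over s′ and solving
d(s, t) = 0 in t yields the inscribed radius t(s) and centre
r₀(s) = r₋(s) + n̂₋(s) t(s).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import interpolate, optimize
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CANONICAL, CANONICAL_EXTENT, HullMask, NeuronPointCloud, ValidationError


class StraighteningError(RuntimeError):
    """Raised when a hull cannot be straightened (degenerate geometry)."""


# ---------------------------------------------------------------------------
# boundary extraction and splitting
# ---------------------------------------------------------------------------

def extract_boundary(mask: HullMask, smoothing: float | None = None,
                     n_samples: int = 2000) -> np.ndarray:
    """Sub-pixel closed boundary contour of the hull, in μm, CCW.

    The marching-squares contour of the binary grid is smoothed with a
    periodic cubic spline (smoothing factor proportional to pixel size, to
    remove pixelation steps while keeping the shape) and resampled densely.
    Returns an (n, 2) array of xy points; the contour is closed implicitly
    (last point != first).
    """
    from skimage import measure

    mask.validate()
    contours = measure.find_contours(mask.grid.astype(float), 0.5)
    if not contours:
        raise StraighteningError("no boundary contour found")
    contour = max(contours, key=len)
    # (row, col) -> (x, y) μm
    xy = np.column_stack([contour[:, 1], contour[:, 0]]) * mask.pixel_size
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    # enforce counter-clockwise orientation (positive shoelace area)
    area2 = np.sum(xy[:, 0] * np.roll(xy[:, 1], -1) - np.roll(xy[:, 0], -1) * xy[:, 1])
    if area2 < 0:
        xy = xy[::-1]
    if smoothing is None:
        # residual budget ~ a third of a pixel per vertex: removes
        # marching-squares stair-steps without visibly rounding true corners
        smoothing = len(xy) * (0.3 * mask.pixel_size) ** 2
    tck, _ = interpolate.splprep(xy.T, s=smoothing, per=1, k=3)
    u = np.linspace(0.0, 1.0, n_samples, endpoint=False)
    out = np.column_stack(interpolate.splev(u, tck))
    if _is_self_intersecting(out):
        raise StraighteningError("boundary self-intersects after smoothing")
    return out


def _is_self_intersecting(poly: np.ndarray) -> bool:
    try:
        from shapely.geometry import Polygon

        return not Polygon(poly).is_valid
    except Exception:  # pragma: no cover - shapely always present in practice
        return False


@dataclass
class EdgeCurvePair:
    """The two opposite body edges as arc-length cubic splines.

    ``r_minus`` runs from head to tail with the body interior on the side of
    the inward normal n̂₋(s) = (−ẏ, ẋ)/|ṙ|; ``r_plus`` runs head to tail
    along the opposite edge.  Both are parameterized on [0, 1] by normalized
    arc length.
    """

    tck_minus: tuple
    tck_plus: tuple
    head: np.ndarray
    tail: np.ndarray
    _plus_cache: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _plus_cache_u: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def minus(self, s) -> np.ndarray:
        return np.column_stack(interpolate.splev(np.atleast_1d(s), self.tck_minus))

    def plus(self, s) -> np.ndarray:
        return np.column_stack(interpolate.splev(np.atleast_1d(s), self.tck_plus))

    def minus_normal(self, s) -> np.ndarray:
        dx, dy = interpolate.splev(np.atleast_1d(s), self.tck_minus, der=1)
        n = np.column_stack([-dy, dx])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def plus_samples(self, n: int = 1024) -> tuple[np.ndarray, np.ndarray]:
        if self._plus_cache is None or len(self._plus_cache) != n:
            u = np.linspace(0.0, 1.0, n)
            self._plus_cache_u = u
            self._plus_cache = self.plus(u)
        return self._plus_cache_u, self._plus_cache


def _arclength_spline(points: np.ndarray, k: int = 3) -> tuple:
    """Fit an interpolating spline parameterized by normalized arc length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-12])
    points = points[keep]
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    u /= u[-1]
    tck, _ = interpolate.splprep(points.T, u=u, s=0.0, k=min(k, len(points) - 1))
    return tck


def edge_pair_from_polylines(minus: np.ndarray, plus: np.ndarray) -> EdgeCurvePair:
    """Build an :class:`EdgeCurvePair` from two head→tail edge polylines.

    ``minus`` must be oriented so that its inward normal (−ẏ, ẋ) points
    toward ``plus`` (for a tube along +x: ``minus`` is the lower edge, both
    traversed left to right).  Intended for analytic test geometries.
    """
    minus = np.asarray(minus, dtype=float)
    plus = np.asarray(plus, dtype=float)
    return EdgeCurvePair(
        _arclength_spline(minus), _arclength_spline(plus), minus[0], minus[-1]
    )


def split_boundary(contour: np.ndarray, min_elongation: float = 1.3) -> EdgeCurvePair:
    """Choose head/tail tip points and split the contour into the two edges.

    Tips are the pair of boundary points at maximal Euclidean separation,
    each refined to the nearest local curvature maximum.  A shape whose
    maximal diameter is not clearly larger than that of the equal-area disk
    (elongation below ``min_elongation``) has no stable tips and is rejected.
    """
    n = len(contour)
    # max-distance pair lies on the convex hull
    from scipy.spatial import ConvexHull, distance

    hull = ConvexHull(contour)
    hv = hull.vertices
    D = distance.cdist(contour[hv], contour[hv])
    i, j = np.unravel_index(np.argmax(D), D.shape)
    max_dist = D[i, j]
    area = hull.volume  # 2D hull "volume" is the area
    if max_dist < min_elongation * 2.0 * np.sqrt(area / np.pi):
        raise StraighteningError(
            "shape is not elongated; head/tail endpoints are unstable"
        )
    idx_a, idx_b = int(hv[i]), int(hv[j])
    idx_a = _refine_to_curvature_max(contour, idx_a)
    idx_b = _refine_to_curvature_max(contour, idx_b)
    if idx_a == idx_b:
        raise StraighteningError("degenerate endpoint pair")

    # deterministic orientation: head = endpoint with smaller x (then smaller y)
    pa, pb = contour[idx_a], contour[idx_b]
    if (pb[0], pb[1]) < (pa[0], pa[1]):
        idx_a, idx_b = idx_b, idx_a
    head, tail = contour[idx_a], contour[idx_b]

    # CCW arc head->tail is r_minus: traversed CCW, the left normal
    # (-dy, dx) points into the interior, matching the n̂₋ convention.
    if idx_a < idx_b:
        arc_minus = contour[idx_a:idx_b + 1]
        arc_plus = np.concatenate([contour[idx_b:], contour[:idx_a + 1]])[::-1]
    else:
        arc_minus = np.concatenate([contour[idx_a:], contour[:idx_b + 1]])
        arc_plus = contour[idx_b:idx_a + 1][::-1]
    if len(arc_minus) < 4 or len(arc_plus) < 4:
        raise StraighteningError("degenerate split: an edge has too few points")
    return EdgeCurvePair(
        _arclength_spline(arc_minus), _arclength_spline(arc_plus), head, tail
    )


def _refine_to_curvature_max(contour: np.ndarray, idx: int, window_frac: float = 0.05) -> int:
    """Snap an endpoint to the local curvature maximum of the polygonal contour."""
    n = len(contour)
    w = max(2, int(round(window_frac * n)))
    cand = (np.arange(idx - w, idx + w + 1)) % n
    prev = contour[(cand - 1) % n]
    cur = contour[cand]
    nxt = contour[(cand + 1) % n]
    v1 = cur - prev
    v2 = nxt - cur
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dots = np.einsum("ij,ij->i", v1, v2)
    turn = np.abs(np.arctan2(cross, dots))
    return int(cand[np.argmax(turn)])


# ---------------------------------------------------------------------------
# inscribed circles
# ---------------------------------------------------------------------------

def tangent_gap(edges: EdgeCurvePair, s: float, s_prime: float, t: float) -> float:
    """Signed gap d(s, s′, t) between the tangent circle and the opposite edge."""
    if not (0.0 <= s <= 1.0 and 0.0 <= s_prime <= 1.0):
        raise ValueError("s and s' must lie in [0, 1]")
    if t < 0:
        raise ValueError("t must be non-negative")
    center = edges.minus(s)[0] + edges.minus_normal(s)[0] * t
    return float(np.linalg.norm(center - edges.plus(s_prime)[0]) - t)


def _min_gap(edges: EdgeCurvePair, center: np.ndarray, t: float,
             n_dense: int = 1024) -> tuple[float, float]:
    """min over s′ of |center − r₊(s′)| − t, via dense sampling + local refine."""
    u, pts = edges.plus_samples(n_dense)
    d = np.linalg.norm(pts - center, axis=1)
    k = int(np.argmin(d))
    lo, hi = u[max(k - 1, 0)], u[min(k + 1, len(u) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda sp: float(np.linalg.norm(edges.plus(sp)[0] - center)),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        if res.fun < d[k]:
            return float(res.fun) - t, float(res.x)
    return float(d[k]) - t, float(u[k])


def solve_tangent_radius(
    edges: EdgeCurvePair, s: float,
    t_max: float | None = None, tol: float = 1e-3,
) -> tuple[float, float]:
    """Radius t(s) of the circle tangent to r₋ at s and touching r₊.

    Solves d(s, t) = 0 by bracketed root finding; d(s, t) is monotone
    non-increasing in t, so the bracket is expanded by doubling until the gap
    changes sign.  Returns ``(t, s_prime_star)``.  Raises if no root exists
    within ``t_max`` (typical near the body tips).
    """
    p = edges.minus(np.clip(s, 0.0, 1.0))[0]
    n = edges.minus_normal(np.clip(s, 0.0, 1.0))[0]

    def gap(t: float) -> tuple[float, float]:
        return _min_gap(edges, p + n * t, t)

    d0, sp0 = gap(0.0)
    if d0 <= tol:
        return max(d0, 0.0), sp0  # edges touch: degenerate sliver
    if t_max is None:
        span = np.linalg.norm(edges.tail - edges.head)
        t_max = span  # generous; tapered bodies never exceed their length
    t_hi = d0 / 2.0  # exact for locally parallel edges
    d_hi, sp_hi = gap(t_hi)
    while d_hi > 0:
        t_hi *= 2.0
        if t_hi > t_max:
            raise StraighteningError(f"no inscribed circle at s={s:.4f}")
        d_hi, sp_hi = gap(t_hi)
    t_lo = 0.0
    # bisection on the monotone gap
    while t_hi - t_lo > tol:
        t_mid = 0.5 * (t_lo + t_hi)
        d_mid, sp_mid = gap(t_mid)
        if d_mid > 0:
            t_lo = t_mid
        else:
            t_hi, sp_hi = t_mid, sp_mid
    return 0.5 * (t_lo + t_hi), sp_hi


@dataclass
class CircleChain:
    """Ordered inscribed circles with cumulative midline arc length (μm)."""

    centers: np.ndarray  # (n, 2)
    radii: np.ndarray  # (n,)
    s: np.ndarray  # (n,) edge parameter of each circle
    cumlen: np.ndarray  # (n,) arc length along the centre polyline

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        self.s = np.asarray(self.s, dtype=float).reshape(-1)
        self.cumlen = np.asarray(self.cumlen, dtype=float).reshape(-1)
        if np.any(self.radii <= 0):
            raise ValidationError("circle radii must be positive")
        if np.any(np.diff(self.s) < 0):
            raise ValidationError("circle ordering must be monotone in s")

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def midline_length(self) -> float:
        return float(self.cumlen[-1])

    def tangent_angles(self) -> np.ndarray:
        d = np.gradient(self.centers, axis=0)
        return np.arctan2(d[:, 1], d[:, 0])


def inscribe_circles(edges: EdgeCurvePair, n_circles: int = 1000,
                     n_solve: int | None = None) -> CircleChain:
    """Inscribe ``n_circles`` tangent circles, equally spaced in midline length.

    Radii are solved on a uniform grid of the edge parameter s (unsolvable
    values near the tips are skipped), then the circle family is resampled so
    adjacent centres are equidistant in cumulative arc length along the
    centre polyline.
    """
    if n_circles < 3:
        raise ValueError("need at least 3 circles")
    if n_solve is None:
        n_solve = max(n_circles, 128)
    grid = np.linspace(0.0, 1.0, n_solve + 2)[1:-1]
    ss, ts, cs = [], [], []
    for s in grid:
        try:
            t, _ = solve_tangent_radius(edges, s)
        except StraighteningError:
            continue
        if t <= 0:
            continue
        center = edges.minus(s)[0] + edges.minus_normal(s)[0] * t
        ss.append(s)
        ts.append(t)
        cs.append(center)
    if len(ss) < 3:
        raise StraighteningError("fewer than 3 solvable inscribed circles")
    s_arr = np.array(ss)
    t_arr = np.array(ts)
    c_arr = np.array(cs)
    # regularize the centre polyline: sub-pixel solver noise inflates the
    # cumulative arc length (every wiggle adds length), so fit a lightly
    # smoothing spline through the centres before measuring the midline
    if len(c_arr) >= 8:
        seg0 = np.linalg.norm(np.diff(c_arr, axis=0), axis=1)
        u0 = np.concatenate([[0.0], np.cumsum(seg0)])
        u0 /= max(u0[-1], 1e-12)
        tck, _ = interpolate.splprep(c_arr.T, u=u0, s=len(c_arr) * 0.15 ** 2, k=3)
        dense_u = np.linspace(0.0, 1.0, max(8 * len(c_arr), 1024))
        c_dense = np.column_stack(interpolate.splev(dense_u, tck))
        t_dense = np.interp(dense_u, u0, t_arr)
        s_dense = np.interp(dense_u, u0, s_arr)
    else:
        c_dense, t_dense, s_dense = c_arr, t_arr, s_arr
    seg = np.linalg.norm(np.diff(c_dense, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    # resample uniformly in midline arc length
    target = np.linspace(0.0, cum[-1], n_circles)
    centers = np.column_stack([np.interp(target, cum, c_dense[:, k]) for k in range(2)])
    radii = np.interp(target, cum, t_dense)
    s_out = np.interp(target, cum, s_dense)
    seg2 = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    cumlen = np.concatenate([[0.0], np.cumsum(seg2)])
    return CircleChain(centers, radii, s_out, cumlen)


# ---------------------------------------------------------------------------
# straightening map
# ---------------------------------------------------------------------------

@dataclass
class CanonicalTransform:
    """The straightening map: circle chain + final isotropic rescale."""

    chain: CircleChain
    scale: float = 1.0
    x_offset: float = 0.0  # pre-scale x of the head-most neuron
    target_lo: float = CANONICAL_EXTENT[0]
    flipped: bool = False

    def to_json(self, path: str | Path) -> None:
        obj = {
            "centers": self.chain.centers.tolist(),
            "radii": self.chain.radii.tolist(),
            "s": self.chain.s.tolist(),
            "cumlen": self.chain.cumlen.tolist(),
            "scale": self.scale,
            "x_offset": self.x_offset,
            "target_lo": self.target_lo,
            "flipped": self.flipped,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "CanonicalTransform":
        obj = json.loads(Path(path).read_text())
        chain = CircleChain(
            np.array(obj["centers"]), np.array(obj["radii"]),
            np.array(obj["s"]), np.array(obj["cumlen"]),
        )
        return cls(chain, obj["scale"], obj["x_offset"], obj["target_lo"], obj["flipped"])


def _map_points_pre_rescale(points_xy: np.ndarray, chain: CircleChain) -> np.ndarray:
    """Apply the per-circle rigid maps and average over containing circles."""
    angles = chain.tangent_angles()
    cos, sin = np.cos(angles), np.sin(angles)
    # rel[j, k, :] = p_j - c_k
    rel = points_xy[:, None, :] - chain.centers[None, :, :]
    dist = np.linalg.norm(rel, axis=2)
    inside = dist <= chain.radii[None, :]
    # rotate local tangent onto +x: R = [[cos, sin], [-sin, cos]]
    ux = rel[:, :, 0] * cos[None, :] + rel[:, :, 1] * sin[None, :]
    uy = -rel[:, :, 0] * sin[None, :] + rel[:, :, 1] * cos[None, :]
    img_x = chain.cumlen[None, :] + ux
    img_y = uy
    none_inside = ~inside.any(axis=1)
    if none_inside.any():
        nearest = np.argmin(dist[none_inside], axis=1)
        inside[none_inside, nearest] = True
    w = inside.astype(float)
    w /= w.sum(axis=1, keepdims=True)
    return np.column_stack([(img_x * w).sum(axis=1), (img_y * w).sum(axis=1)])


def straighten_points(
    points: NeuronPointCloud,
    chain: CircleChain,
    target_extent: tuple[float, float] | None = CANONICAL_EXTENT,
    flip_ap: bool = False,
) -> tuple[NeuronPointCloud, CanonicalTransform]:
    """Map a raw-frame cloud into the canonical straightened frame.

    Each neuron's xy is mapped by every circle whose disc contains it (or by
    the nearest circle if none does) and the rigid images are averaged; z is
    left unchanged.  With a ``target_extent``, all coordinates are then
    isotropically scaled so that the neuron x-range spans the extent.
    With ``target_extent=None`` the pre-rescale positions are returned
    (midline on y = 0, x = cumulative midline length).
    """
    if points.frame == CANONICAL:
        raise ValidationError("points are already in the canonical frame")
    if len(points) == 0:
        tf = CanonicalTransform(chain, 1.0, 0.0,
                                0.0 if target_extent is None else target_extent[0],
                                flip_ap)
        return points.with_positions(points.positions.copy(), frame=CANONICAL), tf

    xy = _map_points_pre_rescale(points.positions[:, :2], chain)
    if flip_ap:
        xy[:, 0] = chain.midline_length - xy[:, 0]
        xy[:, 1] = -xy[:, 1]
    out = np.column_stack([xy, points.positions[:, 2]])
    if target_extent is None:
        tf = CanonicalTransform(chain, 1.0, 0.0, 0.0, flip_ap)
        return points.with_positions(out, frame=CANONICAL), tf
    lo, hi = target_extent
    x0 = out[:, 0].min()
    span = out[:, 0].max() - x0
    scale = (hi - lo) / span if span > 0 else 1.0
    out[:, 0] = lo + (out[:, 0] - x0) * scale
    out[:, 1] *= scale
    out[:, 2] *= scale
    tf = CanonicalTransform(chain, scale, x0, lo, flip_ap)
    return points.with_positions(out, frame=CANONICAL), tf


def canonicalize_worm(
    mask: HullMask,
    points: NeuronPointCloud,
    n_circles: int = 1000,
    target_extent: tuple[float, float] | None = CANONICAL_EXTENT,
    flip_ap: bool = False,
) -> tuple[NeuronPointCloud, CanonicalTransform]:
    """End-to-end straightening: hull mask + raw cloud → canonical cloud."""
    contour = extract_boundary(mask)
    edges = split_boundary(contour)
    chain = inscribe_circles(edges, n_circles=n_circles)
    return straighten_points(points, chain, target_extent=target_extent, flip_ap=flip_ap)


def skeleton_straighten(mask: HullMask, points: NeuronPointCloud) -> NeuronPointCloud:
    """Basic benchmark baseline: x = arc length along the skeleton midline,
    y = signed perpendicular distance to it, z unchanged.  Provided only for
    comparison; the inscribed-circle map is the supported straightener."""
    from skimage.morphology import skeletonize

    skel = skeletonize(mask.grid)
    rr, cc = np.nonzero(skel)
    pts = np.column_stack([cc, rr]).astype(float) * mask.pixel_size
    # order skeleton pixels by walking from one extreme end
    order = _order_path(pts)
    path = pts[order]
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    out = points.positions.copy()
    for i, p in enumerate(points.positions):
        d = np.linalg.norm(path - p[:2], axis=1)
        k = int(np.argmin(d))
        tangent = path[min(k + 1, len(path) - 1)] - path[max(k - 1, 0)]
        tangent /= max(np.linalg.norm(tangent), 1e-12)
        offset = p[:2] - path[k]
        out[i, 0] = cum[k] + offset @ tangent
        out[i, 1] = offset[0] * -tangent[1] + offset[1] * tangent[0]
    return points.with_positions(out, frame=CANONICAL)


def _order_path(pts: np.ndarray) -> np.ndarray:
    """Greedy nearest-neighbour ordering of a (roughly) 1D point set."""
    from scipy.spatial import cKDTree

    start = int(np.argmax(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
    tree = cKDTree(pts)
    visited = np.zeros(len(pts), dtype=bool)
    order = [start]
    visited[start] = True
    cur = start
    for _ in range(len(pts) - 1):
        d, idx = tree.query(pts[cur], k=min(len(pts), 16))
        nxt = next((int(i) for i in np.atleast_1d(idx) if not visited[int(i)]), None)
        if nxt is None:
            rem = np.nonzero(~visited)[0]
            nxt = int(rem[np.argmin(np.linalg.norm(pts[rem] - pts[cur], axis=1))])
        order.append(nxt)
        visited[nxt] = True
        cur = nxt
    return np.array(order)


class WormStraightener(BaseEstimator, TransformerMixin):
    """Inscribed-circle worm straightener with a scikit-learn interface.

    ``fit`` consumes a :class:`HullMask` and builds the circle chain;
    ``transform`` maps raw-frame clouds (or bare (n, 3) position arrays) into
    the canonical straightened frame.

    Parameters
    ----------
    n_circles : int
        Number of inscribed circles, equally spaced in midline arc length.
    target_extent : (float, float) or None
        Canonical x-range after isotropic rescale; ``None`` skips the rescale.
    flip_ap : bool
        Reverse the anterior-posterior orientation of the canonical frame.

    Attributes
    ----------
    chain_ : CircleChain
        Fitted inscribed-circle chain.
    transform_ : CanonicalTransform
        Full map including the rescale fitted on the first transformed cloud.
    """

    def __init__(self, n_circles: int = 1000,
                 target_extent: tuple[float, float] | None = CANONICAL_EXTENT,
                 flip_ap: bool = False):
        self.n_circles = n_circles
        self.target_extent = target_extent
        self.flip_ap = flip_ap

    def fit(self, mask: HullMask, y=None) -> "WormStraightener":
        contour = extract_boundary(mask)
        edges = split_boundary(contour)
        self.edges_ = edges
        self.chain_ = inscribe_circles(edges, n_circles=self.n_circles)
        return self

    def transform(self, X) -> NeuronPointCloud:
        if not hasattr(self, "chain_"):
            raise RuntimeError("WormStraightener is not fitted")
        cloud = X if isinstance(X, NeuronPointCloud) else NeuronPointCloud(np.asarray(X))
        out, tf = straighten_points(
            cloud, self.chain_, target_extent=self.target_extent, flip_ap=self.flip_ap
        )
        self.transform_ = tf
        return out
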
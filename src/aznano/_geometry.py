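"""Shared planar-geometry primitives: alpha shapes, polygon moments, set covariance.

All coordinates are in nm. Polygons are shapely geometries; a MultiPolygon can
arise from an alpha shape at small alpha and is handled everywhere by summing
areas and, where a single outline is needed, taking the largest component.
"""

from __future__ import annotations

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .errors import DegenerateGeometryError

__all__ = [
    "alpha_shape",
    "largest_polygon",
    "smooth_polygon",
    "polygon_aspect_ratio",
    "points_in_polygon",
    "ray_boundary_distance",
    "pair_distance_probabilities",
]


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each Delaunay triangle (abc/4A; inf for degenerate)."""
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    area2 = np.abs(cross)
    with np.errstate(divide="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[area2 == 0] = np.inf
    return r


def alpha_shape(points: np.ndarray, alpha_radius_nm: float):
    """Alpha shape of a 2D point set.

    The alpha complex keeps every Delaunay triangle whose circumradius is at
    most ``alpha_radius_nm``; the shape is the union of the kept triangles.
    For ``alpha_radius_nm -> inf`` this is the convex hull.

    Returns ``(polygon, area_nm2)``. Raises :class:`DegenerateGeometryError`
    for fewer than 3 points or a collinear configuration, and when no triangle
    survives the alpha filter.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DegenerateGeometryError("alpha shape needs at least 3 planar points")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point configuration: {exc}") from exc
    keep = _circumradii(pts, tri.simplices) <= alpha_radius_nm
    if not keep.any():
        raise DegenerateGeometryError(
            "no triangle with circumradius <= alpha radius; points too sparse"
        )
    triangles = [Polygon(pts[s]) for s in tri.simplices[keep]]
    shape = unary_union(triangles)
    if shape.is_empty or shape.area == 0:
        raise DegenerateGeometryError("alpha shape has zero area")
    return shape, float(shape.area)


def largest_polygon(geom) -> Polygon:
    """The largest polygonal component of a (Multi)Polygon."""
    if isinstance(geom, MultiPolygon):
        return max(geom.geoms, key=lambda g: g.area)
    return geom


def smooth_polygon(geom, window: int = 3) -> Polygon:
    """Smooth a polygon outline with a cyclic moving average over its vertices."""
    poly = largest_polygon(geom)
    xy = np.asarray(poly.exterior.coords)[:-1]  # drop repeated closing vertex
    n = len(xy)
    if n < window or n < 4:
        return poly
    half = window // 2
    idx = (np.arange(n)[:, None] + np.arange(-half, half + 1)[None, :]) % n
    sm = xy[idx].mean(axis=1)
    out = Polygon(sm)
    if not out.is_valid or out.area == 0:
        return poly
    return out


def _polygon_moments(poly: Polygon):
    """Area, centroid and second area moments of a simple polygon (shoelace)."""
    xy = np.asarray(poly.exterior.coords)
    x0, y0 = xy[:-1, 0], xy[:-1, 1]
    x1, y1 = xy[1:, 0], xy[1:, 1]
    cross = x0 * y1 - x1 * y0
    area = cross.sum() / 2.0
    cx = ((x0 + x1) * cross).sum() / (6.0 * area)
    cy = ((y0 + y1) * cross).sum() / (6.0 * area)
    jx = ((x0 * x0 + x0 * x1 + x1 * x1) * cross).sum() / 12.0
    jy = ((y0 * y0 + y0 * y1 + y1 * y1) * cross).sum() / 12.0
    jxy = ((x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0) * cross).sum() / 24.0
    return abs(area), cx, cy, jx / area, jy / area, jxy / area


def polygon_aspect_ratio(geom) -> float:
    """Major/minor axis ratio of the second-moment ellipse of a polygon region.

    The covariance of the uniform distribution over the polygon interior is
    computed from the exact area moments; the ratio of the square roots of its
    eigenvalues equals the axis ratio of the equivalent ellipse (3.0 for a
    3:1 ellipse, 1.0 for a disc).
    """
    poly = largest_polygon(geom)
    area, cx, cy, jx, jy, jxy = _polygon_moments(poly)
    if area == 0:
        raise DegenerateGeometryError("zero-area polygon")
    cov = np.array([[jx - cx * cx, jxy - cx * cy], [jxy - cx * cy, jy - cy * cy]])
    ev = np.linalg.eigvalsh(cov)
    if ev[0] <= 0:
        raise DegenerateGeometryError("degenerate second-moment ellipse")
    return float(np.sqrt(ev[1] / ev[0]))


def points_in_polygon(geom, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Boundary-inclusive point-in-polygon mask (vectorized)."""
    pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
    return shapely.covers(geom, pts)


def ray_boundary_distance(geom, origin: np.ndarray, direction: np.ndarray, reach: float) -> float:
    """Distance from ``origin`` to the first boundary crossing along ``direction``.

    ``origin`` is assumed inside (or on) the polygon; ``reach`` must exceed the
    polygon extent so the ray is guaranteed to exit.
    """
    from shapely.geometry import LineString

    origin = np.asarray(origin, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    ray = LineString([origin, origin + d * reach])
    inter = ray.intersection(largest_polygon(geom).exterior)
    if inter.is_empty:
        raise DegenerateGeometryError("ray does not cross the polygon boundary")
    pts = []
    for g in getattr(inter, "geoms", [inter]):
        if g.geom_type == "Point":
            pts.append((g.x, g.y))
        else:  # overlap segment: take its endpoints
            pts.extend(np.asarray(g.coords))
    dist = np.linalg.norm(np.asarray(pts) - origin[None, :], axis=1)
    return float(dist.min())


def pair_distance_probabilities(geom, bin_edges_nm: np.ndarray, grid_nm: float = 2.0) -> np.ndarray:
    """P(|X - Y| in bin) for X, Y iid uniform in the polygon, per radial bin.

    Estimated from the polygon's set covariance on a square grid: the polygon
    is rasterized at ``grid_nm`` resolution, its spatial autocorrelation is
    computed by FFT, and the probability mass is accumulated per distance bin.
    Used as the homogeneous-field expectation in the pair autocorrelation.
    """
    minx, miny, maxx, maxy = geom.bounds
    nx = max(int(np.ceil((maxx - minx) / grid_nm)), 1)
    ny = max(int(np.ceil((maxy - miny) / grid_nm)), 1)
    gx = minx + (np.arange(nx) + 0.5) * grid_nm
    gy = miny + (np.arange(ny) + 0.5) * grid_nm
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    mask = points_in_polygon(geom, xx.ravel(), yy.ravel()).reshape(nx, ny).astype(float)
    n_in = mask.sum()
    if n_in == 0:
        raise DegenerateGeometryError("polygon rasterizes to an empty mask")
    # full autocorrelation via zero-padded FFT
    px, py = 2 * nx, 2 * ny
    f = np.fft.rfft2(mask, s=(px, py))
    corr = np.fft.irfft2(f * np.conj(f), s=(px, py))
    corr = np.fft.fftshift(corr)
    dx = (np.arange(px) - px // 2) * grid_nm
    dy = (np.arange(py) - py // 2) * grid_nm
    edges = np.asarray(bin_edges_nm, float)
    nb = len(edges) - 1
    sums = np.zeros(nb)
    w = corr.ravel() / 4.0
    # integrate each displacement cell over a 2x2 subgrid to soften the
    # lattice-circle quantization of the radial binning
    for ox in (-0.25 * grid_nm, 0.25 * grid_nm):
        for oy in (-0.25 * grid_nm, 0.25 * grid_nm):
            rr = np.hypot(dx[:, None] + ox, dy[None, :] + oy)
            idx = np.digitize(rr.ravel(), edges) - 1
            ok = (idx >= 0) & (idx < nb)
            sums += np.bincount(idx[ok], weights=w[ok], minlength=nb)
    return sums / (n_in * n_in)
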
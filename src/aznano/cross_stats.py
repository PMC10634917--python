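"""Randomization null, cross-enrichment, enrichment classification and the
separation index.

Cross-enrichment measures the density of protein B in radial bins around
nanocluster centers of protein A, normalized bin-by-bin to the same measure
for B randomized uniformly inside the active-zone polygon (100 randomizations
by default). A nanocluster is classified as enriched (or de-enriched) when its
mean enrichment within 60 nm exceeds (or falls below) the mean +/- 1.96 SD of
the statistic over 50 independent randomizations. The separation index of a
nanocluster pair is SI = d / (r1 + r2): center-to-center distance over the sum
of the centroid-to-border distances along the connecting line; SI < 1 means
the boundaries overlap.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial.distance import cdist

from ._geometry import largest_polygon, points_in_polygon, ray_boundary_distance
from .errors import DegenerateGeometryError, InsufficientDataError, ParameterError
from .nanoclusters import DEFAULT_BIN_EDGES_NM, Nanocluster
from .robust_stats import rout_outliers

__all__ = [
    "EnrichmentProfile",
    "SeparationResult",
    "randomize_in_roi",
    "annulus_areas",
    "cross_enrichment",
    "enrichment_statistic",
    "classify_enrichment",
    "smooth_profiles_across_synapses",
    "separation_index",
]


@dataclasses.dataclass
class EnrichmentProfile:
    """Randomization-normalized radial density of protein B around A centers."""

    bin_edges_nm: np.ndarray
    enrichment: np.ndarray  # observed density / randomized density, per bin
    rand_mean: np.ndarray  # per-bin mean of individual randomized enrichments
    rand_sd: np.ndarray
    n_randomizations: int
    density_rand: np.ndarray  # normalization denominator (per-bin density)
    annulus_area: np.ndarray  # (n_centers, n_bins) in-ROI annulus areas
    centers: np.ndarray


@dataclasses.dataclass
class SeparationResult:
    source_id: int
    opposite_id: int
    d_nm: float
    r1_nm: float
    r2_nm: float
    si: float
    overlap: bool
    degenerate: bool = False


def randomize_in_roi(n_points: int, roi_polygon, n_rand: int, rng) -> list[np.ndarray]:
    """``n_rand`` sets of ``n_points`` iid uniform points inside the polygon.

    ``rng`` is a ``numpy.random.Generator`` or a seed. Rejection sampling from
    the bounding box; deterministic for a given seed.
    """
    if n_points < 1:
        raise ParameterError("n_points must be >= 1")
    if roi_polygon is None or roi_polygon.is_empty or roi_polygon.area == 0:
        raise DegenerateGeometryError("degenerate ROI polygon")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    minx, miny, maxx, maxy = roi_polygon.bounds
    sets = []
    for _ in range(n_rand):
        pts = np.empty((0, 2))
        while len(pts) < n_points:
            m = max(int((n_points - len(pts)) * 2.5), 16)
            cand = np.column_stack(
                [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
            )
            ok = points_in_polygon(roi_polygon, cand[:, 0], cand[:, 1])
            pts = np.vstack([pts, cand[ok]])
        sets.append(pts[:n_points])
    return sets


def annulus_areas(center: np.ndarray, roi_polygon, bin_edges_nm, quad_segs: int = 64) -> np.ndarray:
    """In-ROI area of each annulus around ``center`` (polygon clipping)."""
    from shapely.geometry import Point

    p = Point(float(center[0]), float(center[1]))
    edges = np.asarray(bin_edges_nm, float)
    disc_areas = []
    for r in edges:
        if r <= 0:
            disc_areas.append(0.0)
        else:
            disc_areas.append(p.buffer(r, quad_segs=quad_segs).intersection(roi_polygon).area)
    return np.diff(np.asarray(disc_areas))


def _bin_densities(centers, point_sets, areas, edges):
    """Per-bin density (count / in-ROI area) averaged over centers, per point set.

    Returns an (n_sets, n_bins) array with NaN where every center's annulus
    area is zero in that bin.
    """
    nb = len(edges) - 1
    out = np.full((len(point_sets), nb), np.nan)
    valid = areas > 0  # (n_centers, n_bins)
    for s, pts in enumerate(point_sets):
        d = cdist(centers, pts)
        counts = np.stack([np.histogram(d[c], bins=edges)[0] for c in range(len(centers))])
        with np.errstate(divide="ignore", invalid="ignore"):
            dens = np.where(valid, counts / areas, np.nan)
        any_valid = valid.any(axis=0)
        out[s, any_valid] = np.nanmean(dens[:, any_valid], axis=0)
    return out


def cross_enrichment(
    centers_a: np.ndarray,
    points_b: np.ndarray,
    roi_polygon,
    bin_edges_nm=DEFAULT_BIN_EDGES_NM,
    rand_sets_b: list[np.ndarray] | None = None,
    rng=None,
    n_rand: int = 100,
) -> EnrichmentProfile:
    """Randomization-normalized density of B around A nanocluster centers.

    Per bin: density of B (count per in-ROI annulus area, averaged over
    centers) divided by the same quantity averaged over randomized placements
    of B inside the ROI. Bins whose annulus lies fully outside the ROI for all
    centers are NaN (missing) and excluded from downstream averages.
    """
    centers = np.atleast_2d(np.asarray(centers_a, float))
    pts_b = np.asarray(points_b, float)
    if len(centers) < 1 or len(pts_b) < 1:
        raise InsufficientDataError("need at least one center and one point of B")
    if rand_sets_b is None:
        rand_sets_b = randomize_in_roi(len(pts_b), roi_polygon, n_rand, rng)
    edges = np.asarray(bin_edges_nm, float)
    areas = np.stack([annulus_areas(c, roi_polygon, edges) for c in centers])
    dens_obs = _bin_densities(centers, [pts_b], areas, edges)[0]
    dens_rand_sets = _bin_densities(centers, rand_sets_b, areas, edges)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
        dens_rand = np.nanmean(dens_rand_sets, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            enr = np.where(dens_rand > 0, dens_obs / dens_rand, np.nan)
            rand_enr = np.where(dens_rand > 0, dens_rand_sets / dens_rand, np.nan)
        rand_mean = np.nanmean(rand_enr, axis=0)
        rand_sd = np.nanstd(rand_enr, axis=0)
    return EnrichmentProfile(
        bin_edges_nm=edges,
        enrichment=enr,
        rand_mean=rand_mean,
        rand_sd=rand_sd,
        n_randomizations=len(rand_sets_b),
        density_rand=dens_rand,
        annulus_area=areas,
        centers=centers,
    )


def enrichment_statistic(profile: EnrichmentProfile, r_max_nm: float = 60.0) -> float:
    """Unweighted mean enrichment over bins whose outer edge is <= r_max_nm."""
    edges = profile.bin_edges_nm
    sel = edges[1:] <= r_max_nm
    vals = profile.enrichment[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InsufficientDataError("no valid bins within r_max")
    return float(vals.mean())


def classify_enrichment(
    profile: EnrichmentProfile,
    class_sets_b: list[np.ndarray],
    r_max_nm: float = 60.0,
    k_sd: float = 1.96,
) -> tuple[str, float, float, float]:
    """Classify a nanocluster as enriched / indistinguishable / de_enriched.

    The observed statistic (mean enrichment within ``r_max_nm``) is compared
    with the same statistic over independent randomized placements of B
    (``class_sets_b``, 50 by default in the pipeline), all normalized by the
    profile's randomization denominator. Strict inequalities at
    mean +/- ``k_sd`` SD.

    Returns ``(label, statistic, rand_mean, rand_sd)``.
    """
    edges = profile.bin_edges_nm
    sel = edges[1:] <= r_max_nm
    if not sel.any() or not np.isfinite(profile.enrichment[sel]).any():
        return ("unclassifiable", np.nan, np.nan, np.nan)
    stat = enrichment_statistic(profile, r_max_nm)
    dens_sets = _bin_densities(profile.centers, class_sets_b, profile.annulus_area, edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr_sets = np.where(profile.density_rand > 0, dens_sets / profile.density_rand, np.nan)
    stats = np.nanmean(enr_sets[:, sel], axis=1)
    stats = stats[np.isfinite(stats)]
    if stats.size < 2:
        return ("unclassifiable", stat, np.nan, np.nan)
    mu, sd = float(stats.mean()), float(stats.std())
    if stat > mu + k_sd * sd:
        label = "enriched"
    elif stat < mu - k_sd * sd:
        label = "de_enriched"
    else:
        label = "indistinguishable"
    return (label, stat, mu, sd)


def smooth_profiles_across_synapses(curves: np.ndarray, rout_q: float = 0.001) -> np.ndarray:
    """Replace per-bin high outliers across a curve population.

    ``curves`` is (n_curves, n_bins); in every distance bin, values flagged as
    high outliers (ROUT, Q) are replaced by the highest non-outlier value in
    that bin. Returns a smoothed copy.
    """
    out = np.array(curves, float, copy=True)
    for b in range(out.shape[1]):
        col = out[:, b]
        ok = np.isfinite(col)
        if ok.sum() < 3:
            continue
        res = rout_outliers(col[ok], Q=rout_q, side="high")
        if res.mask.any() and (~res.mask).any():
            cap = col[ok][~res.mask].max()
            vals = col[ok]
            vals[res.mask] = cap
            out[ok, b] = vals
    return out


def separation_index(source: Nanocluster, opposite: list[Nanocluster]) -> SeparationResult:
    """Separation index of a nanocluster against the nearest opposite nanocluster.

    The nearest opposite nanocluster is chosen by centroid Euclidean distance
    (ties toward the lower cluster id); r1 and r2 are the centroid-to-border
    distances of the two polygons along the line connecting the centroids.
    Coincident centroids yield SI = 0 flagged degenerate, with r1, r2 reported
    as the polygons' effective radii.
    """
    if not opposite:
        raise ParameterError("opposite nanocluster list is empty")
    dists = np.array([np.linalg.norm(o.centroid_nm - source.centroid_nm) for o in opposite])
    ids = np.array([o.cluster_id for o in opposite])
    best = np.lexsort((ids, dists))[0]
    other = opposite[best]
    d = float(dists[best])
    if d == 0.0:
        return SeparationResult(
            source.cluster_id,
            other.cluster_id,
            0.0,
            source.effective_radius_nm,
            other.effective_radius_nm,
            0.0,
            True,
            degenerate=True,
        )
    direction = (other.centroid_nm - source.centroid_nm) / d
    reach = d + 10.0 * max(source.effective_radius_nm, other.effective_radius_nm) + 100.0
    r1 = ray_boundary_distance(largest_polygon(source.polygon), source.centroid_nm, direction, reach)
    r2 = ray_boundary_distance(largest_polygon(other.polygon), other.centroid_nm, -direction, reach)
    si = d / (r1 + r2)
    return SeparationResult(
        source.cluster_id, other.cluster_id, d, float(r1), float(r2), float(si), bool(si < 1.0)
    )
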
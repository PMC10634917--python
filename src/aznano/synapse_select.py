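"""Synapse selection from scaffold-target localizations.

Candidate synapses are DBSCAN clusters (48 nm radius, 10 minimum points) of
the presynaptic scaffold (Bassoon role) and postsynaptic marker (PSD-95 role),
size-filtered at 75 localizations. Clusters of nonspecific, short-lived imager
binding are rejected by frame statistics. En-face synapses are selected by the
roundness of the smoothed scaffold alpha shape (aspect ratio <= 2) and by at
least 70% area overlap of the two scaffold alpha shapes, and analysis targets
are then restricted to the scaffold (active zone) boundary with a minimum of
25 localizations per target.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.cluster import DBSCAN

from ._geometry import (
    alpha_shape,
    points_in_polygon,
    polygon_aspect_ratio,
    smooth_polygon,
)
from .errors import DegenerateGeometryError
from .locio import LocalizationTable
from .robust_stats import fit_gaussian_1d

__all__ = [
    "SynapseROI",
    "detect_synaptic_clusters",
    "cluster_frame_stats",
    "remove_nonspecific_clusters",
    "alpha_shape",
    "select_enface",
    "restrict_to_active_zone",
]

#: alpha radius for synapse-scale shapes: 0.9375 camera px at 160 nm/px
SYNAPSE_ALPHA_RADIUS_NM = 150.0


@dataclasses.dataclass
class SynapseROI:
    """One candidate synapse and its selection state."""

    bassoon_polygon: object  # shapely (Multi)Polygon, nm
    psd_polygon: object
    overlap_fraction: float
    shape_metric: float
    accepted: bool
    reason: str = ""
    restricted: dict[str, LocalizationTable] = dataclasses.field(default_factory=dict)
    synapse_id: int = -1


def detect_synaptic_clusters(
    table: LocalizationTable,
    eps_nm: float = 48.0,
    min_points: int = 10,
    min_cluster_size: int = 75,
) -> np.ndarray:
    """DBSCAN labels per localization; clusters below the size cut become noise (-1).

    ``min_points`` counts the point itself among its eps-neighbors (core-point
    criterion), matching the common localization-analysis convention.
    """
    xy = table.xy
    if len(xy) == 0:
        return np.empty(0, dtype=int)
    labels = DBSCAN(eps=eps_nm, min_samples=min_points).fit_predict(xy)
    out = labels.copy()
    for lab in np.unique(labels):
        if lab >= 0 and (labels == lab).sum() < min_cluster_size:
            out[labels == lab] = -1
    return out


def cluster_frame_stats(table: LocalizationTable, labels: np.ndarray):
    """Per-cluster mean and SD of the frame number, as {label: (mean, sd)}."""
    frames = table.df["frame"].to_numpy(float)
    stats = {}
    for lab in np.unique(labels):
        if lab < 0:
            continue
        f = frames[labels == lab]
        stats[int(lab)] = (float(f.mean()), float(f.std()))
    return stats


def remove_nonspecific_clusters(
    table: LocalizationTable,
    labels: np.ndarray,
    frame_sd_bounds: tuple[float, float] = (2500.0, 11000.0),
    k_sigma: float = 2.0,
) -> np.ndarray:
    """Reject clusters of nonspecific imager binding by frame statistics.

    Nonspecific binders localize for only a short stretch of the acquisition,
    so their frame-number SD is small and their mean frame deviates from the
    acquisition midpoint. A cluster is removed if its frame SD falls outside
    ``frame_sd_bounds``, or if its mean frame lies outside mu +/- k_sigma * sd
    of a gaussian fit to the mean frames of all clusters (skipped with a
    warning when fewer than 3 clusters are available).
    """
    stats = cluster_frame_stats(table, labels)
    out = labels.copy()
    if not stats:
        return out
    removed = {
        lab
        for lab, (_, sd) in stats.items()
        if sd < frame_sd_bounds[0] or sd > frame_sd_bounds[1]
    }
    if len(stats) >= 3:
        means = np.array([m for m, _ in stats.values()])
        try:
            mu, sd = fit_gaussian_1d(means)
            for lab, (m, _) in stats.items():
                if abs(m - mu) > k_sigma * sd:
                    removed.add(lab)
        except Exception:
            warnings.warn("degenerate gaussian fit of cluster mean frames; skipping criterion")
    else:
        warnings.warn("fewer than 3 clusters: mean-frame criterion skipped")
    for lab in removed:
        out[labels == lab] = -1
    return out


def select_enface(
    bassoon_points: np.ndarray,
    psd_points: np.ndarray,
    alpha_radius_nm: float = SYNAPSE_ALPHA_RADIUS_NM,
    overlap_min: float = 0.70,
    shape_metric_max: float = 2.0,
    overlap_denominator: str = "smaller",
) -> SynapseROI:
    """Build scaffold alpha shapes and apply the en-face criteria.

    ``shape_metric`` is the major/minor axis ratio of the second-moment
    ellipse of the smoothed scaffold boundary (an interpretation of the
    roundness constraint on the smoothed alpha shape); ``overlap_fraction``
    is intersection area over the smaller shape's area by default
    (``overlap_denominator="bassoon"`` uses the scaffold area instead).
    """
    try:
        bas_poly, bas_area = alpha_shape(bassoon_points, alpha_radius_nm)
        psd_poly, psd_area = alpha_shape(psd_points, alpha_radius_nm)
    except DegenerateGeometryError as exc:
        return SynapseROI(None, None, np.nan, np.nan, False, f"degenerate polygon: {exc}")
    smoothed = smooth_polygon(bas_poly)
    try:
        metric = polygon_aspect_ratio(smoothed)
    except DegenerateGeometryError as exc:
        return SynapseROI(bas_poly, psd_poly, np.nan, np.nan, False, f"degenerate polygon: {exc}")
    inter = bas_poly.intersection(psd_poly).area
    denom = min(bas_area, psd_area) if overlap_denominator == "smaller" else bas_area
    overlap = inter / denom if denom > 0 else 0.0
    accepted = bool(metric <= shape_metric_max and overlap >= overlap_min)
    reason = ""
    if metric > shape_metric_max:
        reason = f"shape metric {metric:.2f} > {shape_metric_max}"
    elif overlap < overlap_min:
        reason = f"overlap {overlap:.2f} < {overlap_min}"
    return SynapseROI(bas_poly, psd_poly, float(overlap), float(metric), accepted, reason)


def restrict_to_active_zone(
    roi: SynapseROI,
    tables: dict[str, LocalizationTable],
    min_locs: int = 25,
) -> SynapseROI:
    """Restrict each target to the scaffold boundary (boundary-inclusive).

    The ROI is rejected when any provided target has fewer than ``min_locs``
    localizations inside the scaffold polygon.
    """
    restricted = {}
    counts = {}
    for name, tab in tables.items():
        xy = tab.xy
        if len(xy):
            inside = points_in_polygon(roi.bassoon_polygon, xy[:, 0], xy[:, 1])
        else:
            inside = np.zeros(0, bool)
        restricted[name] = tab.with_df(tab.df.loc[inside])
        counts[name] = int(inside.sum())
    roi = dataclasses.replace(roi, restricted=restricted)
    short = [n for n, c in counts.items() if c < min_locs]
    if short:
        roi.accepted = False
        roi.reason = f"fewer than {min_locs} localizations within scaffold for: {', '.join(short)}"
    return roi
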
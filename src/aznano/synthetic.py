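"""Synthetic DNA-PAINT fields with planted ground truth.

``simulate_field`` emulates one four-target synaptic field of view: a
presynaptic scaffold target (Bassoon role) filling the synapse disc, a
postsynaptic marker (PSD-95 role) on a concentric scaled disc, and two
analysis targets (Munc13-1 and CaV2.1 roles) drawn from planted nanoclusters
plus uniform background. Binding events are expanded into per-frame
localization runs (geometric run length with occasional dark gaps) jittered by
the localization precision; nonspecific short-lived binders are planted in the
scaffold channels with a narrow frame window so the frame-statistics filter
can catch them. ``corrupt`` adds drift and a second-degree chromatic warp.

Defaults mirror the acquisition the analysis assumes: 30,000 frames,
160 nm camera pixels, ~7 nm localization precision, and synapse-scale
geometry typical of hippocampal en-face active zones.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .errors import ParameterError
from .locio import LocalizationTable

__all__ = [
    "FieldParams",
    "GroundTruth",
    "simulate_field",
    "corrupt",
    "constant_drift",
    "linear_drift",
    "random_walk_drift",
    "identity_warp",
    "simulate_fiducial_field",
    "simulate_bead_pairs",
    "simulate_side_view_images",
    "TARGETS",
]

TARGETS = ("bassoon", "psd95", "munc13", "cav2")
ARCHITECTURES = ("co_organized", "segregated", "independent")


@dataclasses.dataclass
class FieldParams:
    """Study conditions for one synthetic field (all lengths nm)."""

    architecture: str = "co_organized"
    field_size_nm: float = 2000.0
    synapse_radius_nm: float = 200.0
    aspect_ratio: float = 1.0  # >1 emulates a tilted / side-view scaffold
    psd_radius_scale: float = 0.9
    psd_offset_nm: float = 0.0
    scaffold_events: int = 500
    n_clusters_a: int = 4
    n_clusters_b: int = 3
    cluster_profile: str = "gaussian"  # or "disc" (uniform within cluster_radius)
    cluster_sd_a_nm: float = 15.0
    cluster_sd_b_nm: float = 20.0
    cluster_radius_a_nm: float = 30.0
    cluster_radius_b_nm: float = 40.0
    events_per_cluster_a: int = 60
    events_per_cluster_b: int = 60
    background_fraction: float = 0.1
    co_offset_nm: float = 0.0
    min_center_sep_nm: float = 100.0
    n_nonspecific: int = 2
    nonspecific_events: int = 90
    nonspecific_sd_nm: float = 12.0
    nonspecific_frame_window: int = 2000
    n_frames: int = 30000
    mean_on_frames: float = 3.0
    max_dark_frames: int = 5
    p_gap: float = 0.2
    precision_mean_nm: float = 7.0
    precision_sd_nm: float = 1.5
    photon_mean: float = 3000.0
    sigma_px_mean: float = 1.0
    sigma_px_sd: float = 0.12
    bad_fraction: float = 0.02
    pixel_size_nm: float = 160.0

    def validate(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ParameterError(f"unknown architecture {self.architecture!r}")
        positive = (
            "field_size_nm synapse_radius_nm aspect_ratio psd_radius_scale scaffold_events "
            "n_clusters_a n_clusters_b cluster_sd_a_nm cluster_sd_b_nm cluster_radius_a_nm "
            "cluster_radius_b_nm events_per_cluster_a events_per_cluster_b n_frames "
            "mean_on_frames precision_mean_nm pixel_size_nm"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ParameterError("background_fraction must be in [0, 1)")
        if self.cluster_profile not in ("gaussian", "disc"):
            raise ParameterError("cluster_profile must be 'gaussian' or 'disc'")


def _json_safe(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclasses.dataclass
class GroundTruth:
    """Planted field architecture; the oracle for every downstream stage."""

    synapse_center_nm: np.ndarray
    synapse_radius_nm: float
    en_face: bool
    architecture: str
    cluster_centers: dict[str, np.ndarray]
    cluster_sd_nm: dict[str, float]
    cluster_radius_nm: dict[str, float]
    events_per_cluster: dict[str, int]
    background_fraction: float
    nonspecific_centers: dict[str, np.ndarray]
    n_frames: int
    seed: int
    drift_trajectory: np.ndarray | None = None
    warp_coefficients: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(_json_safe(dataclasses.asdict(self)))


def _uniform_in_ellipse(rng, n, center, radius, aspect=1.0):
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    x = r * np.cos(th) * np.sqrt(aspect)
    y = r * np.sin(th) / np.sqrt(aspect)
    return np.column_stack([x, y]) + np.asarray(center)


def _sample_centers(rng, n, center, max_radius, min_sep, avoid=None, avoid_dist=0.0):
    """Cluster centers in a disc with minimum pairwise (and avoidance) separation."""
    out = []
    sep = min_sep
    tries = 0
    while len(out) < n:
        cand = _uniform_in_ellipse(rng, 1, center, max_radius)[0]
        ok = all(np.linalg.norm(cand - c) >= sep for c in out)
        if ok and avoid is not None and len(avoid):
            ok = np.min(np.linalg.norm(avoid - cand, axis=1)) >= avoid_dist
        if ok:
            out.append(cand)
        tries += 1
        if tries > 2000:  # relax to keep generation total
            sep *= 0.8
            tries = 0
    return np.array(out)


def _blink_expand(rng, events_xy, params: FieldParams, frame_sampler):
    """Expand binding events into per-frame localization rows."""
    rows_xy, rows_frame = [], []
    for p in events_xy:
        length = int(rng.geometric(1.0 / params.mean_on_frames))
        f = int(frame_sampler(rng))
        frames = [f]
        for _ in range(length - 1):
            step = 1
            if rng.uniform() < params.p_gap:
                step += int(rng.integers(1, params.max_dark_frames + 1))
            f += step
            if f >= params.n_frames:
                break
            frames.append(f)
        for fr in frames:
            rows_xy.append(p)
            rows_frame.append(fr)
    if not rows_xy:
        return np.empty((0, 2)), np.empty(0, int)
    return np.array(rows_xy), np.array(rows_frame, int)


def _make_table(rng, events_xy, params: FieldParams, target, frame_sampler=None) -> pd.DataFrame:
    if frame_sampler is None:
        frame_sampler = lambda r: r.integers(0, params.n_frames)  # noqa: E731
    xy, frames = _blink_expand(rng, events_xy, params, frame_sampler)
    n = len(xy)
    precision = np.clip(rng.normal(params.precision_mean_nm, params.precision_sd_nm, n), 1.0, None)
    jitter = rng.normal(0.0, 1.0, (n, 2)) * precision[:, None]
    # per-frame brightness: a peak at the imager brightness plus a partial-frame
    # tail (event starts/ends mid-exposure), so the photon histogram has a
    # well-defined modal bin
    full = rng.uniform(0, 1, n) < 0.75
    photons = np.where(
        full,
        rng.normal(params.photon_mean, 0.08 * params.photon_mean, n),
        params.photon_mean * rng.uniform(0.15, 1.0, n),
    )
    photons = np.clip(photons, 1.0, None)
    sigma = np.clip(rng.normal(params.sigma_px_mean, params.sigma_px_sd, n), 0.35, 1.55)
    # a small fraction of poor-quality localizations, as in real data
    n_bad = int(round(params.bad_fraction * n))
    if n_bad:
        bad = rng.choice(n, n_bad, replace=False)
        kind = rng.integers(0, 3, n_bad)
        sigma[bad[kind == 0]] = rng.choice([0.2, 1.7], (kind == 0).sum())
        precision[bad[kind == 1]] = rng.uniform(21.0, 35.0, (kind == 1).sum())
        photons[bad[kind == 2]] *= 10.0
    return pd.DataFrame(
        {
            "x_nm": xy[:, 0] + jitter[:, 0],
            "y_nm": xy[:, 1] + jitter[:, 1],
            "frame": frames,
            "photons": photons,
            "sigma_px": sigma,
            "precision_nm": precision,
        }
    )


def simulate_field(
    params: FieldParams | None = None, seed: int = 0, **overrides
) -> tuple[dict[str, LocalizationTable], GroundTruth]:
    """Simulate one four-target synaptic field with planted ground truth."""
    if params is None:
        params = FieldParams(**overrides)
    elif overrides:
        params = dataclasses.replace(params, **overrides)
    params.validate()
    rng = np.random.default_rng(seed)
    center = np.array([params.field_size_nm / 2.0, params.field_size_nm / 2.0])
    r_syn = params.synapse_radius_nm

    # --- planted nanocluster centers ----------------------------------------
    c_max = 0.75 * r_syn
    centers_a = _sample_centers(rng, params.n_clusters_a, center, c_max, params.min_center_sep_nm)
    if params.architecture == "co_organized":
        base = centers_a[
            rng.choice(len(centers_a), params.n_clusters_b, replace=params.n_clusters_b > len(centers_a))
        ]
        offset = params.co_offset_nm
        if offset:
            th = rng.uniform(0, 2 * np.pi, len(base))
            base = base + offset * np.column_stack([np.cos(th), np.sin(th)])
        centers_b = base
    elif params.architecture == "segregated":
        centers_b = _sample_centers(
            rng, params.n_clusters_b, center, c_max, params.min_center_sep_nm,
            avoid=centers_a, avoid_dist=params.min_center_sep_nm,
        )
    else:
        centers_b = _sample_centers(rng, params.n_clusters_b, center, c_max, params.min_center_sep_nm)

    # --- binding-event positions --------------------------------------------
    def analysis_events(centers, sd, radius, per_cluster):
        ev = []
        for c in centers:
            if params.cluster_profile == "gaussian":
                ev.append(rng.normal(0, sd, (per_cluster, 2)) + c)
            else:
                ev.append(_uniform_in_ellipse(rng, per_cluster, c, radius))
        ev = np.vstack(ev) if ev else np.empty((0, 2))
        f = params.background_fraction
        n_bg = int(round(f / (1.0 - f) * len(ev)))
        if n_bg:
            ev = np.vstack([ev, _uniform_in_ellipse(rng, n_bg, center, r_syn, params.aspect_ratio)])
        return ev

    events = {
        "bassoon": _uniform_in_ellipse(rng, params.scaffold_events, center, r_syn, params.aspect_ratio),
        "psd95": _uniform_in_ellipse(
            rng,
            params.scaffold_events,
            center + np.array([params.psd_offset_nm, 0.0]),
            r_syn * params.psd_radius_scale,
            params.aspect_ratio,
        ),
        "munc13": analysis_events(
            centers_a, params.cluster_sd_a_nm, params.cluster_radius_a_nm, params.events_per_cluster_a
        ),
        "cav2": analysis_events(
            centers_b, params.cluster_sd_b_nm, params.cluster_radius_b_nm, params.events_per_cluster_b
        ),
    }

    # --- per-frame expansion and nonspecific binders ------------------------
    tables: dict[str, LocalizationTable] = {}
    nonspecific: dict[str, np.ndarray] = {}
    for target in TARGETS:
        df = _make_table(rng, events[target], params, target)
        if target in ("bassoon", "psd95") and params.n_nonspecific > 0:
            ns_centers = []
            for _ in range(params.n_nonspecific):
                while True:
                    cand = rng.uniform(0, params.field_size_nm, 2)
                    if np.linalg.norm(cand - center) > r_syn + 200.0:
                        break
                ns_centers.append(cand)
                t0 = int(rng.integers(0, max(params.n_frames - params.nonspecific_frame_window, 1)))
                ev = rng.normal(0, params.nonspecific_sd_nm, (params.nonspecific_events, 2)) + cand
                ns_df = _make_table(
                    rng, ev, params, target,
                    frame_sampler=lambda r, t0=t0: t0 + r.integers(0, params.nonspecific_frame_window),
                )
                df = pd.concat([df, ns_df], ignore_index=True)
            nonspecific[target] = np.array(ns_centers)
        else:
            nonspecific[target] = np.empty((0, 2))
        df["frame"] = df["frame"].clip(0, params.n_frames - 1)
        tables[target] = LocalizationTable(
            df, pixel_size_nm=params.pixel_size_nm, n_frames=params.n_frames, target_id=target
        )

    gt = GroundTruth(
        synapse_center_nm=center,
        synapse_radius_nm=r_syn,
        en_face=params.aspect_ratio <= 2.0,
        architecture=params.architecture,
        cluster_centers={"munc13": centers_a, "cav2": centers_b},
        cluster_sd_nm={"munc13": params.cluster_sd_a_nm, "cav2": params.cluster_sd_b_nm},
        cluster_radius_nm={"munc13": params.cluster_radius_a_nm, "cav2": params.cluster_radius_b_nm},
        events_per_cluster={"munc13": params.events_per_cluster_a, "cav2": params.events_per_cluster_b},
        background_fraction=params.background_fraction,
        nonspecific_centers=nonspecific,
        n_frames=params.n_frames,
        seed=seed,
    )
    return tables, gt


# --- corruption: drift and chromatic warp -----------------------------------

def constant_drift(n_frames: int, dx_nm: float, dy_nm: float) -> np.ndarray:
    return np.tile([dx_nm, dy_nm], (n_frames, 1)).astype(float)


def linear_drift(n_frames: int, endpoint_x_nm: float, endpoint_y_nm: float) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_frames)
    return np.column_stack([t * endpoint_x_nm, t * endpoint_y_nm])


def random_walk_drift(n_frames: int, step_nm: float, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.cumsum(rng.normal(0, step_nm, (n_frames, 2)), axis=0)


def identity_warp() -> np.ndarray:
    """Warp coefficients [1, x, y, x^2, xy, y^2] per axis for the identity map."""
    return np.array([[0, 1, 0, 0, 0, 0], [0, 0, 1, 0, 0, 0]], float)


def _apply_warp(xy: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    basis = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    return np.column_stack([basis @ coeffs[0], basis @ coeffs[1]])


def corrupt(
    tables: dict[str, LocalizationTable],
    ground_truth: GroundTruth,
    drift_trajectory: np.ndarray | None = None,
    warp_coefficients: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, LocalizationTable], GroundTruth]:
    """Displace localizations by per-frame drift and per-target chromatic warp.

    ``drift_trajectory`` is an (n_frames, 2) nm offset added at each
    localization's frame; ``warp_coefficients`` maps target ids to (2, 6)
    monomial coefficients applied to those targets' positions. Returns new
    tables and an updated ground truth.
    """
    out = {}
    n_frames = next(iter(tables.values())).n_frames
    if drift_trajectory is not None:
        drift_trajectory = np.asarray(drift_trajectory, float)
        if drift_trajectory.shape != (n_frames, 2):
            raise ParameterError("drift trajectory length must equal n_frames")
    warp_coefficients = warp_coefficients or {}
    for name, tab in tables.items():
        df = tab.df.copy()
        xy = df[["x_nm", "y_nm"]].to_numpy(float)
        if name in warp_coefficients:
            xy = _apply_warp(xy, np.asarray(warp_coefficients[name], float))
        if drift_trajectory is not None:
            xy = xy + drift_trajectory[df["frame"].to_numpy(int)]
        df["x_nm"], df["y_nm"] = xy[:, 0], xy[:, 1]
        out[name] = tab.with_df(df)
    gt = dataclasses.replace(
        ground_truth,
        drift_trajectory=drift_trajectory,
        warp_coefficients={k: np.asarray(v, float) for k, v in warp_coefficients.items()},
    )
    return out, gt


# --- auxiliary synthetic inputs ----------------------------------------------

def simulate_fiducial_field(
    n_sites: int = 100,
    events_per_site: int = 200,
    extent_nm: float = 3000.0,
    site_sd_nm: float = 20.0,
    n_frames: int = 30000,
    mean_on_frames: float = 3.0,
    precision_nm: float = 7.0,
    pixel_size_nm: float = 160.0,
    seed: int = 0,
) -> LocalizationTable:
    """A structured field (fixed binding sites re-visited over the whole
    acquisition) dense enough for drift estimation tests."""
    rng = np.random.default_rng(seed)
    sites = rng.uniform(0, extent_nm, (n_sites, 2))
    ev = sites[rng.integers(0, n_sites, n_sites * events_per_site)]
    ev = ev + rng.normal(0, site_sd_nm, ev.shape)
    params = FieldParams(
        n_frames=n_frames, mean_on_frames=mean_on_frames,
        precision_mean_nm=precision_nm, bad_fraction=0.0, pixel_size_nm=pixel_size_nm,
    )
    df = _make_table(rng, ev, params, "fiducial")
    return LocalizationTable(df, pixel_size_nm=pixel_size_nm, n_frames=n_frames, target_id="fiducial")


def simulate_bead_pairs(
    warp_coefficients: np.ndarray,
    n_beads: int = 40,
    extent_nm: float = 40000.0,
    noise_sd_nm: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Control-point pairs (reference, warped) for chromatic-transform fitting."""
    rng = np.random.default_rng(seed)
    fixed = rng.uniform(0, extent_nm, (n_beads, 2))
    moving = _apply_warp(fixed, np.asarray(warp_coefficients, float))
    if noise_sd_nm:
        moving = moving + rng.normal(0, noise_sd_nm, moving.shape)
    return fixed, moving


def simulate_side_view_images(
    offset_nm: float = 40.0,
    pixel_nm: float = 22.7,
    size_px: int = 64,
    bar_length_nm: float = 500.0,
    bar_width_sd_nm: float = 40.0,
    angle_deg: float = 0.0,
    amplitude: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Two-channel synthetic side-view synapse image.

    The postsynaptic channel is a Gaussian bar; the protein channel is the
    same bar displaced by ``offset_nm`` along the trans-synaptic axis
    (perpendicular to the bar). Returns ``(images, center_nm, axis)`` where
    ``axis`` is the unit profile direction. Images are indexed ``[ix, iy]``
    with world position ``(i + 0.5) * pixel_nm``.
    """
    rng = np.random.default_rng(seed)
    extent = size_px * pixel_nm
    center = np.array([extent / 2.0, extent / 2.0])
    th = np.deg2rad(angle_deg)
    axis = np.array([np.cos(th), np.sin(th)])  # trans-synaptic (profile) axis
    along = np.array([-np.sin(th), np.cos(th)])  # bar direction
    coords = (np.arange(size_px) + 0.5) * pixel_nm
    xx, yy = np.meshgrid(coords, coords, indexing="ij")

    def bar(ch_center):
        dx = xx - ch_center[0]
        dy = yy - ch_center[1]
        u = dx * axis[0] + dy * axis[1]
        v = dx * along[0] + dy * along[1]
        img = amplitude * np.exp(-0.5 * (u / bar_width_sd_nm) ** 2)
        img *= 1.0 / (1.0 + np.exp((np.abs(v) - bar_length_nm / 2) / 20.0))
        if noise_sd:
            img = img + rng.normal(0, noise_sd, img.shape)
        return img

    images = {"psd95": bar(center), "protein": bar(center + offset_nm * axis)}
    return images, center, axis
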
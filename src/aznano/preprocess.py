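"""Localization preprocessing: quality filters, temporal linking of blinking
events, redundant cross-correlation (RCC) drift correction, polynomial
chromatic correction and residual inter-target offset correction.

Filter thresholds follow the acquisition conventions of DNA-PAINT data:
PSF-fit standard deviation outside (0.3, 1.6) camera pixels, localization
error above 20 nm, and photon counts above the modal bin of the photon
histogram are removed. Localizations of one binding event are linked within a
0.3-pixel radius allowing five dark frames.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError, UnderdeterminedError
from .locio import LocalizationTable

__all__ = [
    "QCReport",
    "TransformModel",
    "filter_quality",
    "link_localizations",
    "drift_correct_rcc",
    "fit_chromatic_transform",
    "apply_transform",
    "correct_residual_offset",
]


@dataclasses.dataclass
class QCReport:
    rows_in: int
    rows_removed_sigma: int
    rows_removed_precision: int
    rows_removed_photons: int
    rows_out: int
    sigma_bounds_px: tuple[float, float]
    precision_max_nm: float
    photon_threshold: float | None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


def photon_mode_threshold(photons: np.ndarray, bin_width: float = 50.0) -> float:
    """Upper edge of the modal bin of the photon histogram (ties -> lower bin).

    Bins are ``[0, w), [w, 2w), ...``; counts above the returned threshold are
    removed by the photon filter.
    """
    ph = np.asarray(photons, float)
    ph = ph[np.isfinite(ph)]
    if ph.size == 0:
        return np.inf
    idx = np.floor(ph / bin_width).astype(int)
    counts = np.bincount(idx)
    mode_bin = int(np.argmax(counts))  # argmax takes the lowest index on ties
    return (mode_bin + 1) * bin_width


def filter_quality(
    table: LocalizationTable,
    sigma_bounds_px: tuple[float, float] = (0.3, 1.6),
    precision_max_nm: float = 20.0,
    photon_bin_width: float = 50.0,
) -> tuple[LocalizationTable, QCReport]:
    """Remove low-quality localizations.

    Removal rules (strict inequalities): ``sigma_px < lo`` or ``> hi``;
    ``precision_nm > precision_max_nm``; ``photons`` greater than the upper
    edge of the modal bin of the photon histogram. Rows with a missing quality
    value pass the corresponding rule. Removal causes are counted with
    precedence sigma -> precision -> photons; the surviving set does not depend
    on the precedence. The photon mode is computed on rows surviving the first
    two rules.
    """
    df = table.df
    n_in = len(df)
    sig = df["sigma_px"].to_numpy(float)
    prec = df["precision_nm"].to_numpy(float)
    ph = df["photons"].to_numpy(float)

    bad_sigma = np.isfinite(sig) & ((sig < sigma_bounds_px[0]) | (sig > sigma_bounds_px[1]))
    bad_prec = np.isfinite(prec) & (prec > precision_max_nm)
    thresh = photon_mode_threshold(ph[~(bad_sigma | bad_prec)], photon_bin_width)
    bad_phot = np.isfinite(ph) & (ph > thresh)

    removed = bad_sigma | bad_prec | bad_phot
    report = QCReport(
        rows_in=n_in,
        rows_removed_sigma=int(bad_sigma.sum()),
        rows_removed_precision=int((bad_prec & ~bad_sigma).sum()),
        rows_removed_photons=int((bad_phot & ~bad_sigma & ~bad_prec).sum()),
        rows_out=int((~removed).sum()),
        sigma_bounds_px=tuple(sigma_bounds_px),
        precision_max_nm=precision_max_nm,
        photon_threshold=None if not np.isfinite(thresh) else float(thresh),
    )
    if report.rows_out == 0 and n_in > 0:
        warnings.warn("quality filter removed all localizations")
    return table.with_df(df.loc[~removed]), report


def link_localizations(
    table: LocalizationTable, radius_px: float = 0.3, max_dark_frames: int = 5
) -> LocalizationTable:
    """Merge localizations of one binding event into a single row.

    Greedy in frame order: each localization joins the nearest active event
    whose running (photon-weighted) mean position is within ``radius_px``
    (converted to nm) and whose last appearance is at most ``max_dark_frames``
    frames in the past; ties break toward the earlier-created event. Merged
    rows have the photon-weighted mean position, summed photons, the first
    frame, the minimum member precision (conservative) and carry ``last_frame``
    and ``n_merged`` columns, which makes a second application a no-op on the
    gap criterion.
    """
    df = table.df
    if len(df) == 0:
        return table.copy()
    radius_nm = radius_px * table.pixel_size_nm
    x = df["x_nm"].to_numpy(float)
    y = df["y_nm"].to_numpy(float)
    frame = df["frame"].to_numpy(int)
    photons = df["photons"].to_numpy(float)
    sigma = df["sigma_px"].to_numpy(float)
    precision = df["precision_nm"].to_numpy(float)
    last_in = df["last_frame"].to_numpy(int) if "last_frame" in df else frame
    n_in = df["n_merged"].to_numpy(int) if "n_merged" in df else np.ones(len(df), int)
    w = np.where(np.isfinite(photons) & (photons > 0), photons, 1.0)

    order = np.lexsort((np.arange(len(df)), frame))
    events: list[dict] = []
    active: list[dict] = []
    for row in order:
        f = frame[row]
        active = [e for e in active if f - e["last_frame"] - 1 <= max_dark_frames]
        best = None
        best_d = radius_nm
        for e in active:
            if e["last_frame"] >= f:
                continue  # same-frame localizations never merge
            d = np.hypot(e["mx"] - x[row], e["my"] - y[row])
            if d < best_d or (d == best_d and best is None):
                best, best_d = e, d
        if best is None:
            e = {
                "wsum": w[row],
                "wx": w[row] * x[row],
                "wy": w[row] * y[row],
                "mx": x[row],
                "my": y[row],
                "first": f,
                "last_frame": last_in[row],
                "photons": photons[row],
                "sigma_w": w[row] * sigma[row],
                "precision": precision[row],
                "n": n_in[row],
            }
            events.append(e)
            active.append(e)
        else:
            best["wsum"] += w[row]
            best["wx"] += w[row] * x[row]
            best["wy"] += w[row] * y[row]
            best["mx"] = best["wx"] / best["wsum"]
            best["my"] = best["wy"] / best["wsum"]
            best["last_frame"] = max(best["last_frame"], last_in[row])
            best["photons"] = np.nansum([best["photons"], photons[row]])
            best["sigma_w"] += w[row] * sigma[row]
            best["precision"] = np.nanmin([best["precision"], precision[row]])
            best["n"] += n_in[row]

    out = pd.DataFrame(
        {
            "x_nm": [e["mx"] for e in events],
            "y_nm": [e["my"] for e in events],
            "frame": [e["first"] for e in events],
            "photons": [e["photons"] for e in events],
            "sigma_px": [e["sigma_w"] / e["wsum"] for e in events],
            "precision_nm": [e["precision"] for e in events],
            "last_frame": [e["last_frame"] for e in events],
            "n_merged": [e["n"] for e in events],
        }
    )
    return table.with_df(out)


def _histogram_image(xy: np.ndarray, bounds, pixel_nm: float) -> np.ndarray:
    (x0, y0, x1, y1) = bounds
    nx = max(int(np.ceil((x1 - x0) / pixel_nm)), 1)
    ny = max(int(np.ceil((y1 - y0) / pixel_nm)), 1)
    ix = np.clip(np.floor((xy[:, 0] - x0) / pixel_nm).astype(int), 0, nx - 1)
    iy = np.clip(np.floor((xy[:, 1] - y0) / pixel_nm).astype(int), 0, ny - 1)
    img = np.zeros((nx, ny))
    np.add.at(img, (ix, iy), 1.0)
    return img


def _image_shift(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Sub-pixel displacement d (pixels) with b(r) ~= a(r - d), plus peak prominence."""
    shape = (2 * a.shape[0], 2 * a.shape[1])
    fa = np.fft.rfft2(a - a.mean(), s=shape)
    fb = np.fft.rfft2(b - b.mean(), s=shape)
    corr = np.fft.irfft2(fb * np.conj(fa), s=shape)
    corr = np.fft.fftshift(corr)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    # prominence: main peak over the best peak elsewhere (5-px exclusion zone)
    masked = corr.copy()
    i0, j0 = peak
    masked[max(i0 - 5, 0) : i0 + 6, max(j0 - 5, 0) : j0 + 6] = -np.inf
    second = masked.max()
    base = np.median(corr)
    prominence = float((corr[peak] - base) / max(second - base, 1e-30))
    d = np.array([peak[0] - shape[0] // 2, peak[1] - shape[1] // 2], float)
    for axis in (0, 1):
        i, j = peak
        if 0 < peak[axis] < corr.shape[axis] - 1:
            if axis == 0:
                cm, c0, cp = corr[i - 1, j], corr[i, j], corr[i + 1, j]
            else:
                cm, c0, cp = corr[i, j - 1], corr[i, j], corr[i, j + 1]
            denom = cm - 2 * c0 + cp
            if denom != 0:
                d[axis] += 0.5 * (cm - cp) / denom
    return d, prominence


def drift_correct_rcc(
    table: LocalizationTable,
    segment_frames: int = 1000,
    render_pixel_nm: float = 30.0,
) -> tuple[LocalizationTable, np.ndarray]:
    """Redundant cross-correlation drift correction.

    The acquisition is split into temporal segments of ``segment_frames``
    frames; every segment pair is rendered on a common grid and
    cross-correlated, and the per-segment drift is solved by least squares
    from all pairwise shifts. Per-frame drift is linearly interpolated between
    segment midpoints, anchored to zero at frame 0, and subtracted.

    Returns the corrected table and the estimated per-frame trajectory
    (``n_frames`` x 2, nm). Note that a drift component constant over the whole
    acquisition is unobservable to cross-correlation (pure gauge) and is
    reported as zero.
    """
    n_frames = table.n_frames
    if n_frames < 2 * segment_frames:
        raise ParameterError("need n_frames >= 2 * segment_frames for RCC")
    df = table.df
    xy = table.xy
    frame = df["frame"].to_numpy(int)
    n_seg = n_frames // segment_frames
    seg_of_frame = np.minimum(np.arange(n_frames) // segment_frames, n_seg - 1)
    seg = seg_of_frame[frame]
    bounds = (xy[:, 0].min(), xy[:, 1].min(), xy[:, 0].max(), xy[:, 1].max())
    images = [_histogram_image(xy[seg == s], bounds, render_pixel_nm) for s in range(n_seg)]

    rows, rhs = [], []
    for i in range(n_seg):
        for j in range(i + 1, n_seg):
            d, _ = _image_shift(images[i], images[j])
            row = np.zeros(n_seg)
            row[i], row[j] = -1.0, 1.0
            rows.append(row)
            rhs.append(d * render_pixel_nm)
    a = np.array(rows)[:, 1:]  # anchor segment 0 at zero drift
    rhs = np.array(rhs)
    sol, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    seg_drift = np.vstack([np.zeros((1, 2)), sol])

    centers = np.array(
        [np.mean(np.flatnonzero(seg_of_frame == s)) for s in range(n_seg)]
    )
    frames_all = np.arange(n_frames, dtype=float)
    traj = np.column_stack(
        [np.interp(frames_all, centers, seg_drift[:, k]) for k in range(2)]
    )
    # linear extrapolation beyond the first/last segment midpoints
    for lo, hi, edge in ((0, 1, frames_all < centers[0]), (-2, -1, frames_all > centers[-1])):
        slope = (seg_drift[hi] - seg_drift[lo]) / (centers[hi] - centers[lo])
        anchor = seg_drift[hi] if edge[-1] else seg_drift[lo]
        t0 = centers[hi] if edge[-1] else centers[lo]
        traj[edge] = anchor[None, :] + (frames_all[edge, None] - t0) * slope[None, :]
    traj = traj - traj[0]  # gauge: zero drift at frame 0
    out = df.copy()
    out["x_nm"] = out["x_nm"].to_numpy(float) - traj[frame, 0]
    out["y_nm"] = out["y_nm"].to_numpy(float) - traj[frame, 1]
    return table.with_df(out), traj


@dataclasses.dataclass
class TransformModel:
    """Degree-2 polynomial plane mapping (moving -> fixed) per axis.

    Coefficients are in the monomial basis ``[1, x, y, x^2, x*y, y^2]``.
    """

    degree: int
    coefficients_x: np.ndarray
    coefficients_y: np.ndarray
    fit_rmse_nm: float


def _design(points: np.ndarray) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


def _expand_normalized(c: np.ndarray, mu: np.ndarray, s: float) -> np.ndarray:
    """Rewrite P((x-mx)/s, (y-my)/s) in the raw monomial basis [1,x,y,x²,xy,y²]."""
    a0, a1, a2, a3, a4, a5 = c
    mx, my = mu
    return np.array(
        [
            a0 - a1 * mx / s - a2 * my / s
            + a3 * mx * mx / s**2 + a4 * mx * my / s**2 + a5 * my * my / s**2,
            a1 / s - 2 * a3 * mx / s**2 - a4 * my / s**2,
            a2 / s - 2 * a5 * my / s**2 - a4 * mx / s**2,
            a3 / s**2,
            a4 / s**2,
            a5 / s**2,
        ]
    )


def fit_chromatic_transform(fixed_points, moving_points) -> TransformModel:
    """Least-squares degree-2 polynomial mapping moving -> fixed control points."""
    fixed = np.asarray(fixed_points, float)
    moving = np.asarray(moving_points, float)
    if fixed.shape != moving.shape or fixed.ndim != 2 or fixed.shape[1] != 2:
        raise ParameterError("fixed and moving must be matching (n, 2) arrays")
    if len(fixed) < 6:
        raise UnderdeterminedError("degree-2 polynomial needs >= 6 point pairs")
    # fit in centered/scaled coordinates for conditioning, then expand the
    # coefficients back to the raw monomial basis
    mu = moving.mean(axis=0)
    scale = float(moving.std()) or 1.0
    norm = (moving - mu) / scale
    a_norm = _design(norm)
    if np.linalg.matrix_rank(a_norm) < 6:
        warnings.warn("control points are in a degenerate (e.g. collinear) configuration")
    cx = _expand_normalized(np.linalg.lstsq(a_norm, fixed[:, 0], rcond=None)[0], mu, scale)
    cy = _expand_normalized(np.linalg.lstsq(a_norm, fixed[:, 1], rcond=None)[0], mu, scale)
    a = _design(moving)
    pred = np.column_stack([a @ cx, a @ cy])
    rmse = float(np.sqrt(np.mean(np.sum((pred - fixed) ** 2, axis=1))))
    return TransformModel(2, cx, cy, rmse)


def apply_transform(model: TransformModel, obj):
    """Apply a fitted transform to an (n, 2) array or a LocalizationTable."""
    if isinstance(obj, LocalizationTable):
        pts = obj.xy
        mapped = apply_transform(model, pts)
        df = obj.df.copy()
        df["x_nm"], df["y_nm"] = mapped[:, 0], mapped[:, 1]
        return obj.with_df(df)
    pts = np.asarray(obj, float)
    a = _design(pts)
    return np.column_stack([a @ model.coefficients_x, a @ model.coefficients_y])


def correct_residual_offset(
    reference_table: LocalizationTable,
    other_table: LocalizationTable,
    render_pixel_nm: float = 20.0,
    min_prominence: float = 2.0,
) -> tuple[LocalizationTable, np.ndarray, bool]:
    """Correct the residual rigid offset of one target against the reference.

    Both tables are rendered on a common grid and cross-correlated; the other
    table is translated by the (sub-pixel interpolated) correlation peak.
    Returns ``(shifted_table, applied_shift_nm, low_confidence)`` where the low
    confidence flag marks a correlation peak with prominence below
    ``min_prominence`` (e.g. two unrelated point patterns).
    """
    rxy, oxy = reference_table.xy, other_table.xy
    if (
        rxy[:, 0].max() < oxy[:, 0].min()
        or oxy[:, 0].max() < rxy[:, 0].min()
        or rxy[:, 1].max() < oxy[:, 1].min()
        or oxy[:, 1].max() < rxy[:, 1].min()
    ):
        raise InsufficientDataError("bounding boxes of the two targets do not overlap")
    bounds = (
        min(rxy[:, 0].min(), oxy[:, 0].min()),
        min(rxy[:, 1].min(), oxy[:, 1].min()),
        max(rxy[:, 0].max(), oxy[:, 0].max()),
        max(rxy[:, 1].max(), oxy[:, 1].max()),
    )
    ref_img = _histogram_image(rxy, bounds, render_pixel_nm)
    oth_img = _histogram_image(oxy, bounds, render_pixel_nm)
    d, prominence = _image_shift(ref_img, oth_img)
    shift_nm = -d * render_pixel_nm  # move 'other' back onto the reference
    df = other_table.df.copy()
    df["x_nm"] = df["x_nm"].to_numpy(float) + shift_nm[0]
    df["y_nm"] = df["y_nm"].to_numpy(float) + shift_nm[1]
    return other_table.with_df(df), shift_nm, prominence < min_prominence
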
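"""STED side-view line-profile quantification.

For a side-view synapse, a 750-nm-long, 250-nm-wide line profile is drawn
perpendicular to the postsynaptic density marker across its center. After a
5-pixel rolling average, profiles of individual synapses are aligned to the
peak of the postsynaptic marker and averaged; the maximum of each smoothed
profile is the peak intensity, normalized per culture to the mean of the
comparison condition (percent scale). Default sampling is the acquisition
pixel size of 22.7 nm.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .errors import BoundsError, NormalizationError, ParameterError

__all__ = [
    "SideViewProfile",
    "extract_profile",
    "smooth_profile",
    "align_and_average",
    "peak_intensity",
    "normalize_peaks",
]

log = logging.getLogger(__name__)

DEFAULT_PIXEL_NM = 22.7


@dataclasses.dataclass
class SideViewProfile:
    """Multi-channel line profile through one side-view synapse."""

    positions_nm: np.ndarray  # offsets along the profile axis, 0 at the window center
    intensity: dict[str, np.ndarray]
    pixel_nm: float
    alignment_offset_nm: float = 0.0

    @property
    def peak_value(self) -> dict[str, float]:
        return {ch: float(v.max()) for ch, v in self.intensity.items()}


def extract_profile(
    images: dict[str, np.ndarray],
    center_nm,
    direction,
    length_nm: float = 750.0,
    width_nm: float = 250.0,
    pixel_nm: float = DEFAULT_PIXEL_NM,
) -> SideViewProfile:
    """Sample a line profile from 2D images (bilinear interpolation).

    ``direction`` is the profile axis (need not be normalized); intensity at
    each along-axis sample is the mean over the across-axis samples spanning
    ``width_nm``. Images are indexed ``[ix, iy]`` with pixel centers at
    ``(i + 0.5) * pixel_nm``. Raises :class:`BoundsError` if the sampling
    window exits the image.
    """
    center = np.asarray(center_nm, float)
    d = np.asarray(direction, float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ParameterError("direction must be a nonzero vector")
    d = d / norm
    perp = np.array([-d[1], d[0]])
    n_along = int(round(length_nm / pixel_nm)) + 1
    n_across = int(round(width_nm / pixel_nm)) + 1
    along = (np.arange(n_along) - (n_along - 1) / 2.0) * pixel_nm
    across = (np.arange(n_across) - (n_across - 1) / 2.0) * pixel_nm
    # world sample positions, (n_along, n_across, 2)
    pos = center[None, None, :] + along[:, None, None] * d[None, None, :] + across[None, :, None] * perp[None, None, :]
    ij = pos / pixel_nm - 0.5  # fractional pixel indices

    intensity = {}
    for ch, img in images.items():
        if (
            ij.min() < 0
            or ij[..., 0].max() > img.shape[0] - 1
            or ij[..., 1].max() > img.shape[1] - 1
        ):
            raise BoundsError("profile window exits the image bounds")
        vals = map_coordinates(
            np.asarray(img, float), [ij[..., 0].ravel(), ij[..., 1].ravel()], order=1
        ).reshape(n_along, n_across)
        intensity[ch] = vals.mean(axis=1)
    return SideViewProfile(positions_nm=along, intensity=intensity, pixel_nm=float(pixel_nm))


def smooth_profile(profile: SideViewProfile, window_px: int = 5) -> SideViewProfile:
    """Centered rolling average; windows shrink at the profile edges."""
    n = len(profile.positions_nm)
    if n < window_px:
        raise ParameterError("profile shorter than the smoothing window")
    kernel = np.ones(window_px)
    counts = np.convolve(np.ones(n), kernel, "same")
    smoothed = {
        ch: np.convolve(v, kernel, "same") / counts for ch, v in profile.intensity.items()
    }
    return dataclasses.replace(profile, intensity=smoothed)


def _peak_index(values: np.ndarray) -> int:
    """Index of the maximum; ties break toward the profile center."""
    m = values.max()
    idx = np.flatnonzero(values == m)
    if len(idx) > 1:
        log.info("non-unique profile maximum; tie broken toward the center")
        center = (len(values) - 1) / 2.0
        idx = idx[np.argmin(np.abs(idx - center))]
        return int(idx)
    return int(idx[0])


def align_and_average(
    profiles: list[SideViewProfile], reference_channel: str
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Align profiles to the reference-channel peak and average channel-wise.

    Each profile is shifted (whole samples) so the reference peak sits at
    offset 0; the channel-wise mean and SEM are computed on the grid common to
    all profiles. Returns ``(positions_nm, mean, sem)``.
    """
    if not profiles:
        raise ParameterError("no profiles to average")
    step = profiles[0].pixel_nm
    peaks = [_peak_index(p.intensity[reference_channel]) for p in profiles]
    lo = max(-pk for pk in peaks)
    hi = min(len(p.positions_nm) - 1 - pk for p, pk in zip(profiles, peaks))
    if hi < lo:
        raise ParameterError("profiles have no common support after alignment")
    offsets = np.arange(lo, hi + 1)
    channels = profiles[0].intensity.keys()
    mean, sem = {}, {}
    for ch in channels:
        stack = np.stack([p.intensity[ch][offsets + pk] for p, pk in zip(profiles, peaks)])
        mean[ch] = stack.mean(axis=0)
        sem[ch] = stack.std(axis=0, ddof=1) / np.sqrt(len(stack)) if len(stack) > 1 else np.zeros(stack.shape[1])
    for p, pk in zip(profiles, peaks):
        p.alignment_offset_nm = -p.positions_nm[pk]
    return offsets * step, mean, sem


def peak_intensity(profile: SideViewProfile, channel: str) -> float:
    """Maximum of the (smoothed) profile in the given channel."""
    return float(profile.intensity[channel].max())


def normalize_peaks(records: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Normalize peak intensities per culture to the control condition's mean.

    ``records`` needs columns ``culture``, ``condition``, ``peak``; a
    ``normalized_pct`` column is added (percent of the control-condition mean
    within the same culture).
    """
    out = records.copy()
    out["normalized_pct"] = np.nan
    for culture, grp in records.groupby("culture"):
        ctrl = grp.loc[grp["condition"] == control_condition, "peak"]
        if ctrl.empty:
            raise NormalizationError(f"no control-condition profiles in culture {culture!r}")
        mean = ctrl.mean()
        if mean == 0:
            raise NormalizationError(f"zero control mean in culture {culture!r}")
        out.loc[grp.index, "normalized_pct"] = 100.0 * grp["peak"] / mean
    return out
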
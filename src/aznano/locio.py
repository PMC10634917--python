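"""Localization-table I/O and density rendering.

A :class:`LocalizationTable` is the pipeline's universal currency: one row per
localization with spatial (nm), temporal (frame) and quality columns, plus
field-of-view metadata (camera pixel pitch, total frame count, target label).
Positions are always stored in nm internally; on-disk pixel units are converted
on read using ``pixel_size_nm``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import EmptyInputError, FormatError, ParameterError, ParseError

REQUIRED_COLUMNS = ("x", "y", "frame")
OPTIONAL_COLUMNS = ("photons", "sigma", "precision")

#: internal column names of a LocalizationTable dataframe
COLUMNS = ("x_nm", "y_nm", "frame", "photons", "sigma_px", "precision_nm")

_DISK_TO_INTERNAL = {
    "x": "x_nm",
    "y": "y_nm",
    "frame": "frame",
    "photons": "photons",
    "sigma": "sigma_px",
    "precision": "precision_nm",
}
_INTERNAL_TO_DISK = {v: k for k, v in _DISK_TO_INTERNAL.items()}


@dataclasses.dataclass
class LocalizationTable:
    """Per-target localization table with field-of-view metadata.

    ``df`` columns: x_nm, y_nm (float, nm), frame (int, 0-based), photons,
    sigma_px (PSF-fit SD in camera pixels), precision_nm (localization error).
    Row order carries no meaning. Optional columns (e.g. ``last_frame`` after
    temporal linking) are preserved by all operations that do not own them.
    """

    df: pd.DataFrame
    pixel_size_nm: float
    n_frames: int
    target_id: str = ""

    def __post_init__(self):
        if self.pixel_size_nm <= 0:
            raise ParameterError("pixel_size_nm must be > 0")
        if self.n_frames <= 0:
            raise ParameterError("n_frames must be > 0")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x_nm", "y_nm"]].to_numpy(float)

    def validate(self) -> None:
        df = self.df
        if not np.isfinite(df[["x_nm", "y_nm"]].to_numpy(float)).all():
            raise ParameterError("non-finite coordinates")
        fr = df["frame"].to_numpy()
        if len(fr) and (fr.min() < 0 or fr.max() >= self.n_frames):
            raise ParameterError("frame outside [0, n_frames)")
        for col, lo in (("photons", 0.0), ("sigma_px", 0.0), ("precision_nm", 0.0)):
            if col in df and len(df) and df[col].min() < lo:
                raise ParameterError(f"{col} must be >= {lo}")

    def with_df(self, df: pd.DataFrame) -> "LocalizationTable":
        return dataclasses.replace(self, df=df.reset_index(drop=True))

    def copy(self) -> "LocalizationTable":
        return self.with_df(self.df.copy())


@dataclasses.dataclass
class DensityImage:
    """Rendered point-pattern density on a regular grid.

    ``pixels[i, j]`` covers the world square
    ``[origin + i*pixel, origin + (i+1)*pixel)`` along x (index i) and y (j).
    Total pixel mass equals the number of rendered localizations.
    """

    pixels: np.ndarray
    pixel_nm: float
    origin_nm: tuple[float, float]

    def write_tiff(self, path) -> None:
        tifffile.imwrite(str(path), self.pixels.astype(np.float32))


def _frame_to_int(series: pd.Series, path) -> pd.Series:
    vals = pd.to_numeric(series, errors="coerce")
    bad = vals.isna()
    if bad.any():
        raise ParseError(f"non-numeric cell in column 'frame' at row {int(bad.idxmax())} of {path}")
    return vals.astype(np.int64)


def read_localizations(
    path,
    dialect: str = "csv",
    *,
    pixel_size_nm: float,
    n_frames: int,
    target_id: str = "",
    units: str | None = None,
) -> LocalizationTable:
    """Read a localization table from CSV or HDF5.

    On-disk columns are ``x, y, frame`` (required) and
    ``photons, sigma, precision`` (optional; absent columns are filled with
    NaN, never zero). ``units`` declares the on-disk unit of x/y (``"px"`` or
    ``"nm"``); if omitted, a sidecar YAML ``<path>.yaml`` is consulted and the
    default is ``"px"``. Pixel positions are multiplied by ``pixel_size_nm``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if units is None:
        sidecar = path.with_name(path.name + ".yaml")
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text()) or {}
            units = meta.get("units", "px")
        else:
            units = "px"
    if units not in ("px", "nm"):
        raise ParameterError(f"unknown units {units!r}")

    if dialect == "csv":
        raw = pd.read_csv(path, float_precision="round_trip")
    elif dialect == "hdf5":
        with h5py.File(path, "r") as f:
            group = f[target_id] if target_id and target_id in f else f[list(f.keys())[0]]
            raw = pd.DataFrame({k: np.asarray(group[k]) for k in group.keys()})
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")

    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise FormatError(col)
    out = pd.DataFrame()
    for disk, internal in _DISK_TO_INTERNAL.items():
        if disk == "frame":
            out[internal] = _frame_to_int(raw["frame"], path)
        elif disk in raw.columns:
            vals = pd.to_numeric(raw[disk], errors="coerce")
            bad = vals.isna() & raw[disk].notna()
            if bad.any():
                raise ParseError(
                    f"non-numeric cell in column '{disk}' at row {int(bad.idxmax())} of {path}"
                )
            out[internal] = vals.astype(float)
        else:
            out[internal] = np.nan
    if units == "px":
        out["x_nm"] *= pixel_size_nm
        out["y_nm"] *= pixel_size_nm
    table = LocalizationTable(out, pixel_size_nm=pixel_size_nm, n_frames=n_frames, target_id=target_id)
    table.validate()
    return table


def write_localizations(table: LocalizationTable, path, dialect: str = "csv") -> None:
    """Write a table (positions in nm) with a YAML sidecar declaring the units."""
    path = Path(path)
    disk = pd.DataFrame({_INTERNAL_TO_DISK[c]: table.df[c] for c in COLUMNS if c in table.df})
    if dialect == "csv":
        disk.to_csv(path, index=False, float_format="%.17g")  # value-preserving
        sidecar = {
            "units": "nm",
            "pixel_size_nm": table.pixel_size_nm,
            "n_frames": table.n_frames,
            "target_id": table.target_id,
        }
        path.with_name(path.name + ".yaml").write_text(yaml.safe_dump(sidecar))
    elif dialect == "hdf5":
        with h5py.File(path, "a") as f:
            name = table.target_id or "localizations"
            if name in f:
                del f[name]
            g = f.create_group(name)
            for col in disk.columns:
                g.create_dataset(col, data=disk[col].to_numpy())
            g.attrs["units"] = "nm"
            g.attrs["pixel_size_nm"] = table.pixel_size_nm
            g.attrs["n_frames"] = table.n_frames
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")


def render_ash(table: LocalizationTable, pixel_nm: float, m: int = 4) -> DensityImage:
    """Averaged-shifted-histogram density image of a localization table.

    Equivalent to averaging ``m**2`` histograms shifted on a ``pixel_nm`` grid:
    a histogram at ``pixel_nm`` resolution is convolved with a separable
    triangular kernel of half-width ``m`` fine pixels. The grid is padded by
    ``m - 1`` pixels on every side so total mass is conserved exactly.
    """
    if pixel_nm <= 0:
        raise ParameterError("pixel_nm must be > 0")
    if len(table) == 0:
        raise EmptyInputError("cannot render an empty table")
    xy = table.xy
    pad = m - 1
    xmin, ymin = xy[:, 0].min(), xy[:, 1].min()
    x0 = xmin - pad * pixel_nm
    y0 = ymin - pad * pixel_nm
    # indices relative to the data minimum (exact at the minimum), then padded
    ix = np.floor((xy[:, 0] - xmin) / pixel_nm).astype(int) + pad
    iy = np.floor((xy[:, 1] - ymin) / pixel_nm).astype(int) + pad
    nx = ix.max() + 1 + pad
    ny = iy.max() + 1 + pad
    hist = np.zeros((nx, ny))
    np.add.at(hist, (ix, iy), 1.0)
    k = (1.0 - np.abs(np.arange(-(m - 1), m)) / m) / m  # sums to 1
    sm = np.apply_along_axis(np.convolve, 0, hist, k, "same")
    sm = np.apply_along_axis(np.convolve, 1, sm, k, "same")
    return DensityImage(pixels=sm, pixel_nm=float(pixel_nm), origin_nm=(float(x0), float(y0)))
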
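"""Localization table I/O, axis projection and STORM-style rendering.

The periodicity statistic operates on the 1D distribution of localizations
along the axon axis.  This module reads and writes localization tables as
plain delimited text, projects the (x, y) point cloud onto an axis — either
the cloud's first principal axis or a user-supplied polyline centerline — and
renders localizations as a sum of 2D Gaussian peaks for visual inspection.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely

from .exceptions import AxisError, FormatError, ParameterError, ProjectionError
from .synthetic import LocalizationTable

__all__ = [
    "AxisSpec",
    "Positions1D",
    "read_locs",
    "write_locs",
    "project_to_axis",
    "render_storm",
]

NATIVE_COLUMNS = ("axon_id", "x_nm", "y_nm", "z_nm", "frame")


@dataclass(frozen=True)
class AxisSpec:
    """How the axon axis is defined for 1D projection.

    ``mode='principal-axis'`` uses the dominant principal component of the
    (x, y) cloud; ``mode='polyline'`` uses the arc length along a supplied
    centerline, which also handles curved axons.
    """

    mode: str = "principal-axis"
    polyline: Optional[Sequence[Sequence[float]]] = None

    def __post_init__(self):
        if self.mode not in ("principal-axis", "polyline"):
            raise ParameterError(f"unknown axis mode {self.mode!r}")
        if self.mode == "polyline":
            if self.polyline is None or len(self.polyline) < 2:
                raise ParameterError("polyline mode requires >= 2 points")
            pts = np.asarray(self.polyline, dtype=float)
            if np.sum(np.hypot(*np.diff(pts, axis=0).T)) <= 0:
                raise ParameterError("polyline must have positive length")
        elif self.polyline is not None:
            raise ParameterError("polyline given but mode is not 'polyline'")


@dataclass
class Positions1D:
    """Axial coordinates (nm) of the retained localizations of one axon."""

    s_nm: np.ndarray
    extent_nm: tuple
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.s_nm)


def write_locs(table: LocalizationTable, path) -> None:
    """Write a localization table as delimited text with a fixed column order.

    Optional columns (z_nm, frame) are emitted only when present; the float
    formatting is value-exact, so write → read round-trips bit-for-bit.
    """
    cols = [c for c in NATIVE_COLUMNS if c in table.data.columns]
    extra = [c for c in table.data.columns if c not in cols]
    table.data[cols + extra].to_csv(path, index=False, lineterminator="\n")


def read_locs(path, dialect: str = "native", column_map: Optional[dict] = None) -> LocalizationTable:
    """Read a localization table from delimited text.

    ``dialect='native'`` expects the column names this package writes
    (``axon_id,x_nm,y_nm[,z_nm][,frame]``).  ``dialect='generic'`` accepts any
    CSV plus a ``column_map`` from source column names to native names;
    coordinates are taken to be in nm.  Unmapped columns are preserved and
    listed in the table metadata.
    """
    if dialect not in ("native", "generic"):
        raise FormatError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty localization file") from exc
    if df.empty and df.columns.size == 0:
        raise FormatError(f"{path}: empty localization file")

    if dialect == "generic":
        if column_map:
            df = df.rename(columns=dict(column_map))

    for required in ("x_nm", "y_nm"):
        if required not in df.columns:
            raise FormatError(f"{path}: missing coordinate column {required!r}")

    for col in ("x_nm", "y_nm", "z_nm"):
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"{path}: non-numeric {col} at row {row}")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise FormatError(f"{path}: missing {col} at row {row}")
        df[col] = coerced.astype(float)

    if "axon_id" not in df.columns:
        stem = os.path.splitext(os.path.basename(os.fspath(path)))[0]
        df.insert(0, "axon_id", stem)

    extra = [c for c in df.columns if c not in NATIVE_COLUMNS]
    meta = {"source": os.fspath(path), "dialect": dialect}
    if extra:
        meta["extra_columns"] = extra
    return LocalizationTable(df, meta)


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit vector of the dominant principal axis with a deterministic sign.

    Sign convention: positive projection onto +x; if the axis is exactly
    perpendicular to x, positive projection onto +y.
    """
    centered = points - points.mean(axis=0)
    if not np.any(centered):
        raise AxisError("degenerate point cloud: zero variance")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        v = -v
    return v


def project_to_axis(
    table: LocalizationTable,
    axis: Optional[AxisSpec] = None,
    corridor_nm: float = 500.0,
) -> Positions1D:
    """Project localizations onto the axon axis to get 1D axial positions.

    Localizations farther than ``corridor_nm`` (perpendicular distance) from
    the axis are dropped and counted.  In principal-axis mode the coordinates
    are shifted so the smallest retained position is 0; in polyline mode the
    coordinate is the arc length of the nearest point on the centerline.
    The z coordinate is ignored.
    """
    if axis is None:
        axis = AxisSpec()
    if corridor_nm <= 0:
        raise ParameterError("corridor_nm must be positive")
    points = table.xy()
    if len(points) < 2:
        raise ProjectionError("need at least 2 localizations to define an axis")

    if axis.mode == "principal-axis":
        v = _principal_axis(points)
        centered = points - points.mean(axis=0)
        s = centered @ v
        perp = centered @ np.array([-v[1], v[0]])
        keep = np.abs(perp) <= corridor_nm
        if not keep.any():
            raise ProjectionError("all localizations outside the axis corridor")
        s = s[keep]
        s = s - s.min()
        extent = (0.0, float(s.max()))
    else:
        line = shapely.LineString(np.asarray(axis.polyline, dtype=float))
        pts = shapely.points(points)
        dist = shapely.distance(line, pts)
        keep = dist <= corridor_nm
        if not keep.any():
            raise ProjectionError("all localizations outside the axis corridor")
        s = shapely.line_locate_point(line, pts[keep])
        extent = (0.0, float(line.length))

    return Positions1D(s_nm=np.asarray(s, dtype=float), extent_nm=extent,
                       n_dropped=int(len(points) - keep.sum()))


def render_storm(
    table: LocalizationTable,
    pixel_nm: float,
    sigma_nm: float,
    shape: Optional[tuple] = None,
    origin_nm: Optional[tuple] = None,
):
    """Render localizations as a sum of unit-integral 2D Gaussian peaks.

    Each localization contributes a Gaussian of width ``sigma_nm`` sampled at
    pixel centers ``(index + 0.5) * pixel_nm + origin`` and scaled by the
    pixel area, so its total intensity is 1 (to well under 0.1% for
    ``sigma_nm >= pixel_nm`` and peaks away from the border).  Returns
    ``(image, origin_nm)`` with image rows along y and columns along x.
    """
    if pixel_nm <= 0 or sigma_nm <= 0:
        raise ParameterError("pixel_nm and sigma_nm must be positive")
    if len(table) == 0:
        warnings.warn("rendering an empty localization table", stacklevel=2)
        out_shape = shape if shape is not None else (1, 1)
        out_origin = origin_nm if origin_nm is not None else (0.0, 0.0)
        return np.zeros(out_shape, dtype=float), tuple(out_origin)

    x = table.data["x_nm"].to_numpy(dtype=float)
    y = table.data["y_nm"].to_numpy(dtype=float)
    pad = 3.0 * sigma_nm
    if origin_nm is None:
        origin_nm = (x.min() - pad, y.min() - pad)
    ox, oy = float(origin_nm[0]), float(origin_nm[1])
    if shape is None:
        n_cols = int(np.ceil((x.max() + pad - ox) / pixel_nm))
        n_rows = int(np.ceil((y.max() + pad - oy) / pixel_nm))
        shape = (max(n_rows, 1), max(n_cols, 1))

    image = np.zeros(shape, dtype=float)
    norm = pixel_nm ** 2 / (2.0 * np.pi * sigma_nm ** 2)
    halfwin = int(np.ceil(8.0 * sigma_nm / pixel_nm))  # truncation error < 1e-13
    for xi, yi in zip(x, y):
        ci = (xi - ox) / pixel_nm - 0.5  # fractional column of the peak
        ri = (yi - oy) / pixel_nm - 0.5
        c0, c1 = max(0, int(np.floor(ci)) - halfwin), min(shape[1], int(np.ceil(ci)) + halfwin + 1)
        r0, r1 = max(0, int(np.floor(ri)) - halfwin), min(shape[0], int(np.ceil(ri)) + halfwin + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        xc = (np.arange(c0, c1) + 0.5) * pixel_nm + ox
        yc = (np.arange(r0, r1) + 0.5) * pixel_nm + oy
        gx = np.exp(-((xc - xi) ** 2) / (2.0 * sigma_nm ** 2))
        gy = np.exp(-((yc - yi) ** 2) / (2.0 * sigma_nm ** 2))
        image[r0:r1, c0:c1] += norm * np.outer(gy, gx)
    return image, (ox, oy)
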
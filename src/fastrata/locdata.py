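"""Localization tables, ROI polygons and rasterization.

A localization table is the standard output of single-molecule localization
microscopy (SMLM/PALM/iPALM): one row per detected molecule with lateral
(x, y) and axial (z) coordinates in nanometres, the acquisition frame, a
channel label (the tagged protein), and optionally a lateral localization
precision.  z is measured as distance from the coverslip; y increases
downward to match raster images.

This module is the I/O substrate for every analysis stage: reading/writing
the canonical CSV dialect (with a column-mapping hook for other exports,
e.g. ThunderSTORM-style headers), selecting localizations inside polygonal
regions of interest, and rasterizing point clouds into 2D count images.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon

from .exceptions import FormatError

#: canonical column order of the native CSV dialect
CANONICAL_COLUMNS = ("id", "frame", "x_nm", "y_nm", "z_nm", "channel", "precision_nm")
_MANDATORY = ("x_nm", "y_nm", "z_nm")

#: recognised ROI classes (adhesion, near-adhesion, away-from-adhesion,
#: colony-scale classes, and a catch-all)
ROI_CLASSES = frozenset(
    {"fa", "fa_adjacent", "fa_distal", "colony_edge", "colony_centre", "other"}
)


@dataclass
class LocalizationTable:
    """Ordered collection of localizations backed by a pandas DataFrame.

    Parameters
    ----------
    data
        DataFrame with the canonical columns (see :data:`CANONICAL_COLUMNS`).
    meta
        Free-form provenance (source file, generation seed, ...).
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.data
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"table missing columns: {missing}")
        if len(df):
            coords = df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
            if not np.isfinite(coords).all():
                raise ValueError("x_nm, y_nm, z_nm must be finite")
            if (df["frame"].to_numpy() < 0).any():
                raise ValueError("frame must be non-negative")
            prec = df["precision_nm"].to_numpy(dtype=float)
            if np.any(prec[~np.isnan(prec)] < 0):
                raise ValueError("precision_nm must be non-negative when present")
            if df["id"].duplicated().any():
                raise ValueError("localization ids must be unique")

    @classmethod
    def from_arrays(
        cls,
        x_nm,
        y_nm,
        z_nm,
        channel,
        frame=None,
        precision_nm=None,
        meta: dict | None = None,
    ) -> "LocalizationTable":
        """Build a table from coordinate arrays; ids assigned sequentially."""
        x = np.asarray(x_nm, dtype=float)
        n = len(x)
        if np.isscalar(channel) or isinstance(channel, str):
            channel = np.full(n, channel, dtype=object)
        df = pd.DataFrame(
            {
                "id": np.arange(n, dtype=int),
                "frame": np.zeros(n, dtype=int) if frame is None else np.asarray(frame),
                "x_nm": x,
                "y_nm": np.asarray(y_nm, dtype=float),
                "z_nm": np.asarray(z_nm, dtype=float),
                "channel": channel,
                "precision_nm": np.full(n, np.nan) if precision_nm is None else precision_nm,
            }
        )
        return cls(df, meta=dict(meta or {}))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> set:
        return set(self.data["channel"].unique()) if len(self.data) else set()

    @property
    def z(self) -> np.ndarray:
        return self.data["z_nm"].to_numpy(dtype=float)

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x_nm", "y_nm"]].to_numpy(dtype=float)

    def filter_channel(self, channel: str) -> "LocalizationTable":
        if channel not in self.channels:
            raise KeyError(f"unknown channel {channel!r}; have {sorted(self.channels)}")
        sub = self.data[self.data["channel"] == channel].reset_index(drop=True)
        return LocalizationTable(sub, meta=dict(self.meta))


@dataclass
class RoiRegion:
    """A labelled polygonal region of interest in nm coordinates."""

    label: str
    polygon: np.ndarray  # (n, 2) vertices, nm
    klass: str = "other"

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.klass not in ROI_CLASSES:
            raise ValueError(f"klass must be one of {sorted(ROI_CLASSES)}")
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        poly = Polygon(self.polygon)
        if not poly.is_simple or not poly.is_valid or poly.area <= 0:
            raise ValueError("polygon must be simple with positive area")

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.polygon)

    @property
    def area_nm2(self) -> float:
        return self.shapely.area


def read_localizations(path, dialect: dict | None = None) -> LocalizationTable:
    """Read a localization CSV.

    ``dialect`` maps canonical names to the file's column names, e.g.
    ``{"x_nm": "x [nm]", "y_nm": "y [nm]", "z_nm": "z [nm]"}`` for
    ThunderSTORM-style exports.  Units are taken as nm.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    if dialect:
        raw = raw.rename(columns={v: k for k, v in dialect.items()})
    for col in _MANDATORY:
        if col not in raw.columns:
            raise FormatError(f"missing mandatory column '{col}' in {path.name}")
    n = len(raw)
    out = {}
    for col in ("x_nm", "y_nm", "z_nm", "precision_nm"):
        if col in raw.columns:
            vals = pd.to_numeric(raw[col], errors="coerce")
            bad = vals.isna() & raw[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
                raise FormatError(f"non-numeric value in column '{col}' at data row {row}")
            out[col] = vals.to_numpy(dtype=float)
        else:
            out[col] = np.full(n, np.nan)
    if "frame" in raw.columns:
        frames = pd.to_numeric(raw["frame"], errors="coerce")
        if frames.isna().any():
            row = int(np.flatnonzero(frames.isna().to_numpy())[0]) + 1
            raise FormatError(f"non-numeric value in column 'frame' at data row {row}")
        out["frame"] = frames.to_numpy(dtype=int)
    else:
        out["frame"] = np.zeros(n, dtype=int)
    out["id"] = (
        pd.to_numeric(raw["id"]).to_numpy(dtype=int)
        if "id" in raw.columns
        else np.arange(n, dtype=int)
    )
    out["channel"] = (
        raw["channel"].astype(str).to_numpy(dtype=object)
        if "channel" in raw.columns
        else np.full(n, "ch0", dtype=object)
    )
    df = pd.DataFrame(out)[list(CANONICAL_COLUMNS)]
    return LocalizationTable(df, meta={"source": str(path)})


def write_localizations(table: LocalizationTable, path) -> None:
    """Write the canonical CSV (missing precision as empty fields)."""
    df = table.data[list(CANONICAL_COLUMNS)]
    df.to_csv(path, index=False)


def select_roi(
    table: LocalizationTable, roi: RoiRegion, channel: str | None = None
) -> LocalizationTable:
    """Subset localizations whose (x, y) lie inside ``roi``.

    Points exactly on the polygon boundary are included.  Row order is
    preserved; an unknown ``channel`` raises ``KeyError``.
    """
    if channel is not None:
        table = table.filter_channel(channel)
    df = table.data
    pts = shapely.points(df["x_nm"].to_numpy(float), df["y_nm"].to_numpy(float))
    keep = shapely.covers(roi.shapely, pts)  # covers => boundary inclusive
    meta = dict(table.meta)
    meta["roi"] = roi.label
    return LocalizationTable(df[keep].reset_index(drop=True), meta=meta)


def render_density(table: LocalizationTable, pixel_nm: float, bounds) -> np.ndarray:
    """Rasterize a table into a per-pixel localization count image.

    ``bounds`` is (x0, y0, x1, y1) in nm.  Pixel (i, j) covers the half-open
    square [x0 + j*p, x0 + (j+1)*p) x [y0 + i*p, y0 + (i+1)*p), so the sum
    over pixels equals the number of in-bounds localizations.
    """
    x0, y0, x1, y1 = map(float, bounds)
    if pixel_nm <= 0:
        raise ValueError("pixel_nm must be positive")
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate bounds: need x1 > x0 and y1 > y0")
    nx = int(np.ceil((x1 - x0) / pixel_nm))
    ny = int(np.ceil((y1 - y0) / pixel_nm))
    x = table.data["x_nm"].to_numpy(float)
    y = table.data["y_nm"].to_numpy(float)
    inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
    j = np.floor((x[inside] - x0) / pixel_nm).astype(int)
    i = np.floor((y[inside] - y0) / pixel_nm).astype(int)
    img = np.zeros((ny, nx), dtype=np.int64)
    np.add.at(img, (i, j), 1)
    return img


def write_density_tiff(image: np.ndarray, path) -> None:
    """Write a count image as a single-channel TIFF."""
    tifffile.imwrite(path, np.asarray(image))


def read_rois(path) -> list[RoiRegion]:
    """Read a JSON array of {label, klass, polygon: [[x, y], ...]} in nm."""
    with open(path) as fh:
        items = json.load(fh)
    return [
        RoiRegion(label=it["label"], polygon=it["polygon"], klass=it.get("klass", "other"))
        for it in items
    ]


def write_rois(rois: list[RoiRegion], path) -> None:
    items = [
        {"label": r.label, "klass": r.klass, "polygon": r.polygon.tolist()} for r in rois
    ]
    with open(path, "w") as fh:
        json.dump(items, fh, indent=1)
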
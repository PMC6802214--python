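"""Within-adhesion lateral architecture.

Three read-outs quantify how a protein is arranged across an adhesion's
footprint:

* normalized line intensity profiles across a rendered density image,
* edge-ring enrichment — the ratio of localization density in a rim strip
  just inside the adhesion outline to the density of the remaining
  interior (ring-like proteins such as beta5 integrin and talin give
  ratios > 1, uniform proteins give ~1),
* a quadratic (paraboloid) surface fit z(x, y) to the 3D point cloud,
  whose principal curvatures separate flat layers (paxillin) from cup
  shapes (vinculin).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import profile_line

from .locdata import LocalizationTable, RoiRegion

#: curvature magnitude below which a fitted surface is called flat (1/nm)
FLAT_CURVATURE_THRESHOLD = 1e-5
#: default rim width for the ring-enrichment metric (nm)
DEFAULT_RIM_WIDTH_NM = 200.0


@dataclass
class LineProfile:
    """Intensity along a segment, averaged over a perpendicular width and
    normalized so the maximum is 1."""

    positions_nm: np.ndarray
    values: np.ndarray  # in [0, 1], max exactly 1
    src: tuple
    dst: tuple
    width_px: int


@dataclass
class SurfaceFit:
    """OLS fit of z = c0 + c1 x + c2 y + c3 x^2 + c4 xy + c5 y^2."""

    coefficients: np.ndarray  # c0..c5
    curvatures: np.ndarray  # eigenvalues of [[2c3, c4], [c4, 2c5]], 1/nm
    rss: float
    n_points: int
    flat_threshold: float = FLAT_CURVATURE_THRESHOLD

    @property
    def is_flat(self) -> bool:
        return bool(np.all(np.abs(self.curvatures) < self.flat_threshold))


def line_profile(
    image: np.ndarray, src, dst, width_px: int = 1, pixel_nm: float = 1.0
) -> LineProfile:
    """Normalized line intensity profile between two (row, col) endpoints.

    Intensity is averaged perpendicular to the segment over ``width_px``
    pixels, sampled at pixel pitch, then divided by its maximum; an
    all-zero strip has no defined normalization and raises ``ValueError``.
    """
    if width_px < 1:
        raise ValueError("width must be at least 1 pixel")
    img = np.asarray(image, dtype=float)
    vals = profile_line(
        img, src, dst, linewidth=width_px, reduce_func=np.mean, mode="constant", order=0
    )
    peak = vals.max()
    if peak <= 0:
        raise ValueError("all-zero strip: normalization undefined")
    positions = np.arange(len(vals)) * pixel_nm
    return LineProfile(
        positions_nm=positions, values=vals / peak,
        src=tuple(src), dst=tuple(dst), width_px=width_px,
    )


def edge_enrichment(
    table: LocalizationTable, fa: RoiRegion, rim_width_nm: float = DEFAULT_RIM_WIDTH_NM
) -> float:
    """Rim/interior localization density ratio for one adhesion outline.

    The rim is the band of points within ``rim_width_nm`` of the polygon
    boundary (inside it); the interior is the rest.  Densities are
    count/area, so a laterally uniform protein gives ~1 and a ring-like
    protein gives > 1.  An empty interior yields ``math.inf`` with a
    warning; an empty rim yields 0.
    """
    poly = fa.shapely
    inner = poly.buffer(-rim_width_nm)
    if inner.is_empty or inner.area <= 0:
        raise ValueError("rim_width must be smaller than the polygon's minimal half-extent")
    import shapely as _sh

    xy = table.xy
    pts = _sh.points(xy[:, 0], xy[:, 1])
    in_poly = _sh.covers(poly, pts)
    in_interior = _sh.covers(inner, pts) & in_poly
    n_rim = int(in_poly.sum() - in_interior.sum())
    n_int = int(in_interior.sum())
    rim_area = poly.area - inner.area
    if n_int == 0:
        warnings.warn("empty interior: rim/interior density ratio is infinite")
        return math.inf
    rim_density = n_rim / rim_area
    interior_density = n_int / inner.area
    return rim_density / interior_density


def fit_paraboloid(table_or_xyz) -> SurfaceFit:
    """Fit the 6-term quadratic surface to a 3D point cloud by OLS.

    Accepts a :class:`LocalizationTable` or an (n, 3) array.  Curvatures
    are the eigenvalues of the Hessian [[2c3, c4], [c4, 2c5]]; both below
    the flatness threshold gives a "flat" verdict (positive curvature =
    cup opening upward, z increasing with r).
    """
    if isinstance(table_or_xyz, LocalizationTable):
        xyz = table_or_xyz.data[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    else:
        xyz = np.asarray(table_or_xyz, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3 or len(xyz) < 6:
        raise ValueError("need at least 6 (x, y, z) points")
    x, y, z = xyz.T
    design = np.column_stack([np.ones_like(x), x, y, x**2, x * y, y**2])
    if np.linalg.matrix_rank(design) < 6:
        raise np.linalg.LinAlgError("rank-deficient design (collinear points)")
    coef, _, _, _ = np.linalg.lstsq(design, z, rcond=None)
    resid = z - design @ coef
    hess = np.array([[2.0 * coef[3], coef[4]], [coef[4], 2.0 * coef[5]]])
    curv = np.linalg.eigvalsh(hess)
    return SurfaceFit(
        coefficients=coef, curvatures=curv, rss=float(resid @ resid), n_points=len(xyz)
    )
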
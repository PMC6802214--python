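"""Adhesion segmentation, colony edge/centre partition, and the
hyper-exponential adhesion-area model.

Focal-adhesion areas in stem-cell colonies are heavy-tailed: a weighted sum
of two exponential densities

    f(x) = w * exp(-x/A1)/A1 + (1 - w) * exp(-x/A2)/A2,    A1 < A2,

whose means A1 and A2 are the "characteristic areas" of the small and large
adhesion populations.  The canonical estimator here is maximum likelihood on
raw areas via expectation-maximization (EM); a histogram least-squares mode
is provided for comparison with binned-curve fits.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.optimize import curve_fit
from scipy.special import logsumexp
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops
from statsmodels.tools.numdiff import approx_hess

from .exceptions import FitError


@dataclass
class AdhesionMap:
    """Segmented adhesions: a labeled image plus a per-adhesion table
    (label, area_um2, centroid_x, centroid_y, klass)."""

    labels: np.ndarray  # 2D int image, 0 = background
    records: pd.DataFrame
    pixel_um: float

    def __len__(self) -> int:
        return len(self.records)

    @property
    def areas_um2(self) -> np.ndarray:
        return self.records["area_um2"].to_numpy(dtype=float)


@dataclass
class AreaMixtureFit:
    """Two-exponential (hyper-exponential) mixture fit, components ordered
    so that a1 < a2."""

    a1: float  # um^2, smaller characteristic area
    a2: float  # um^2, larger characteristic area
    w: float  # weight of the a1 component
    se_a1: float
    se_a2: float
    se_w: float
    loglik: float
    n: int
    n_iter: int
    converged: bool
    degenerate: bool = False
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def segment_adhesions(
    image: np.ndarray,
    pixel_um: float,
    min_area_um2: float = 0.05,
    threshold: float | None = None,
) -> AdhesionMap:
    """Threshold (Otsu by default), label 8-connected components and drop
    regions below ``min_area_um2``.  A blank image yields an empty map."""
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    img = np.asarray(image)
    if img.dtype == bool:
        binary = img
    else:
        if threshold is None:
            if img.max() == img.min():  # blank / constant image
                return AdhesionMap(
                    labels=np.zeros(img.shape, dtype=np.int32),
                    records=_empty_records(),
                    pixel_um=pixel_um,
                )
            threshold = threshold_otsu(img)
        binary = img > threshold
    lab = sk_label(binary, connectivity=2)
    px_area = pixel_um**2
    rows, keep_labels = [], []
    for rp in regionprops(lab):
        area = rp.area * px_area
        if area >= min_area_um2:
            keep_labels.append(rp.label)
            rows.append((rp.label, area, rp.centroid[1], rp.centroid[0]))
    # relabel sequentially, preserving scan order
    out = np.zeros_like(lab, dtype=np.int32)
    records = _empty_records()
    for new, (old, area, cx, cy) in enumerate(rows, start=1):
        out[lab == old] = new
        records.loc[len(records)] = (new, area, cx, cy, None)
    return AdhesionMap(labels=out, records=records, pixel_um=pixel_um)


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=["label", "area_um2", "centroid_x", "centroid_y", "klass"])


def partition_edge_centre(
    colony_mask: np.ndarray,
    strip_px: float | None = None,
    strip_um: float | None = None,
    pixel_um: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a colony mask into an edge strip and the remaining centre.

    The edge is the set of colony pixels within ``strip`` of the colony
    boundary (Euclidean distance to the outside), the centre is the rest;
    the two masks are disjoint and their union is the colony.  Presets of
    interest: a 40-pixel strip (fixed-cell analysis) and a 5-um strip
    (live-cell analysis, via ``strip_um`` and ``pixel_um``).
    """
    mask = np.asarray(colony_mask, dtype=bool)
    if not mask.any():
        raise ValueError("colony mask is empty")
    if strip_px is None:
        if strip_um is None or pixel_um is None:
            raise ValueError("give strip_px, or strip_um together with pixel_um")
        strip_px = strip_um / pixel_um
    if strip_px <= 0:
        raise ValueError("strip thickness must be positive")
    # pad so a colony touching the image border still has a boundary
    padded = np.pad(mask, 1)
    dist = distance_transform_edt(padded)[1:-1, 1:-1]
    edge = mask & (dist <= strip_px)
    centre = mask & ~edge
    if not centre.any():
        warnings.warn("strip exceeds colony half-width: centre region is empty")
    return edge, centre


def assign_classes(adhesions: AdhesionMap, edge_mask: np.ndarray) -> AdhesionMap:
    """Set each adhesion's klass to 'edge' or 'centre' by the majority of
    its pixels falling inside the edge mask (centroid as tie-break)."""
    edge_mask = np.asarray(edge_mask, dtype=bool)
    klass = []
    for _, row in adhesions.records.iterrows():
        pix = adhesions.labels == int(row["label"])
        n_edge = int((pix & edge_mask).sum())
        n_tot = int(pix.sum())
        if n_edge * 2 > n_tot:
            klass.append("edge")
        elif n_edge * 2 < n_tot:
            klass.append("centre")
        else:
            i, j = int(round(row["centroid_y"])), int(round(row["centroid_x"]))
            klass.append("edge" if edge_mask[i, j] else "centre")
    adhesions.records["klass"] = klass
    return adhesions


# ---------------------------------------------------------------------------
# hyper-exponential (two-exponential mixture) fitting


def _mixture_loglik(x: np.ndarray, a1: float, a2: float, w: float) -> float:
    log_f = np.logaddexp(
        np.log(max(w, 1e-300)) - np.log(a1) - x / a1,
        np.log(max(1.0 - w, 1e-300)) - np.log(a2) - x / a2,
    )
    return float(log_f.sum())


def _em_run(x, a1, a2, w, max_iter, tol):
    trace = []
    for it in range(max_iter):
        # E-step: responsibility of component 1
        l1 = np.log(max(w, 1e-300)) - np.log(a1) - x / a1
        l2 = np.log(max(1.0 - w, 1e-300)) - np.log(a2) - x / a2
        denom = np.logaddexp(l1, l2)
        r1 = np.exp(l1 - denom)
        ll = float(denom.sum())
        if trace and ll < trace[-1] - 1e-8:  # EM guarantee
            raise FitError("EM log-likelihood decreased", details={"iteration": it})
        if trace and abs(ll - trace[-1]) <= tol * (abs(ll) + 1.0):
            trace.append(ll)
            return a1, a2, w, np.array(trace), True
        trace.append(ll)
        # M-step
        s1 = r1.sum()
        s2 = len(x) - s1
        w = s1 / len(x)
        if s1 > 0:
            a1 = float((r1 * x).sum() / s1)
        if s2 > 0:
            a2 = float(((1 - r1) * x).sum() / s2)
        a1 = max(a1, 1e-12)
        a2 = max(a2, 1e-12)
    return a1, a2, w, np.array(trace), False


def fit_area_mixture(
    areas,
    n_starts: int = 5,
    max_iter: int = 5000,
    tol: float = 1e-10,
    seed: int = 0,
) -> AreaMixtureFit:
    """Maximum-likelihood fit of ``w*Exp(a1) + (1-w)*Exp(a2)`` by EM on raw
    areas, multi-start with best-likelihood selection.

    Components are reported ordered (a1 < a2); standard errors come from the
    observed information at the MLE.  Near-identical components are returned
    with the ``degenerate`` flag set rather than as an error.
    """
    x = np.asarray(areas, dtype=float)
    if len(x) < 50:
        raise ValueError("need at least 50 areas")
    if np.any(x <= 0):
        raise ValueError("areas must be positive")
    m = float(x.mean())
    rng = np.random.default_rng(seed)
    starts = [(0.5 * m, 2.0 * m, 0.5)]
    for _ in range(n_starts - 1):
        f = rng.uniform(0.2, 0.8)
        starts.append((m * rng.uniform(0.1, 0.9), m * rng.uniform(1.1, 4.0), f))
    best = None
    for a1_0, a2_0, w0 in starts:
        try:
            a1, a2, w, trace, conv = _em_run(x, a1_0, a2_0, w0, max_iter, tol)
        except FitError:
            raise
        ll = trace[-1]
        if best is None or ll > best[3][-1]:
            best = (a1, a2, w, trace, conv)
    a1, a2, w, trace, conv = best
    if not conv:
        raise FitError(
            "EM did not converge", details={"trace_tail": trace[-5:].tolist(), "n": len(x)}
        )
    if a1 > a2:  # ordering convention: a1 is the smaller characteristic area
        a1, a2, w = a2, a1, 1.0 - w
    degenerate = (a2 - a1) / a2 < 0.05 or w < 1e-3 or w > 1 - 1e-3
    se_a1 = se_a2 = se_w = np.nan
    if not degenerate:
        try:
            neg_ll = lambda p: -_mixture_loglik(x, p[0], p[1], p[2])
            hess = approx_hess(np.array([a1, a2, w]), neg_ll)
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
            se_a1, se_a2, se_w = map(float, se)
        except np.linalg.LinAlgError:
            pass
    return AreaMixtureFit(
        a1=float(a1), a2=float(a2), w=float(w),
        se_a1=se_a1, se_a2=se_a2, se_w=se_w,
        loglik=float(trace[-1]), n=len(x), n_iter=len(trace),
        converged=True, degenerate=degenerate, loglik_trace=trace,
    )


def fit_area_mixture_histogram(areas, bin_width_um2: float = 0.25) -> AreaMixtureFit:
    """Histogram least-squares variant of the hyper-exponential fit, for
    comparison with binned-curve analyses."""
    x = np.asarray(areas, dtype=float)
    if len(x) < 50:
        raise ValueError("need at least 50 areas")
    edges = np.arange(0, x.max() + bin_width_um2, bin_width_um2)
    counts, _ = np.histogram(x, bins=edges)
    centres = 0.5 * (edges[:-1] + edges[1:])
    dens = counts / (len(x) * bin_width_um2)

    def model(t, a1, a2, w):
        return w * np.exp(-t / a1) / a1 + (1 - w) * np.exp(-t / a2) / a2

    m = x.mean()
    popt, _ = curve_fit(
        model, centres, dens, p0=[0.5 * m, 2 * m, 0.5],
        bounds=([1e-6, 1e-6, 0.0], [np.inf, np.inf, 1.0]), maxfev=10000,
    )
    a1, a2, w = popt
    if a1 > a2:
        a1, a2, w = a2, a1, 1.0 - w
    ll = _mixture_loglik(x, a1, a2, w)
    return AreaMixtureFit(
        a1=float(a1), a2=float(a2), w=float(w),
        se_a1=np.nan, se_a2=np.nan, se_w=np.nan,
        loglik=ll, n=len(x), n_iter=0, converged=True,
        degenerate=(a2 - a1) / a2 < 0.05,
    )
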
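"""Vertical (z) layer decomposition of localization distributions.

The axial organisation of a focal-adhesion protein is summarised by binning
its localization z-coordinates into a 1-nm histogram and fitting one
Gaussian — or, for proteins occupying two discrete vertical layers (actin,
alpha-actinin), a sum of two Gaussians with independent centres and widths.
The fitted centre ``Z_centre`` and width ``s_vert`` of each layer are the
primary read-outs; per-ROI fits are combined into protein-level summaries
(mean/SD plus median, quartiles and median +/- 1.5*IQR whiskers).

Model order is chosen conservatively: two components are reported only when
the two-Gaussian fit improves BIC by at least ``BIC_MARGIN`` and the fitted
centres are not degenerate (closer than half the larger width).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .exceptions import FitError

#: BIC improvement a two-component fit must show to be selected
BIC_MARGIN = 10.0
#: relative RSS change considered converged between restarts
MAX_RESTARTS = 5


@dataclass
class ZHistogram:
    """Uniform-width histogram of vertical positions (default 1-nm bins)."""

    bin_edges: np.ndarray  # length n_bins + 1, nm
    counts: np.ndarray  # length n_bins, non-negative ints
    n_total: int
    roi_label: str | None = None
    protein: str | None = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        widths = np.diff(self.bin_edges)
        if len(widths) < 1 or not np.all(widths > 0):
            raise ValueError("bin edges must be strictly increasing")
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must have uniform width")
        if int(self.counts.sum()) != int(self.n_total):
            raise ValueError("sum(counts) must equal n_total")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class GaussianComponent:
    z_centre: float  # nm
    s_vert: float  # nm
    weight: float  # area fraction of this layer
    amplitude: float  # peak height in counts


@dataclass
class LayerFit:
    """Result of a 1- or 2-component Gaussian decomposition of a z-histogram."""

    model_order: int
    components: list[GaussianComponent]
    rss: float
    bic: float
    n_total: int
    converged: bool
    degenerate: bool = False

    def __post_init__(self):
        # components are always reported low-z first
        self.components = sorted(self.components, key=lambda c: c.z_centre)

    @property
    def z_centres(self) -> list[float]:
        return [c.z_centre for c in self.components]

    @property
    def s_verts(self) -> list[float]:
        return [c.s_vert for c in self.components]


@dataclass
class ComponentSummary:
    z_centre_mean: float
    z_centre_sd: float
    z_centre_median: float
    q1: float
    q3: float
    whisker_low: float  # median - 1.5 * IQR
    whisker_high: float  # median + 1.5 * IQR
    s_vert_mean: float


@dataclass
class ProteinSummary:
    """Per-protein combination of per-ROI layer fits."""

    protein: str
    model_order: int
    components: list[ComponentSummary]
    n_rois: int


@dataclass
class ModelSelection:
    order: int
    fit1: LayerFit
    fit2: LayerFit | None
    note: str = ""


def make_histogram(z_values, bin_width: float = 1.0, zrange=None) -> ZHistogram:
    """Bin z values into half-open [e, e+w) bins.

    The default range spans floor(min) .. ceil(max); values equal to the
    upper limit fall in the last bin only if the edge grid extends to cover
    them (half-open convention, no right-closure of the final bin).
    """
    z = np.asarray(z_values, dtype=float)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if zrange is None:
        if z.size == 0:
            raise ValueError("empty input requires an explicit range")
        lo, hi = float(np.floor(z.min())), float(np.ceil(z.max()))
    else:
        lo, hi = map(float, zrange)
    if hi <= lo:
        hi = lo + bin_width
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-12)))
    # extend by one bin if the max value sits exactly on the last edge
    if z.size and z.max() >= lo + n_bins * bin_width:
        n_bins += 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.floor((z - lo) / bin_width).astype(int)
    ok = (z >= lo) & (idx < n_bins) & (idx >= 0)
    counts = np.bincount(idx[ok], minlength=n_bins)
    return ZHistogram(bin_edges=edges, counts=counts, n_total=int(ok.sum()))


def pooled_histogram(z_lists, bin_width: float = 1.0, zrange=None) -> ZHistogram:
    """Histogram of localizations pooled across ROIs (alternative to
    fitting each ROI and averaging the fitted centres)."""
    return make_histogram(np.concatenate([np.asarray(z) for z in z_lists]), bin_width, zrange)


def _gauss1(z, a, mu, sigma):
    return a * np.exp(-((z - mu) ** 2) / (2.0 * sigma**2))


def _gauss2(z, a1, mu1, s1, a2, mu2, s2):
    return _gauss1(z, a1, mu1, s1) + _gauss1(z, a2, mu2, s2)


def _bic(rss: float, n_bins: int, k: int) -> float:
    # least-squares BIC over the binned counts
    rss = max(rss, 1e-12)
    return n_bins * np.log(rss / n_bins) + k * np.log(n_bins)


def _check_preconditions(hist: ZHistogram, min_occupied: int) -> None:
    if int((hist.counts > 0).sum()) < min_occupied:
        raise ValueError(f"need >= {min_occupied} occupied bins")
    if hist.n_total < 50:
        raise ValueError("need >= 50 localizations")


def _moment_init(hist: ZHistogram):
    c, w = hist.bin_centres, hist.counts.astype(float)
    mu = float(np.average(c, weights=w))
    sd = float(np.sqrt(np.average((c - mu) ** 2, weights=w)))
    return mu, max(sd, hist.bin_width / 2.0)


def _fit_curve(hist: ZHistogram, model, p0, bounds, restarts_of):
    """curve_fit with bounded deterministic restarts; best RSS wins."""
    centres, counts = hist.bin_centres, hist.counts.astype(float)
    best = None
    attempts = []
    rng = np.random.default_rng(0)
    for trial, start in enumerate([p0] + [restarts_of(rng) for _ in range(MAX_RESTARTS)]):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, centres, counts, p0=start, bounds=bounds, maxfev=5000
                )
            rss = float(np.sum((model(centres, *popt) - counts) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
            if trial == 0:
                break  # first start converged; keep it
        except RuntimeError as exc:
            attempts.append(str(exc))
    if best is None:
        raise FitError(
            "Gaussian fit did not converge after restarts",
            details={"attempts": attempts, "n_total": hist.n_total},
        )
    return best


def fit_gaussian(hist: ZHistogram) -> LayerFit:
    """Least-squares single-Gaussian fit ``A*exp(-(z-mu)^2/(2*sigma^2))``
    to the bin counts at bin centres.

    Requires >= 5 occupied bins and >= 50 localizations.
    """
    _check_preconditions(hist, min_occupied=5)
    counts = hist.counts.astype(float)
    mu0, sd0 = _moment_init(hist)
    a0 = float(counts.max())
    lo, hi = hist.bin_edges[0], hist.bin_edges[-1]
    span = hi - lo
    bounds = ([0.0, lo - span, hist.bin_width / 4.0], [np.inf, hi + span, 4.0 * span])

    def restarts(rng):
        return [a0 * rng.uniform(0.5, 1.5), mu0 + rng.normal(0, sd0), sd0 * rng.uniform(0.5, 2.0)]

    (a, mu, sigma), rss = _fit_curve(hist, _gauss1, [a0, mu0, sd0], bounds, restarts)
    comp = GaussianComponent(z_centre=float(mu), s_vert=float(abs(sigma)), weight=1.0, amplitude=float(a))
    return LayerFit(
        model_order=1,
        components=[comp],
        rss=rss,
        bic=_bic(rss, len(counts), k=3),
        n_total=hist.n_total,
        converged=True,
    )


def _peak_guesses(hist: ZHistogram):
    """Two most prominent local maxima of the 3-bin moving-average counts."""
    smooth = np.convolve(hist.counts.astype(float), np.ones(3) / 3.0, mode="same")
    peaks, props = find_peaks(smooth, prominence=0.0)
    if len(peaks) >= 2:
        top = peaks[np.argsort(props["prominences"])[::-1][:2]]
        return sorted(hist.bin_centres[top])
    return None


def _quartile_guesses(hist: ZHistogram):
    c, w = hist.bin_centres, hist.counts.astype(float)
    cdf = np.cumsum(w) / w.sum()
    return [float(c[np.searchsorted(cdf, q)]) for q in (0.25, 0.75)]


def fit_two_gaussians(hist: ZHistogram, init=None) -> LayerFit:
    """Least-squares fit of a sum of two Gaussians with independent centres
    and widths; components reported in ascending ``z_centre``.

    When the fitted centres collapse (|mu1 - mu2| < max(sigma)/2) the fit is
    still returned converged, with the ``degenerate`` flag set.
    """
    _check_preconditions(hist, min_occupied=10)
    counts = hist.counts.astype(float)
    mu0, sd0 = _moment_init(hist)
    if init is not None:
        g1, g2 = sorted(map(float, init))
    else:
        guesses = _peak_guesses(hist) or _quartile_guesses(hist)
        g1, g2 = guesses
    a0 = float(counts.max())
    s0 = max(sd0 / 2.0, hist.bin_width / 2.0)
    lo, hi = hist.bin_edges[0], hist.bin_edges[-1]
    span = hi - lo
    bounds = (
        [0.0, lo - span, hist.bin_width / 4.0] * 2,
        [np.inf, hi + span, 4.0 * span] * 2,
    )
    q1, q3 = _quartile_guesses(hist)

    def restarts(rng):
        # alternate quartile-based and jittered starts
        if rng.random() < 0.5:
            return [a0, q1, s0, a0, q3, s0]
        return [
            a0 * rng.uniform(0.5, 1.5), g1 + rng.normal(0, sd0 / 2), s0 * rng.uniform(0.5, 2),
            a0 * rng.uniform(0.5, 1.5), g2 + rng.normal(0, sd0 / 2), s0 * rng.uniform(0.5, 2),
        ]

    popt, rss = _fit_curve(hist, _gauss2, [a0, g1, s0, a0, g2, s0], bounds, restarts)
    a1, mu1, s1, a2, mu2, s2 = popt
    s1, s2 = abs(s1), abs(s2)
    # weights = area fractions of the two layers
    area1, area2 = a1 * s1, a2 * s2
    total = area1 + area2 if (area1 + area2) > 0 else 1.0
    comps = [
        GaussianComponent(float(mu1), float(s1), float(area1 / total), float(a1)),
        GaussianComponent(float(mu2), float(s2), float(area2 / total), float(a2)),
    ]
    # centre collapse, or one layer carrying (almost) no mass: either way
    # there is only a single effective centre
    degenerate = abs(mu1 - mu2) < max(s1, s2) / 2.0 or min(comps[0].weight, comps[1].weight) < 0.02
    return LayerFit(
        model_order=2,
        components=comps,
        rss=rss,
        bic=_bic(rss, len(counts), k=6),
        n_total=hist.n_total,
        converged=True,
        degenerate=degenerate,
    )


def select_model(hist: ZHistogram) -> ModelSelection:
    """Choose between one and two vertical layers.

    Returns 2 iff the two-component BIC improves on the single-component
    BIC by at least :data:`BIC_MARGIN` and the two centres are
    non-degenerate; otherwise 1 (parsimony default).
    """
    fit1 = fit_gaussian(hist)
    try:
        fit2 = fit_two_gaussians(hist)
    except (FitError, ValueError) as exc:
        return ModelSelection(order=1, fit1=fit1, fit2=None, note=f"two-component fit unavailable: {exc}")
    note = ""
    if hist.n_total < 200:
        note = "low-confidence: n_total < 200"
    two = (fit2.bic <= fit1.bic - BIC_MARGIN) and not fit2.degenerate
    return ModelSelection(order=2 if two else 1, fit1=fit1, fit2=fit2, note=note)


def summarize_protein(fits: list[LayerFit], protein: str) -> ProteinSummary:
    """Combine per-ROI fits into a protein-level summary.

    Per component: arithmetic mean and SD of ``Z_centre`` across ROIs, plus
    the box-plot statistics (median, quartiles, and whiskers at
    median +/- 1.5 * IQR).
    """
    if not fits:
        raise ValueError("need at least one fit")
    orders = {f.model_order for f in fits}
    if len(orders) != 1:
        raise ValueError(f"mixed model orders {sorted(orders)}; summarize separately")
    order = orders.pop()
    comps = []
    for k in range(order):
        zc = np.array([f.components[k].z_centre for f in fits])
        sv = np.array([f.components[k].s_vert for f in fits])
        q1, med, q3 = np.percentile(zc, [25, 50, 75])
        iqr = q3 - q1
        comps.append(
            ComponentSummary(
                z_centre_mean=float(zc.mean()),
                z_centre_sd=float(zc.std(ddof=0)),
                z_centre_median=float(med),
                q1=float(q1),
                q3=float(q3),
                whisker_low=float(med - 1.5 * iqr),
                whisker_high=float(med + 1.5 * iqr),
                s_vert_mean=float(sv.mean()),
            )
        )
    return ProteinSummary(protein=protein, model_order=order, components=comps, n_rois=len(fits))
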
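# Methods

This note records the models, estimators and numerical choices behind
`fastrata`, and what the synthetic generator does and does not emulate.

## Coordinate and data conventions

Localizations are continuous nm coordinates with the origin at the image
corner, y increasing downward to match raster images, and z the distance
from the coverslip.  The native CSV dialect is comma-separated with a
mandatory header (`id,frame,x_nm,y_nm,z_nm,channel,precision_nm`); other
exports are ingested through a column-mapping dialect rather than by
sniffing.  ROI polygons are closed simple polygons in nm; points exactly
on the boundary count as inside (`shapely` `covers`), a deterministic
convention chosen because any rule is defensible and this one is easiest
to test.  Rasterization uses half-open pixel intervals so no localization
is double-counted and per-pixel counts always sum to the in-bounds total.

## Vertical layer model

A protein's axial distribution within an adhesion is modelled as one or
two Gaussian layers.  The canonical estimator is **unweighted least
squares on the 1-nm-binned histogram** (bin centres vs counts), not
maximum likelihood on raw z: the histogram fit is the field's standard
read-out for this kind of data and keeps the estimator faithful to how
layer positions are conventionally reported.  Pooling localizations
across ROIs before fitting is available (`pooled_histogram`), but the
default combination averages per-ROI fitted centres, with box statistics
(median, quartiles, median ± 1.5·IQR whiskers) alongside mean ± SD.

Numerical choices, all fixed in code rather than inferred:

* initialization from histogram moments (single) or the two most
  prominent maxima of a 3-bin moving average (double), quartile-based
  starts as fallback; up to 5 deterministic restarts; `curve_fit` bounded
  with σ ≥ bin_width/4 and µ within one span of the data range.
* model selection returns two components only when the two-component BIC
  (least-squares BIC over bins, k = 3 vs 6) improves by ≥ 10 **and** the
  fit is non-degenerate.  Degeneracy means a single effective centre:
  |µ₁ − µ₂| < max(σ)/2, or one component carrying < 2 % of the fitted
  mass (amplitude collapse, which otherwise masquerades as a
  well-separated second layer).
* component weights are area fractions A·σ normalised across components;
  components are always reported low-z first, so relabelling inputs never
  changes the output.
* fits with n_total < 200 carry a low-confidence note; preconditions
  (≥ 5/10 occupied bins, ≥ 50 localizations) reject histograms too sparse
  to constrain the model.  A perfectly symmetric two-bin histogram is
  formally below the precondition; its symmetric centre is still exercised
  in tests through the internal fit routine with σ bounded away from the
  spike limit.

## Tag geometry

For a doubly-tagged molecule the signed separation Δz = z_C − z_N of the
two fitted layers gives the orientation verdict; |Δz| ≤ 5 nm is called
"level", a floor motivated by the sub-20 nm axial resolution class of the
instrument (configurable).  The inclination angle is
θ = arcsin(|Δz|/L) in degrees.  **L is a required user input**: the full
molecular length used in published θ values is not part of the data, and
shipping a guessed constant would silently parameterise other people's
results.  Output metadata records that θ was computed from summary-level
(not per-ROI) separations.

## Lateral architecture

* Line profiles average perpendicular to the segment over a stated width
  (`skimage.measure.profile_line`, nearest-neighbour sampling) and are
  normalized to their maximum; an all-zero strip is an error because the
  normalization is undefined.
* "Ring-ness" is operationalised as the rim/interior density ratio: rim =
  points within `rim_width` (default 200 nm) of the outline on the
  inside, obtained with a negative polygon buffer; densities are
  count/area.  Empty interiors return an infinite-ratio sentinel with a
  warning rather than an exception, since they are a legitimate extreme
  of ring-like data.  The metric is invariant under rigid motions.
* The surface fit is OLS on the 6-term quadratic; curvatures are the
  eigenvalues of [[2c₃, c₄], [c₄, 2c₅]].  Both |curvatures| below
  1e-5 nm⁻¹ gives a "flat" verdict; positive curvature means a cup
  opening upward (z increasing with r).  The threshold is a declared
  configuration value, not an estimate.

## Adhesion morphology and the area mixture

Segmentation is deliberately plain: global Otsu threshold (or a fixed
value), 8-connected components, minimum area 0.05 µm².  The colony edge
strip is defined by Euclidean distance to the colony boundary
(`distance_transform_edt` on the padded mask), with presets of 40 px
(fixed-cell) and 5 µm (live imaging); edge and centre masks are disjoint
and cover the colony exactly.

The area model is the hyper-exponential mixture
`w·Exp(A1) + (1−w)·Exp(A2)`, A1 < A2.  The canonical estimator is
**maximum likelihood via EM on raw areas** — statistically cleaner than a
binned histogram fit and free of bin-width choices; a histogram
least-squares mode exists for comparison with binned-curve analyses.
EM details: responsibilities in log-space, 5 starts (moment-based plus
seeded perturbations), convergence when the relative log-likelihood change
falls below 1e-10, cap 5000 iterations (the nearly-degenerate A2/A1 ≈ 2
regime genuinely needs ~10³ iterations), monotonicity asserted at every
step, components ordered a1 < a2 on exit, standard errors from the
numerically-differentiated observed information.  Fits with
(a2 − a1)/a2 < 5 % or w within 1e-3 of {0, 1} are flagged degenerate —
the data are then effectively single-exponential and A1/A2 are not
separately identified.

## Tracking and dynamics

Frame-to-frame linking is by maximal pixel overlap with deterministic
tie-breaks (larger overlap, then smaller label); on splits the largest
fragment keeps the identity; there is **no gap closing**, so a one-frame
disappearance ends a track.  Lifetime = frames present × frame interval,
capped (default 105 min, the shortest-replicate convention) before
binning; default bins are 15 min for lifetime and 0.5 µm² for maximal
size.  Coverage is the percentage of each class mask occupied by
adhesion pixels per frame; empty masks yield NaN with a warning.

## Synthetic generator

The generator emulates the statistical structure of the real data —
Gaussian vertical layers at the measured (Z_centre, s_vert) pairs
(`REFERENCE_LAYERS`), annular/ring/cup/wall lateral geometries, a uniform
[0, 300] nm z-background for the cytoplasmic fraction, hyper-exponential
area samples, and colony movies with stable edge adhesions (log-linear
growth to a maximal size, then static) versus centre adhesions with
exponential lifetimes (mean 20 min at 1 min/frame over 105 frames, a
realistic turnover contrast for this system).  Colony geometry defaults
(256² px at 0.5 µm/px, centred disc colony, 12 edge / 30 centre
adhesions) are package choices where no measured value exists.  One
explicit `numpy.random.Generator` per call; identical (spec, seed) pairs
are bit-identical.

It does **not** emulate photophysics (blinking, photon budgets,
localization precision as a function of signal), detector noise, drift,
or manual ROI outlining.  Passing recovery tests therefore demonstrates
estimator correctness under the declared generative model, not robustness
to instrument artefacts; real data additionally need the upstream
localization pipeline's quality controls.  Quantities the source
measurements never constrained — ring contrast, cup curvature (default
1e-4 nm⁻¹ in examples), movie birth rates — are free parameters of the
generator, not claims about cells.

## Problem sizes

Recovery checks use 20 000 localizations per protein ROI and 50 000 areas
per mixture fit — comfortably in the asymptotic regime for these
estimators while keeping the full suite fast; at these sizes the
Monte-Carlo error of a fitted layer centre is ~0.1–0.2 nm, an order of
magnitude below the ±2 nm acceptance band used in the tests.

## Known limitations

* The histogram fit ignores per-localization precision; a
  precision-weighted or MLE mode would be the natural extension.
* Overlap tracking has no gap closing and no merge bookkeeping beyond
  "larger fragment wins", so blinking segmentations fragment tracks.
* The two-Gaussian fit assumes at most two layers; more stratified
  distributions would need a general mixture with its own selection rule.
* `edge_enrichment` treats the polygon as exact; segmentation bias in the
  outline propagates directly into the ratio.
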
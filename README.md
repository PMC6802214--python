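# fastrata

Nanoscale architecture analysis of focal adhesions from 3D single-molecule
localization microscopy (iPALM-class) data, built around the layered
organisation of the large, stable "cornerstone" adhesions that ring human
pluripotent stem-cell (hPSC) colonies.

It is a library for microscopists and image analysts who have localization
tables (x, y, z per molecule, z measured from the coverslip) and adhesion
images, and want quantitative answers to:

* **Where does a protein sit vertically?**  Bin z into a 1-nm histogram and
  fit `A·exp(−(z−µ)²/2σ²)`; the fitted centre `Z_centre` and width `s_vert`
  define the protein's layer.  Proteins occupying two discrete layers
  (actin, α-actinin) are fitted with a sum of two Gaussians with independent
  centres and widths; a BIC criterion (margin ≥ 10, non-degenerate centres)
  decides the model order.  Per-ROI fits combine into protein summaries
  (mean/SD, median, quartiles, median ± 1.5·IQR whiskers).
* **Which way up is a molecule?**  For N- and C-terminally tagged
  constructs, the signed separation Δz = z_C − z_N gives the orientation
  verdict and, with a user-supplied molecular length L, the inclination
  angle θ = arcsin(|Δz|/L).
* **How is a protein arranged laterally?**  Normalized line profiles,
  rim/interior density ratios (ring-forming proteins such as β5 integrin
  and talin give ratios ≫ 1), and a quadratic surface fit
  `z = c0 + c1x + c2y + c3x² + c4xy + c5y²` whose principal curvatures
  separate flat layers (paxillin) from cup shapes (vinculin).
* **How big and how stable are adhesions?**  Adhesion areas follow a
  hyper-exponential law `w·Exp(A1) + (1−w)·Exp(A2)` with characteristic
  areas A1 < A2, fitted by EM on raw areas; movies are tracked by pixel
  overlap to get per-class (colony edge vs centre) lifetime and
  maximal-size distributions and coverage fractions.

A synthetic-data module generates localization tables, area samples and
colony movies at the measured cornerstone-adhesion parameters, so every
stage is testable with exact ground truth and no downloads.

## Worked example

```sh
python examples/layer_decomposition.py
```

```
paxillin: Z_centre = 55.7 nm, s_vert = 8.4 nm
actin: 2 layers selected; centres 99.7 and 155.3 nm (separation 55.6 nm)
```

20 000 synthetic paxillin localizations are generated at the reference
layer (55.7 ± 8.5 nm) and the fit recovers the layer to sub-nm accuracy;
for actin the selector correctly chooses two components and recovers both
layer centres, whose ~56 nm separation brackets the low-density gap
between the two actin populations.  The other scripts in `examples/` cover
tag orientation (`tag_orientation.py`: talin C-above-N at +30 nm, vinculin
N-above-C at −24 nm), lateral architecture, area mixtures and colony
dynamics, each printing one or two interpreted numbers.

A thin CLI mirrors the library for shell pipelines, e.g.

```sh
strata simulate --spec paxillin.yaml --seed 7 --out run/
strata zprofile --loc run/localizations.csv --model auto --out run/fits/
```

Every stage writes a `manifest.json` (version, full config, input hashes)
from which its outputs can be regenerated.

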
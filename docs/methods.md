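# Methods

## Pipeline model

The analysis treats a stained whole-lung section as a binary tissue field
observed through an RGB raster. Five stages:

1. **Exclusion.** Large bronchi and vessels (diameter > 200 µm) and their
   peri-structural collagen are removed before any measurement, either via a
   single-channel exclusion mask aligned to the image or as "sentinel"
   pixels: regions painted pure white into the image itself (a common manual
   erasure workflow). Sentinels are recognised within a small channel
   distance of (255, 255, 255), default tolerance 2.
2. **Segmentation.** Masson-trichrome tissue (collagen blue, muscle and
   cytoplasm red-purple) is saturated and dark against the near-white slide,
   so tissue vs background is decided by a Rec. 601 luminance threshold
   (0.299 R + 0.587 G + 0.114 B), fixed or chosen by Otsu's method on the
   non-sentinel pixels. No colour deconvolution is attempted: the indexes
   measure tissue density, not collagen content specifically.
3. **Reduction.** The binary mask at scan resolution is block-averaged by an
   integer factor into a per-pixel tissue *fraction* image at the analysis
   resolution of 3.632 µm/px (factor 8 for an x20 scan at ~0.454 µm/px;
   factor 4 from 0.908 µm/px). Trailing partial blocks are averaged over
   their true pixel count so border tissue is not diluted. A continuous
   "soft" per-pixel fraction, (threshold − luminance)/threshold clamped to
   [0, 1], is available for inputs that only exist at the reduced
   resolution; without it, 2×2-px tiles would quantise to multiples of 1/4.
4. **Footprint and inclusion.** The section footprint is recovered from the
   thin septal network by morphological closing (disk radius 10 px ≈ 36 µm,
   sized to bridge alveolar lumens), filling of interior holes below 5000 px,
   and removal of components below 0.1% of the image area. The tile-eligible
   domain is footprint AND NOT exclusion.
5. **Tiling and grading.** Square micro-tiles (default 2 px = 7.264 µm side,
   52.8 µm² area) are anchored at the raster origin. A tile is included iff
   it is a full tile and the fraction of its pixels inside the inclusion
   domain is ≥ `min_inclusion` (default 1.0). Its density is the sum of the
   tissue fraction over **all** tile pixels divided by the full tile pixel
   count — the denominator is never renormalised to the included part, which
   keeps the definition "tissue area over total tile area" exact; partial
   border tiles are excluded rather than rescaled.

Dm is the arithmetic mean of included tile densities. Densities are graded
into 20 classes of width 0.05, lower-inclusive — class k covers
[(k−1)·0.05, k·0.05), class 20 closed at 1.0 — so both endpoints map
unambiguously and HDFm at threshold 12 equals the fraction of tiles with
d ≥ 0.55. Class membership is computed against the canonical double-precision
values of the decimal boundaries k/20 (naive division by 0.05 misplaces
exact boundaries: 0.95/0.05 = 18.999…).

## HDFm calibration

The HDFm threshold is a property of the control group: the per-class mean of
the control histograms is scanned from class 20 downward, and the threshold
is the lowest class from which every class stays below the cutoff (default
1%, a parameter). The scan stops at the first class at or above the cutoff,
so the range is contiguous to class 20; an isolated quiet class further down
never extends it. Averaging weights each control section equally
(`combine="mean"`); tile-count weighting (`combine="pool"`) is available, as
is tile-pooling of multiple sections per animal before calibration. If class
20 itself is at or above the cutoff, calibration fails loudly rather than
returning a vacuous threshold.

## Reconstruction

Each included tile is painted with its class colour on a fixed 20-step
linear RGB gradient from light blue (173, 216, 230) to yellow (255, 255, 0);
excluded tiles take the background colour (white). The true palette of the
original instrument is not published, so a reproducible gradient was chosen
over fidelity; a user palette file (20 lines `class,R,G,B`) overrides it.
The output raster has the analysis pixel pitch, so it overlays 1:1 on the
reduced section.

## Statistics layer

Dose-response contrasts against the control group use one-way ANOVA followed
by Dunnett's test (multivariate-t formulation, `scipy.stats.dunnett`) for
continuous readouts, and Kruskal–Wallis followed by Dunn's test for ordinal
readouts (Ashcroft scores by default). Dunn's contrasts are rank z-tests
with the tie-corrected rank variance, Bonferroni-adjusted over the control
contrasts only. A readout that is constant across all groups is degenerate
and reported as p = 1 with a warning. Correlations are Spearman rank
correlations (pairwise-complete), reported with an ordinary least-squares
slope and intercept for plotting; group tests drop animals listwise.
Significance stars follow the 0.05 / 0.01 / 0.001 / 0.0001 convention.

## Synthetic sections

The generator emulates the *tile-density statistics* of lung parenchyma, not
its photographic appearance.

- **Septal network.** A Gaussian random field (white noise smoothed with a
  Gaussian kernel, σ = `alveole_scale_um` / pitch / 3) defines a cellular
  pattern; tissue is every pixel within a fixed distance of the field's zero
  contour, computed by an exact Euclidean distance transform. The distance
  threshold is the quantile of the (tie-jittered) distance map that hits the
  target tissue fraction, so walls have uniform thickness and the fraction is
  exact to ±0.01 by construction. A level-set construction (|field| < ε) was
  rejected: near critical points of the field it degenerates into solid
  blobs that grossly inflate the high-density tile frequencies.
- **Network scale.** `alveole_scale_um` defaults to 10 µm. At a 25% tissue
  fraction this yields ~3 µm walls, thin relative to the 7.26 µm micro-tile,
  which reproduces the control-lung regime: most frequency mass in low
  classes and < 1% per class from roughly class 12–13 upward. Real mouse
  parenchyma combines 30–60 µm alveolar lumens with 2–5 µm septa plus
  intra-septal capillary texture; a single fine scale stands in for that
  composite. Rendered sections therefore look finer-grained than real
  histology — a deliberate trade of visual realism for correct per-tile
  density statistics.
- **Fibrotic foci** are disks (lognormal radii, default median 100 µm) placed
  by dart throwing — centres uniform over the footprint, rejected inside
  existing foci — until the requested fraction of the footprint is covered;
  5000 consecutive rejections abort generation as unreachable coverage.
  Inside a focus, tissue is i.i.d. per-pixel Bernoulli at `lesion_density`
  (default 0.9), so in-focus tile densities concentrate near 0.9. Foci may
  overlap vessel exclusion zones, as peribronchial fibrosis does.
- **Vessels** are rings (default 3 per section, 250 µm outer diameter, wall
  12% of radius) whose filled outline plus a 15 µm margin is recorded in the
  exclusion mask; lumens carve the septal field.
- **Rendering.** Septa and vessel walls take a red-purple hue (150, 80, 115),
  focal tissue a collagen-blue (95, 105, 165), background near-white
  (247, 245, 248), plus i.i.d. Gaussian channel noise (σ = 5). The elliptical
  section footprint keeps a slide margin of at least 50 µm so the
  footprint-closing morphology cannot bleed to the raster border at any
  section size.
- **Ground truth** per-tile densities are computed from the truth mask by the
  pipeline's own tiling definition (reduction + tiling), with the inclusion
  domain = analysis pixels fully inside the ellipse and touching no excluded
  native pixel.

Default section geometry is 1.8 × 1.8 mm at 0.908 µm/px native pitch,
reduced ×4 to 3.632 µm/px — a desk-scale stand-in for a whole lobe section
(real sections are 5–10 mm across) that still yields ~37 000 micro-tiles.
Unit tests use 0.4–0.6 mm sections; at that miniature scale a single
> 200 µm vessel exclusion would swallow much of the footprint, so
study-level tests run vessel-free.

## Synthetic studies

A study is one section per animal: one saline control group (n = 6) and four
dose groups (n = 12) at 0.25/0.5/0.75/1.0 mg/kg, the standard 14-day
bleomycin dose-response design. The dose → mean lesion coverage map defaults
to {0.07, 0.10, 0.13, 0.16}, which places group-mean Dm increments over
control in the ~18–42% band while HDFm rises by several hundred to over a
thousand percent; per-animal coverage scatters around the group mean by a
lognormal factor (σ = 0.2) to emulate biological variability. Dm/HDFm are
measured either by the full RGB pipeline (`measure="pipeline"`, the default)
or directly from the truth masks (`measure="truth"`, fast and noise-free);
the HDFm threshold is calibrated from the control group at the 1% cutoff.

Covariates derive from the achieved coverage c through the saturating link
g(c) = c/(c + 0.10) plus Gaussian noise (defaults in parentheses):

| covariate | link | unit | noise sd |
|---|---|---|---|
| Ashcroft score | round(8·g), clipped to 0–8 | ordinal | 0.6 |
| micro-CT HU peak | −480 + 500·g | HU | 20 |
| Cdyn | 0.040·(1 − 0.65·g) | mL/cmH₂O | 0.0025 |
| FVC | 1.20·(1 − 0.45·g) | mL | 0.05 |
| lung wet weight | 150·(1 + 1.4·g) | mg | 10 |
| body weight | 24 − 3.5·g | g | 0.8 |

These noise scales put the synthetic Spearman correlations of HDFm with the
covariates in the 0.6–0.95 band — informative but not degenerate. All
randomness flows from a single master seed through
`numpy.random.SeedSequence`-derived per-animal seeds; identical seeds give
bit-identical studies. Because 54 native-resolution images would hold
~0.6 GB, section bundles are retained only when `keep_sections=True`; the
study object always carries the per-animal table, histograms and
calibration.

## What passing tests do and do not show

The generator proves internal consistency: that the pipeline recovers known
tile-density ground truth (end-to-end Dm within ±0.03 of the truth-mask Dm),
that the calibration rule behaves as specified, and that the dose-response
and correlation machinery reproduce the expected orderings and
directionalities. It does not validate the segmentation against real
staining variability, scanner colour profiles, tissue folds, or the spatial
(peribronchial/subpleural) localisation of real fibrosis — foci here are
uniformly placed. Absolute HDFm percent changes on synthetic studies can
exceed the real-tissue regime because the synthetic control background above
the threshold is cleaner than residual collagen and erythrocytes on real
slides.

## Numerical and degenerate-input choices

- Tile densities from a factor-4 reduction of a binary mask are multiples of
  1/64; the blocked computation is exactly equal to a per-pixel loop on
  binary inputs (dyadic sums), and is tested for exact equality.
- Grid anchoring is deterministic at the top-left origin; no tie-breaking is
  needed anywhere in the pipeline.
- An all-white image yields an empty tissue mask under a fixed threshold but
  is an error under Otsu (nothing to threshold on); an empty tissue raster
  has no footprint (error), while morphology that removes everything returns
  an empty footprint; an empty inclusion domain fails at tiling with an
  explicit "empty section" error.
- Constant columns in group tests return p = 1 with a warning rather than
  NaN; zero-variance correlation inputs are an explicit error.
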
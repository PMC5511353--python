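# Methods

This note documents the models, conventions, parameters and numerical
choices behind `ccsquant`, including where the design was genuinely open
and what the synthetic validation does and does not establish.

## Coordinate and raster conventions

Continuous coordinates are nanometres with the origin at the top-left
corner of the field, x rightward, y downward. Raster pixel *i* covers
the half-open interval [i·p, (i+1)·p) nm, so a localization on a pixel
edge belongs to exactly one pixel. Frames are 0-based; time is
frame × frame interval. Localization tables are treated as unordered
sets: permuting rows changes no result (tested).

## Rendering and brightness

Scenes are rendered at 20 nm/pixel. Two modes exist:

* **histogram** — each localization adds 1 to its containing pixel.
  Pixel values are localization counts; this image defines *brightness*
  (localizations per pixel) everywhere brightness is measured.
* **normalized_gaussian** — each localization adds a unit-integral 2D
  Gaussian of sd equal to its localization uncertainty (fallback: one
  pixel), discretized by integrating the Gaussian over pixel intervals.
  Total mass equals the localization count up to edge clipping. This
  image is a density estimate and drives segmentation shape.

Measuring brightness on the histogram image matters: the "scattered
single-molecule background" estimate is the mean over *non-zero* pixels,
which for homogeneous Poisson background with per-pixel mean µ converges
to µ/(1−e^(−µ)) ≈ 1 at realistic sparsity. On a Gaussian render the
same estimator would average kernel tails and be meaningless as a
count.

The 3×3 uniform mean filter exists for display only; filtered images
are flagged and refuse quantification.

## Segmentation and morphometrics

The default threshold is Otsu on the log1p-transformed rendered image
(manual override always available — segmentation of real data was
historically done interactively, and automation is what makes the
pipeline reproducible). Components are 8-connected; objects under
2 pixels are discarded.

Sub-400-nm objects are then re-sized at **half their interior level**
(FWHM sizing): the interior level is estimated as the footprint's 75th
percentile, and the object is cut at half that value. Rationale: a
compact structure blurred by localization precision σ has its true edge
at the half-interior contour, whereas a single global threshold sits far
down the blurred skirt and inflates equivalent diameters by ~20% at
pit scales. The upper quartile sits on the interior plateau of a blurred
disk while resisting inflation by shot-noise maxima (the 95th percentile
over-estimates the level by ~1.6 noise sd and biases diameters ~13 nm
low). Objects larger than 400 nm are insensitive to precision blur
relative to their size and keep the global-threshold footprint.

Morphometrics per object: area; perimeter by weighted boundary counting;
circularity 4πA/P², clipped at 1.05 to absorb pixelation; equivalent
diameter 2·√(A/π); maximum/minimum Feret diameters from the convex hull
of pixel corners (rotating-calipers width for the minimum); hole count
as 1 − Euler number with 8-connected foreground (hence 4-connected
background); mean brightness from the histogram image; centroid
intensity-weighted.

## Classification rules

* pit: equivalent diameter in the **closed** interval [100, 200] nm,
  AND (circularity ≥ 0.7 OR hole count ≥ 1), AND brightness ratio ≥ 2.
* plaque: minimum Feret diameter **strictly** greater than 200 nm
  ("larger than 200 nm in each direction" read literally as the minimal
  caliper width) AND brightness ratio strictly below 2.
* otherwise unclassified.

The circularity cutoff 0.7 quantifies "circular" tolerantly for 5–10 px
objects; the brightness boundary at exactly 2.0 belongs to the pit rule
(≥) and not the plaque rule (<), so the two rules are mutually exclusive
with no gap in brightness. Pits overlapping plaques are recovered by
re-thresholding each plaque footprint at 2× background and applying the
pit geometric rules to the sub-components; recovered pit pixels are
removed from the plaque. How such composites should be tallied is an
explicit policy of this package, as is measuring the background
per-image outside all segmented objects rather than per cell.

## Peripheral ROI and CCS metrics

The analysis band is the cell polygon minus its inward offset by the
band width (default 3 µm), rasterized at the working pixel size by
pixel-centre membership. If the erosion empties the polygon the band
degrades to the whole cell with a warning. Pits are counted by centroid
membership (pits are integer events); plaques contribute their
pixel-level intersection with the band (plaques are areas). Pit density
and plaque-covered fraction follow directly.

## Chromatic registration and CBC

Registration is a 2D affine (6 parameters) fitted by least squares to
≥3 non-collinear matched bead pairs; on noise-free data recovery is
exact to machine precision, and with isotropic noise sd σ the residual
RMS is σ·√(2(n−3)/n) (both tested). The CBC implementation follows the
standard published definition (neighbour-count curves area-normalized at
r_max, Spearman correlation with average ranks for ties, exponential
distance weight); r_max = 300 nm and 10 radii are conventional defaults
that must be reported alongside any score, as the appropriate radius
depends on structure scale. Neighbour searches use a k-d tree whose
counts are verified against brute-force distance computation in tests.

Two estimator properties worth knowing:

* On sparse complete-spatial-randomness data the score has an intrinsic
  **positive bias** (~0.1 at 10–40 points/µm², r_max 300 nm): both
  neighbour curves are piecewise-decreasing in r between count steps, so
  even independent channels rank-correlate positively. The bias shrinks
  with density; the null validation uses 1000 points in a 3×3 µm field
  (~111/µm², typical of clustered SMLM data).
* The identical-channel sanity check (mean ≥ 0.9) holds for clustered
  scenes. Isolated single localizations score low against their own
  channel because the self-count asymmetry distorts near-empty
  neighbourhoods — such points carry no colocalization information
  either way.

## Movie preprocessing, masks and tracking

"Automatic thresholding" means per-frame Otsu everywhere it occurs
(bleach correction, background medians) — one auditable convention.
Temporal filters use shrinking windows at the edges (no fabricated
pre-acquisition frames) and accept odd windows only; the workflow's
10 s median at 1 frame/s is therefore realized as a 9-frame window.

Bleach correction rescales each frame by (S₀−B₀)/(S_t−B_t) with S/B the
Otsu-class means; it is idempotent by construction and exact on
exponential decay (tested to 1e-6). A vanishing contrast at any frame is
an error naming the frame.

CCS masks: per frame, bilateral filter (spatial radius 1 px, intensity
range 3× the background sd) followed by a per-pixel moving-window
isodata iteration (half-size 10 px, convergence 0.5 intensity units) —
a deterministic stand-in for an interactive local-threshold step that
cannot be reproduced exactly. The local threshold is floored at
background + 3× the robust background spread, with the spread taken as
the frame's scaled median absolute deviation (sub-Otsu statistics are
truncated and underestimate the sd on structure-free frames), plus a 5%
dynamic-range contrast floor that keeps the far tails of bright
structures out of noise-free masks. Masks are cleaned by hole filling
and removal of components under 3 px. The isodata level tracks roughly
half-maximum, so masks approximate structure cores (~1.5σ of a Gaussian
spot); validation is at object level — every planted structure detected,
every mask component explained by a planted structure — which is the
property tracking depends on. Pixel-perfect boundary agreement is not
claimed and not achievable at SNR 10 on diffraction-scale spots.

Tracking is frame-pair linear assignment on squared displacement with
birth/death dummy cost equal to the squared maximum displacement
(300 nm/frame for CCSs; 15 µm/frame for nucleus tracks), no gap closing,
splitting or merging. The assignment equals exhaustive enumeration on
small instances (tested). Detections are intensity-weighted centroids of
mask components. Migration statistics optionally keep only tracks
spanning the entire movie (the convention that excludes mitotic cells).

Receptor enrichment: per frame, the median of sub-Otsu pixels of the
signal frame is subtracted, the mean over CCS-mask pixels is taken, and
the series is normalized to its pre-stimulation mean (exactly 1 by
construction). Frames with empty masks propagate as missing values —
interpolation would manufacture dynamics. Kymographs are bilinear line
profiles stacked over time, thin regions averaged across width. The
EPI/TIRF internalization ratio background-subtracts both channels the
same way (a documented choice), averages over the cell mask, and
normalizes to the first frame.

## Biosensor translocation

The membrane is the outer band of the cell outline (default width 1 µm,
a plausible default that should be set per dataset); the cytoplasm is
the remainder; the two masks partition the cell. The M/C ratio is
computed per frame after Otsu background subtraction and is invariant to
global intensity scaling. Human "blind scoring" of responsive cells is
replaced by an explicit criterion: a trace is responsive iff it exceeds
baseline mean + 3 sd for ≥2 consecutive post-stimulus frames (both
parameters exposed). No attempt is made to mimic any particular human
rater's implicit threshold.

## The synthetic-data generator

The generator emulates the statistical structure of the data the
pipeline is built for; its defaults are the reference conditions of all
validation:

* **Pits**: disks, or annuli with inner radius half the outer for the
  30% donut fraction; diameters from a truncated normal, mean 120 nm,
  sd 25 nm, support [100, 200] nm (inverse-CDF sampling — clipping
  would put a probability atom exactly on the classification boundary).
* **Plaques**: circles with radius 250–600 nm perturbed by Fourier
  modes 2–5 (amplitudes up to 0.35/(m−1)), giving irregular simple
  polygons whose minimum extent stays above the pit range. No published
  quantitative plaque-shape statistics exist; these parameters are a
  documented free choice, not a fit.
* **Brightness**: factors are defined relative to the *apparent*
  background (mean count over occupied 20-nm pixels) — pits 3×,
  plaques 1.3×, straddling the 2× boundary. Emitted counts are Poisson
  with the expectation corrected for the rim leak caused by precision
  jitter (a fraction ≈ 0.8·σ/R of the mass crosses the edge; donut
  emission concentrates on the annulus, raising the leak 4/3-fold), so
  the *delivered* in-footprint brightness honours the configured factor.
* **Background**: homogeneous Poisson, default 25/µm². Localization
  precision σ = 12 nm jitters every emitted position and is written to
  the uncertainty column. Every localization carries a `truth_id`
  linking it to its source structure (or −1 for background).
* **Movies**: Gaussian spots (σ 1.5 px, truncated at 4σ — finite PSF
  support), amplitude 100 over background 10, exponential lifetimes,
  frame-wise exp(−t/τ) bleaching applied to every fluorophore channel,
  post-stimulus receptor recruitment by a configurable fold with
  first-order kinetics (τ = 0 gives a step), Poisson then Gaussian read
  noise applied last so zero-noise oracles stay closed-form.
* **Sensor movies**: an elliptical cell with uniform cytoplasm whose
  peripheral band rises to gain × cytoplasm after stimulation; the band
  is rasterized with the same geometry code the analyzer uses, so
  zero-noise ratios are exact.

One global integer seed drives everything; per-operation substreams
(CRC-keyed) keep outputs bit-reproducible and independent across
generators.

What passing tests on these data do **not** show: robustness to drift
and fixation artefacts, overlapping/merging real structures, antibody
labelling inhomogeneity, camera pattern noise, cell-to-cell background
variation, or any optics beyond an isotropic Gaussian blur. The
generator contains no PSF engine and no raw-frame SMLM simulation; it
validates the quantification logic, not a localization pipeline.

## Validation problem sizes

The shipped validation uses desk-scale problems chosen to exercise every
code path with tight statistics: 50-pit/5-plaque scenes on a 15×15 µm
field (~20k localizations), 1000-point CSR fields for the CBC null,
50-bead registration fields, 120-frame movies with 15 structures for the
persistence contrast (mean lifetimes 5 s vs 20 s, ratio 4), and
10-cell sensor populations with 40% true responders.

## Known limitations

* The interactive local-threshold step of the original workflow is
  approximated by a deterministic isodata iteration; only the stand-in's
  parameters are guaranteed.
* Brightness-based rules assume a roughly uniform labelling density;
  strong spatial variation in background would require per-region
  background estimates.
* 3D (astigmatic) localization data are out of scope; z columns are
  carried through as opaque extras.
* The classifier's equivalent diameter is an area-based estimator;
  comparisons with diameter statistics measured differently (e.g. Feret
  means) need a conversion.
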
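# Methods

## Problem and pipeline

Coarctation of the aorta (CoA) is diagnosed morphometrically from the
minimum internal diameters of five aortic sites measured on cross-sections
cut perpendicular to the vessel centerline. `coameter` implements the
image-processing half of that workflow — from a rendered cross-section
image to a calibrated minimum diameter — plus the rule-based classifiers
and the diagnostic evaluation. The 3D reconstruction and sectioning that
produce the images are upstream of this package and out of its scope, as
is any Z-score-based criterion.

The measurement chain is deterministic: HSV colour segmentation →
morphological cleanup → contour of the largest component → moment
centroid → polar quadrant decomposition → slope-matched diameter search →
physical calibration.

## Segmentation

RGB→HSV uses the piecewise max/min hue formula with hue in degrees,
stored as h ∈ [0,180] (half-degrees, rounded), s,v ∈ [0,255]. That storage
convention is the only one under which the default red thresholds
([0,43,46]–[10,255,255] and [156,43,46]–[180,255,255], inclusive on both
ends) are meaningful, and it keeps the continuous formula and the integer
thresholds simultaneously true. Red needs two bands because hue wraps at
the origin.

Cleanup is a morphological opening — one erosion then one dilation with a
3×3 rectangular structuring element — followed by a 3×3 Gaussian filter
and re-binarisation. Open choices resolved here:

* the Gaussian is applied to the *mask*, not the colour image, and the
  smoothed mask is re-thresholded at 0.5 (ties count as foreground);
* the 3×3 Gaussian kernel is the binomial [1,2,1]/4 ⊗ [1,2,1]/4, the
  conventional fixed kernel for that size;
* an empty mask after cleanup raises `NoLumenFound` rather than returning
  an empty measurement.

## Morphometry

The contour keeps **every** boundary pixel (no chain approximation): a
foreground pixel of the selected 8-connected component with at least one
4-neighbour outside it. Components below 9 px are rejected; among several
components the largest area wins. The centroid is computed from the
filled region (all foreground pixels), not the contour polyline, because
the moment sums integrate over the image.

Quadrant classification happens on the translated signs with the image
y-axis pointing down; a translated coordinate with magnitude < 0.5 px is
treated as exactly zero and routes the point to an axis class (±x, ±y).
Points essentially coincident with the centroid are excluded and counted
in a warning.

Diameter candidates:

* axis pairs: any +x point with any −x point (resp. ±y), length ρ₁+ρ₂;
* slope pairs: Q1×Q3 and Q2×Q4 pairs whose tangents agree within
  `slope_abs_tol` = 0.0256 (absolute, plus a 10⁻⁹ relative term, matching
  the conventional `isclose` semantics). For near-vertical chords
  (|tangent| > 40) the tangent comparison is numerically meaningless, so
  those pairs are additionally accepted when their polar angles agree
  within atan(0.0256) — the equivalent tolerance mapped to angle.

`find_min_diameter` returns the raw minimum ρ₁+ρ₂. The end-to-end
`measure()` adds a **+1 px pixel-extent correction** (0.5 px per end):
boundary pixel centres sit half a pixel inside the true lumen edge, so
the raw polar sum systematically underestimates the physical diameter by
about one pixel. With the correction, measurement error on crisp phantoms
is centred near zero and bounded by the rasterisation scale.

Calibration is linear: mm = px × (scale-bar mm / scale-bar px); the
default 10 mm / 379 px bar gives 0.026 mm/px (3 dp).

Concave lumina whose centroid falls outside the region are not rejected:
the search still returns the minimum centroid-passing chord, and the
coincident-point warning count flags the geometry for review.

## Diagnostic criteria

All inequalities are strict; boundary values classify as "no CoA". The
transverse arch is min(D1, D2) — the isthmus has its own role in the CHD
rule and is excluded from the arch minimum. The CHD-database conditions
combine by OR: meeting any one suffices. Karl's weight brackets are

| weight w (kg) | threshold (mm) |
|---|---|
| 0 < w < 6 | w + 1 |
| 6 ≤ w < 20 | w |
| 20 ≤ w < 30 | w / 2 |
| 30 ≤ w < 40 | w / 2.5 |
| w ≥ 40 | w / 3 |

**Caveat:** the published bracket list does not state a rule for
10–20 kg; this package fills the gap by extending threshold = w from the
6–10 kg bracket (the continuous choice). The brackets are nondecreasing
within each range but discontinuous at 20 kg; that is a property of the
published rule, not of this implementation.

## Evaluation

For a single binary decision the ROC has one interior operating point, so
AUC = (sensitivity + specificity)/2 — the two-point trapezoidal area.
Cohen's kappa uses marginal-product chance agreement; agreement grades are
good (κ ≥ 0.75), fair (0.4 ≤ κ < 0.75), poor (κ < 0.4). Degenerate
denominators raise `UndefinedMetricError` instead of silently reporting 0.

The Wilcoxon signed-rank test drops zero differences and averages tied
ranks. For n ≤ 25 the two-sided p-value comes from the exact null
distribution of W⁺, built by dynamic-programming convolution on doubled
ranks (valid under averaged ties, where W⁺ lives on a half-integer
lattice); beyond that, a normal approximation with tie correction and a
0.5 continuity correction. The exact path is verified against full 2ⁿ
sign enumeration in the test suite.

Reported metrics are rounded with decimal round-half-even at two
decimals, the package's reporting convention.

## Synthetic data

`phantoms` generates the study inputs:

* **Cross-section phantoms** — discs, rotated ellipses, and lobed blobs
  (cosine-perturbed radius), red fill on a configurable background,
  rendered crisply by default. The returned ground truth is the minimum
  centre-passing width of the *continuous* shape: 2·min(a,b) for
  discs/ellipses, a dense angular scan of r(θ)+r(θ+π) for blobs.
  Optional per-pixel intensity noise (`noise_sd`) and Gaussian edge
  softening (`edge_sigma`) stress the segmenter; the test battery uses
  noise_sd = 8 and edge_sigma = 0.5 px — mild render noise and roughly
  one pixel of anti-aliasing, the realistic level for crisp 3D-render
  slices.
* **Scale bars** of exact pixel length with the physical length in a
  metadata sidecar.
* **Measurement cohorts** — 53 CoA + 40 control subjects by default.
  Per site and group, the manual diameter is log-normal with parameters
  matched to published median/IQR values (log-normal keeps diameters
  positive and maps the median to exp(μ)); the intelligent value is the
  manual value minus a Gaussian paired difference matched to the
  published difference median/IQR. Weights are uniform on [2, 12] kg
  (infants under one year). Diameters are floored at 0.05 mm after the
  paired difference.

What the generator does **not** emulate: the joint correlation structure
of real anatomy. Sites are sampled independently of each other and of
weight, so a subject's AOA carries no information about their D3, and
Karl's weight threshold faces weights uncorrelated with arch size.
Consequently the diagnostic scores on synthetic cohorts are substantially
weaker than scores on real patients and are *not* comparable to published
patient-cohort values; passing tests demonstrate internal consistency,
calibrated marginals and classifier correctness, not clinical accuracy.
Phantoms likewise demonstrate geometric accuracy of the measurement
chain, not segmentation of real CT renderings.

## Numerical choices and limitations

* Problem sizes: the property battery measures 204 phantoms on 181×181
  canvases (semi-axes 15–70 px) against a brute-force centroid-chord
  oracle; the acceptance script uses 100 phantoms. Both sizes give the
  oracle O(n²) pair enumeration headroom while exercising every shape
  class.
* Colour-threshold segmentation reads any sufficiently red pixel as
  lumen: with soft edges, pixels down to alpha ≈ 0.18 (value ≥ 46) are
  included, so strong anti-aliasing (σ ≳ 0.7 px) biases diameters
  outward by ~1–2 px. This is inherent to fixed HSV thresholds, worth
  remembering when images are resampled or blurred.
* The slope tolerance 0.0256 trades candidate count against pairing
  slack; the brute-force-oracle bound (within +3 px) in the tests is the
  empirical guarantee that the slack stays bounded.
* Determinism: every stochastic generator takes an explicit integer seed;
  identical seed + spec reproduce outputs bit-exactly.
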
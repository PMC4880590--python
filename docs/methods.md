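# Methods

This note documents the models, numerical choices and known limitations of
`leafspad`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The measurement problem

A SPAD chlorophyll meter clips onto a ~2 mm spot of a leaf. On rice,
chlorophyll varies systematically along the blade (low at base and tip,
peaking at 50–60 % of the length), so single readings are position-biased
and replicate readings are position-variance-limited. The package asks two
questions of a blade: *what single value best represents the whole leaf?*
(the area-weighted C value) and *where on the blade does a single reading
reproduce that value most reliably?* (the representative-position /
variance analysis).

## Models and procedures

### DN → SPAD calibration (`calibration`)

Ordinary least squares of SPAD on the red-band digital number, via
`scipy.stats.linregress`. The shipped constant
(slope −0.2509 SPAD/DN, intercept 52.735 SPAD, r² 0.851, n 39) is the
red-band relation; red is the default band because its DN range
(~62–150) sits comfortably inside the 8-bit scale, whereas green runs high
and blue carries little signal. No weighting and no through-origin option:
the relation is an empirical straight line, not a physical law. The
published constant stores p as NaN (its source reports only significance
at p < 0.01); user-fitted models carry the exact F-test p.

### Chlorophyll profile (`profile_model`)

Quadratic OLS of SPAD on position, solved through the SVD-based
Vandermonde least squares of `numpy.polynomial` (exact minimizer; exact
interpolation at three distinct points). Coefficients are stored both
against absolute position (cm) and against proportional position
L/length, since pooled multi-leaf analyses use the proportional axis.
The concavity is not enforced in fitting — a fitted a₂ ≥ 0 simply means
the data do not show the canonical profile.

### Area-weighted representative value (`representative`)

Part areas integrate the digitized width profile with a composite
trapezoid rule, 100 panels per part (`n_sub`), interpolating the width
linearly between samples. Because the width representation is itself
piecewise linear, the trapezoid rule is exact whenever panel edges align
with the sample knots, and the sum of part areas equals the whole-blade
integral by construction. C is then the area-weighted mean of the per-part
SPAD values — a convex combination, so min ≤ C ≤ max always, and C equals
the arithmetic mean exactly when all part areas are equal.

Representative positions solve a₂L² + a₁L + (a₀ − target) = 0 in closed
form. A discriminant below −10⁻¹² yields an explicit empty result (the
target is unattainable); |disc| ≤ 10⁻¹² yields the double root. Roots
outside [0, length] are returned but logged, never clamped: clamping
would fabricate a measurement position.

### Scan processing (`scan`)

* **Normalization**: per channel, linear map sending the black-standard
  mean to 0 and the white-standard mean to 255, then clip and round.
  Idempotent up to 1 DN.
* **Segmentation**: excess-green index 2G − R − B > 30 (configurable) on
  the normalized raster, then the largest connected component; both
  standard regions are excluded unconditionally. The criterion exploits
  that green tissue scores ≳ 200 under the renderer's band model while
  white background and grey standards score ≈ 0.
* **Axis and digitization**: the blade axis is the principal (largest
  eigenvalue) direction of the mask pixels. Width at a station is the
  transect extent perpendicular to that axis, in cm at 2.54/dpi per
  pixel. The base end is auto-identified as the end whose adjacent 10 %
  of the axis is wider (rice blades are wider near the base than the
  tip); an explicit `base=` override exists because the heuristic is
  wrong for pathological shapes (e.g. a wedge widening toward the tip).
* **Slicing**: k parts of equal axial *length* (not equal area), matching
  how a slice tool cuts a scan at equal intervals.
* **DN extraction**: per part, mean DN per channel after (a) eroding the
  mask by 2 px to drop margin pixels and (b) dropping the central 20 % of
  each transect (the midrib strip). This mimics an operator avoiding
  veins and margins. Part areas use the *full* pixel count — exclusion is
  a sampling choice, not a geometry change. Whether the original
  Photoshop-based workflow excluded the midrib is unknown; both knobs are
  exposed in `ExclusionConfig`.

### Variance diagnostics and selection (`diagnostics`)

Sample SDs use the n−1 denominator throughout. For di-positional
combinations (ab, ac, bc, abc) each replicate leaf contributes the mean
of its member-position readings and the SD is taken across replicates —
the natural reading of "combination of positions", though averaging
before vs after taking the SD is an interpretation. The selection rule:
a candidate fraction p lies in part ⌈p·k⌉; the candidate whose part has
the lowest SD wins, ties breaking toward 2/3. Confidence bands on the
regression fits are the standard pointwise OLS interval for the mean at
level 0.95, computed from the coefficient covariance
(cross-checked in tests against `statsmodels.get_prediction` and the
textbook closed form).

The chlorophyll extraction formula
Chla+b = (5.1·A665 + 20.04·A649)·V/m (mg/g, V in liters, m in grams) is
the two-wavelength relation for 96 % ethanol extracts.

## The synthetic-leaf generator

### What it emulates

* **Silhouette**: a linearly tapering pedestal (base width 2 % of the
  maximum) plus the beta-like bump
  `(x/p)·((Lt−x)/(Lt−p))^β`, with β solved so the bump peaks at p. This
  family is smooth, single-peaked, zero at the tip, positive at the base,
  and has a closed-form area (beta function) used as an independent
  integration oracle. The exponent is fixed at 1 on the rising side
  because that guarantees a single interior maximum for every parameter
  choice; the pedestal shifts the true peak ~0.06 cm proximal of p,
  below half the default sampling interval.
* **Profile**: concave quadratic built from vertex form (peak position,
  peak value, base value).
* **Scanner**: inside the silhouette the *true* red DN at axial position
  L is (SPAD(L) − intercept)/slope, green = 0.55·red + 110 (reproducing
  the observed band ordering green > red > blue), blue = 20. The scanner
  response is a global affine `observed = gain·true + offset`
  (defaults 0.92 and 8) applied to leaf, background and standards alike,
  plus additive Gaussian sensor noise (default SD 1 DN), rounded to
  8 bits. Since the standards are rendered at true DN 0/255,
  normalization inverts the affine response exactly up to rounding.
* **Populations**: per-part SPAD noise with a U-shaped SD along the
  blade, σ(m) = 0.3 + 10·(m − 0.7)² SPAD at part midpoint fraction m —
  minimum spanning parts 7–8 of 10, matching the observed low-variance
  60–80 % band. Default 30 leaves per population, a realistic field
  sampling effort (ten plants, a few leaves each); this size keeps the
  sampling error of the per-part SD estimates small enough that the
  empirical SD minimum is expected to fall in parts 7–8 in ≳ 98 % of
  draws (SD-of-SD ≈ σ/√(2(n−1))). SPAD-meter reading noise defaults to
  0.3 SPAD, typical meter repeatability.

### What it does not emulate

Scanner optics (glare, shadows, vignetting, chromatic effects), real
vein/midrib reflectance structure, leaf curling or overlap, adaxial vs
abaxial differences, and any nitrogen-physiology coupling beyond the
profile's shape. Passing round-trip tests therefore demonstrates the
*pipeline's* correctness (geometry, normalization, calibration algebra),
not robustness to real scanner artifacts.

## Numerical choices and degenerate inputs

* Discriminant tolerance 10⁻¹² for double roots; root round-trip is
  verified to 10⁻⁶.
* Rasterization cannot represent sub-pixel widths: at 300 dpi the last
  ~0.1 cm of the taper (width < 1 px ≈ 0.0085 cm) drops out of the
  silhouette, so recovered length is compared against the rendered
  mask's extent, and the 0.5-SPAD round-trip tolerance absorbs
  DN quantization (one DN step ≈ 0.25 SPAD through the calibration).
* Problem sizes: round-trip tests render one 25 cm blade at 300 dpi
  (~3000 × 240 px); the Monte-Carlo study runs 200 populations of
  30 leaves × 10 parts.
* Degenerate inputs raise typed errors (`errors.py`): equal black/white
  standards, empty segmentation, masks with < 3 transects, constant-DN
  calibration designs, all-zero profiles, empty candidate sets.
* `LeafShape` enforces taper-to-zero at the tip; `strict=False` waives
  only that check for analytic reference shapes (exact rectangles and
  wedges) used in closed-form integration tests.

## Open design points, decided

* The worked-example blade length is set to 25.2 cm, which places the
  reference profile's vertex at ~50 % of the blade, consistent with the
  observed 50–60 % peak band; only root *values*, not the length, enter
  the headline numbers.
* The area-weighted C of the original study's blade (39.11, with
  positions 8.96/16.00 cm) depends on that blade's digitized silhouette,
  which is not available, and is mutually inconsistent with the printed
  profile (C = 39.11 solves to ≈ 6.35/18.62 cm on it). It is therefore
  documented but not used as a numeric target; the conventional pair
  (38.42 → 5.21/19.76 cm) is internally consistent and is asserted.
* Fits are performed on whatever point set is supplied; pooling across
  leaves (absolute vs proportional axis) is the caller's choice.

## Known limitations

Real rice blades are proportionally wider at the base than the synthetic
family's 2 % pedestal; the family is a geometric stand-in chosen for its
oracle-friendly closed form, not a claim about rice morphology. The
segmentation criterion assumes a white scanner background; the base-end
heuristic assumes base-heavier silhouettes; and the shipped calibration
is scanner-specific — refit it for any scanner other than the one it came
from.
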
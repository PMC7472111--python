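# Methods

This note documents the models and numerical choices behind hyperleaf:
what each stage assumes, which parameters matter, what the synthetic
data does and does not emulate, and where the design was genuinely open.

## Signal model and pre-processing

A leaf reflectance signature is treated as a smooth continuum carved by
absorption features, observed through a sensor with one Gaussian
spectral response per band and corrupted by three artefacts: detector
splice offsets, multiplicative illumination/geometry jitter, and
additive sensor noise.

**Calibration.** Camera intensities are converted to reflectance per
pixel and band as `r = (i_plant − i_dark) / (i_white − i_dark)`.  The
division is guarded at 1e-9 intensity units: pixels whose white/dark
difference falls below the guard in any band are set to 0 and returned
in an invalid-pixel mask rather than propagating infinities.

**Splice-jump removal.** Full-range spectrometers stitch several
physical detectors; each junction shows a step offset.  For each
junction, processed left to right, a straight line is fitted by least
squares through the trailing `m = 6` points of the left segment and
evaluated at the first wavelength of the right segment; the entire
right segment is shifted so its first value lands on that line.  The
shift is additive, which preserves all within-segment first differences
exactly and makes the correction idempotent.  Whether the original
instruments were aligned additively or multiplicatively is not
observable from the data model here; a multiplicative mode is provided
behind the same interface.  Fitting fewer than two points is refused,
and a segment shorter than `m` raises an error naming the segment.

**Smoothing and trimming.** Savitzky–Golay smoothing with window 11 and
polynomial order 2 by default — wide enough to suppress band-to-band
noise on a 1 nm grid, short enough to leave 14–26 nm absorption features
essentially untouched (a degree-2 polynomial is reproduced exactly).
Signatures are then trimmed to 400–2400 nm, where the detectors are
reliable; VNIR-only camera data is trimmed to 400–1000 nm.  Smoothing is
applied after jump removal so the filter never straddles an uncorrected
step.

## Leaf extraction

Pixels are compared with a blue marker target signature by spectral
angle, `arccos(a·b / |a||b|)`, which is invariant to illumination
scale; angles below 0.2 rad classify a pixel as marker.  The threshold
is interpreted in radians — the only convention under which 0.2 is a
plausible arccos output for "similar" spectra.  The leaf-bed region of
interest is placed at configured pixel offsets along the principal axis
of the marker pixel coordinates (eigenvector of their spatial
covariance); the offsets are rig calibration and default to the
synthetic layout.

Inside the ROI, pixels are transformed to hyper-hue — the unit-norm
direction left after subtracting the achromatic (equal-value)
component: `h = (v − mean(v)·1)/‖v − mean(v)·1‖`.  This keeps the
brightness-independent spectral direction, which is the part of the
cited hue construction that carries class information; the saturation
and intensity channels are deliberately omitted.  Constant (achromatic)
pixels have no hue and map to background.

A one-class SVM (RBF kernel, ν = 0.1, bandwidth from the median
heuristic on the training pixels' pairwise squared distances) learns the
leaf hue distribution from annotated leaf pixels; in this package's use
about 200 training pixels are supplied, below which the boundary
generalises poorly.  Because a ν-SVM rejects roughly a ν fraction of
genuine inliers as scattered speckle, the raw mask is tidied by a 3×3
morphological closing and hole fill (disable with `clean_mask=False`);
the classifier output itself is what the ν-property tests check.

Per-leaf signatures are the arithmetic per-band mean over the mask; an
empty mask raises so the caller can flag the sample as an acquisition
error.  VNIR and SWIR signatures of one leaf are merged by
concatenation — SWIR bands at or below the last VNIR wavelength are
dropped, so the VNIR value wins in the overlap — followed by the same
splice-jump removal across the junction.

## Band resampling

The weight of source band *s* in destination band *d* is the
destination's Gaussian response (σ_d = FWHM_d / 2√(2 ln 2)) evaluated at
the source centre, zeroed when |λ_d − λ_s| exceeds (FWHM_d + FWHM_s)/2
— i.e. when the FWHM intervals do not overlap — and rows are normalised
to sum to one after the cut.  Sampling the response at source centres
(instead of integrating response products) is the standard
approximation for dense sources; with a 1 nm source grid and 10–100 nm
destinations the difference is far below the noise floor.  Row
normalisation after truncation makes every output a convex combination
of source values: constants are conserved and outputs never leave the
source range.  Note the truncation at the FWHM rather than at ±3σ is a
hard kernel cut; staged coarsening (10 nm then 100 nm) therefore agrees
with direct coarsening only to ~0.5% on spectra smooth at the 100 nm
scale, and a few percent across sharp features such as the red edge.

Even grids tile [lo, hi] with centres at lo + FWHM/2, lo + 3·FWHM/2, …;
the phase is anchored at the lower edge (the construction fixes band
count and end centres, e.g. 20 bands at 450…2350 nm for 400–2400 nm at
100 nm FWHM).  Key-wavelength layouts come in narrow-band form (native
sensor FWHM: 1, 5.5 or 12 nm depending on the instrument) and
broad-band form, where each band's half-width reaches halfway to its
nearest neighbouring key, i.e. FWHM = min(left gap, right gap), end
keys using their single neighbour; a mean-of-half-gaps alternative is
switchable.

## Regression and model selection

The regression is PLS1 computed by NIPALS with deflation.  Predictors
are mean-centred per training partition; no unit-variance scaling is
applied, since reflectance bands share units and scaling would inflate
noisy bands.  One NIPALS pass yields the coefficient vectors of *all*
component counts 1..K (PᵀW is upper triangular, so each leading block
reuses the same decomposition), which makes the latent-variable search
cheap.  The implementation reproduces scikit-learn's PLSRegression
coefficients to machine precision; the library is used in the test
suite as an independent oracle, not in the pipeline.

Validation is nested: samples are shuffled into 5 outer folds by a
seeded permutation (an option keeps all measurements of one plant in a
fold); inside each outer training partition a 5-fold inner
cross-validation picks the component count in 1–20 minimising pooled
validation RMSE — selecting on the outer fold would leak.  Counts are
capped at min(n_train − 1, n_bands) with a warning.  The headline
statistic is the mean of the five outer-fold validation R² values;
RMSE, bias, mean and median absolute error are reported alongside.  R²
uses the mean of the evaluated reference values as baseline, so a
constant mean predictor scores exactly 0 and out-of-distribution
application can score negative.

**Key-wavelengths.** The five folds' coefficient vectors are averaged
pointwise; strict interior local extrema of the averaged curve are
ranked by absolute coefficient.  A run of equal values counts as one
extremum at its centre band; runs touching the grid ends are not
extrema.  Requesting more keys than exist returns all with a warning.

**Cross-sensor application.** A model refit on all cleaned samples (its
component count selected by the same inner-CV rule) is applied to
spectra resampled onto its band grid.  Coarse-band data resampled up to
a fine model grid attenuates narrow absorption features, so predictions
keep a strong linear relationship with the reference but show slope
shrinkage and bias — the package reports slope, bias and R² so this
regime is visible rather than hidden.

## Vegetation indices

NREAI = (SD_r − SD_b)/(SD_r + SD_b), where SD_b and SD_r integrate the
first-derivative spectrum over 490–530 nm and 670–737 nm.  The
derivative is by central differences on the native grid and the
integral by the trapezoid rule; on an exactly linear spectrum this gives
(67 − 40)/(67 + 40) = 27/107 to rounding.  A zero denominator returns
NaN (undefined marker).  NDVI(λi, λj) = (r_i − r_j)/(r_i + r_j) is
searched over all wavelength pairs in a range at the native 1 nm FWHM;
each pair is scored by univariate least squares against N% using the
same cross-validation folds as the PLSR models (cross-validated rather
than in-sample R², the stricter reading).  The R² matrix is symmetric
under pair swap, with NaN on the constant diagonal.  The exhaustive 1 nm
search over 400–2400 nm is ~2 million pairs; the search function exposes
a `step` parameter and the default experiment config searches a 10 nm
lattice, which is dense relative to the ≥ 20 nm width of any structure
the generator plants.

## Synthetic data: what it emulates, what it does not

The generator produces the statistical structure the analysis assumes,
not leaf biophysics (no radiative-transfer modelling).  Per sample:
N% is drawn from a treatment-shifted normal (means 2.0/3.0/4.0/5.5% for
soil treatments of 25/50/100/200 mg N per kg, sd 0.6, clipped to the
1–7% window — chosen to span the study's outlier gate); reflectance is a
fixed PCHIP continuum through green-leaf control points minus Gaussian
absorption dips whose depths are linear in N% (defaults centred on
protein/chlorophyll-associated bands at 676, 1517, 2106, 2180, 2313 nm
with 14–26 nm FWHM and 0.9–1.3% reflectance depth per N% unit), minus
water-band confounders at 1450/1940 nm with N-independent random
depths; then a per-sample multiplicative jitter (sd 5%), additive
Gaussian noise (sd 0.005 reflectance), Gaussian-response resampling onto
the sensor grid, and splice offsets (sd 0.02) at the detector junctions
(1000 and 1800 nm for the spectrometer, 1000 nm for the merged camera
pair).  All randomness flows from one mandatory seed through named
substreams, so each artefact is reproducible in isolation.

Image cubes place a flat dark background, a blue marker block and an
elliptical leaf whose pixels share one cohort-model spectrum with 3%
per-pixel amplitude variation; raw intensities are produced by
inverting the calibration against generated dark/white frames, so
calibration recovers the planted reflectance exactly when noise is off.

Consequently, passing tests demonstrate that the machinery recovers
known structure under the stated noise model — they do not certify
accuracy on real leaves, where geometry, shadows, water status and
instrument drift produce artefacts the generator does not model
(consistent with the large cross-sensor degradation the pipeline itself
exhibits between sensor types).

## Problem sizes and determinism

Default study conditions are 300-sample cohorts at noise 0.005; the
cleaning fixture uses 600 records with 42 under-weight, 8 outlier and 7
acquisition-error rows (543 survivors).  The example experiment configs
in the tests and the acceptance script run reduced grids (a couple of
FWHMs and key counts, 10–25 nm NDVI search steps, 48×64×110 cubes);
every number they print is recomputed from the seed at run time, and
re-running any configuration with the same seed reproduces the report
byte for byte.

## Known limitations

* The FWHM-overlap truncation makes resampling weights discontinuous in
  the band spacing; bands needing sub-FWHM tail contributions (e.g.
  1 nm destinations more than half a source FWHM from every coarse
  source centre) raise a no-coverage error instead of extrapolating.
* Key-wavelength extrema on noisy coefficient curves can place several
  ranked entries inside one broad feature; ranks are reported rather
  than de-duplicated by feature.
* The one-class SVM consumes hue vectors at full band dimension; very
  small training sets (tens of pixels) under-cover the hue cluster and
  the ν-rejection then exceeds its nominal rate.
* `SampleRecord` accepts a missing N% for under-weight rows before
  cleaning has flagged them, so freshly read ledgers are representable;
  any other missing N% must carry an exclusion flag.
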
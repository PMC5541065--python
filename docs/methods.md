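# Methods

This note records the models, numerical choices and limitations behind
`benthoscan`, in the order data flows through a transect analysis.

## Geometry and data model

A push-broom transect cube is ordered `[line, sample, band]`: lines are
successive frames along the swim track, samples span the across-track
line-of-view, bands are contiguous wavelengths (default grid 400–900 nm in
480 bands, ~1.05 nm spacing). On-disk storage is ENVI header/binary pairs
(interleaves bil/bsq/bip; uint16/float32/float64; written bil + float32 by
default, the natural frame-major layout for a line scanner). Nearest-band
lookup resolves ties toward the lower wavelength; display rendering uses a
(2, 98) percentile stretch per channel and never modifies the raw planes.

Survey arithmetic is exact algebra on the plan parameters: lateral pixel =
swath / spatial pixels, transverse pixel = frame spacing, coverage = speed ×
swath, data rate = frame rate × frame bytes, and volume ≡ rate × duration.
`bytes_per_sample` defaults to 2 (16-bit ADC, typical for this imager
class); GB means 10⁹ bytes.

## Reflectance correction

A spectrally flat gray board in the scene shares the illumination and
water-column path of its neighborhood, so

    R(l, s, λ) = ρ_board · I(l, s, λ) / Ī_board(λ)

cancels the common light field in one division. The correction is linear
and scale-invariant per band, which is exactly the operative assumption —
that the average light field does not change materially over the 1–2 minute
transect. Its known failure mode is retained deliberately: when imaging
altitude varies along the track, the per-line attenuation differs from the
board lines' attenuation and corrected spectra tilt accordingly (the
simulator reproduces this). The board's true albedo is rarely known, so
`board_albedo` defaults to 1 and the output is reflectance *relative to the
board*. Out-of-gamut values (reflectance < 0 or > 1 from noise or shadow)
are flagged in a QC mask, never clipped — clipping would bias the spectral
derivatives computed next. Multiple "Reference" polygons (sparse patches or
boards at both transect ends) are pooled into one pixel mask before
averaging; the ≥ 25 pixel minimum applies to the union. True-color
rendering applies one shared percentile stretch to the three reflectance
planes: independent per-channel stretches would re-tint the image the
correction just removed; with the shared stretch the board renders neutral
by construction.

## Spectral derivatives and index maps

Derivatives are local-polynomial (Savitzky–Golay) fits — the standard way
to stabilize band-to-band noise while preserving narrow features — with a
7-band window (~7 nm) and physical units (per nm, per nm²); edge bands use
one-sided fits. Polynomial degree defaults to 2 for first derivatives and 4
for second derivatives: a cubic's second derivative at the window center
equals a quadratic's and carries an O(h²) bias proportional to the fourth
derivative of the spectrum, about −2.7% at the center of a σ = 10 nm
Gaussian dip on this grid; the quartic cancels that term (measured residual
0.2%). Grids uneven beyond 1% are linearly resampled to the median spacing
before differentiation.

Sign convention: an absorption dip is convex at its minimum, so a positive
second derivative at the feature wavelength indicates presence. The
registry ships `chl_670` (2nd, 670 nm), `coral_rededge_700` (1st, 700 nm,
negatives rectified to 0 — the index is defined on positive slopes),
`chromo_580` and `phyco_605` (both 2nd). The 580 nm feature is named by
wavelength, not pigment, since the underlying chromoprotein identity is not
settled. Index maps are computed on reflectance; values are uncalibrated
(relative) pigment proxies, not concentrations.

## Topography and rugosity

Bottom depth under the track is diver depth (pressure, positive down) plus
altimeter altitude. Along-track distance is assigned by a constant-speed
assumption over the stated transect length — the dominant approximation, as
the instrument has no positioning; a hook accepts an external distance
series when one exists. Gaps ≤ 5 s are linearly interpolated; longer gaps
split the profile into segments and whole-profile rugosity is reported per
segment. The arc-chord index is Σ√(Δx² + Δz²) / (x_N − x_0) ≥ 1, invariant
to depth offset and reflection; windowed mode uses non-overlapping windows
and drops the last partial window.

## Classification

Features: "hsi" mode restricts to 400–750 nm (the infrared bands carry no
usable signal underwater) and Z-norms each *pixel spectrum* across bands —
zero mean, unit SD per pixel — which removes per-pixel brightness and gain
differences (altitude, shadow, electronic gain) while keeping spectral
shape; with the default 480-band grid this yields 336 features. A per-band
(across-pixels) normalization is available for comparison but is not the
default, because underwater brightness varies pixel-to-pixel far more than
band statistics do. "rgb" mode uses the three raw intensities at the bands
nearest 640/540/460 nm, un-normalized, mirroring what a color camera sees.
Pixels with zero spectral SD (Z-norm undefined) are excluded from training
with a warning and, at map time, assigned by nearest class mean with a QC
count.

Splits are stratified per class at 75/25 (round-half-up per class, each
class keeping at least one validation row), seeded and reproducible.

Three classifiers:

- **perceptron** — one hidden layer (64 units), ≤ 500 epochs, stopping on a
  training-loss plateau (tol 1e-5, patience 25). A held-out-score stopping
  rule was rejected: with a few dozen annotated rows per class the held-out
  score plateaus long before the fit converges.
- **mahalanobis** — implemented from its definition: argmin over classes of
  (x − μ_k)ᵀ Σ⁻¹ (x − μ_k), ties to the lexicographically first class.
  Σ defaults to the within-class covariance pooled over all classes,
  regularized by ε·I with ε = 1e-6 · trace(Σ)/F. Pooling is the standard
  form of this classifier in hyperspectral work, and the only well-posed
  choice in the sparse-annotation regime, where per-class training sets
  (tens of rows) are smaller than the band count (hundreds): an independent
  per-class Σ_k is then rank-deficient, the tiny shrinkage amplifies
  null-space noise, and accuracy collapses (measured: 0.75 versus 1.00
  pooled on the reference scene). The per-class (quadratic-discriminant)
  form remains available via `covariance="per_class"` for datasets with
  n_k ≫ F.
- **svm_linear** — linear-kernel SVM, one-vs-rest, C = 1.

Metrics come from the confusion matrix (rows true, columns predicted):
accuracy = trace/total, precision_k = M\[k,k\]/column sum (producer
accuracy), recall_k = M\[k,k\]/row sum (user accuracy). Classes absent from
validation keep their row with NaN-marked metrics rather than being dropped.

## The scene simulator

The simulator exists so that every stage above has a ground-truth oracle.
Per pixel of class c at line altitude h:

    I(λ) = E(λ) · exp(−2·Kd(λ)·h) · R_c(λ) · (1 + ε),   ε ~ N(0, 1/SNR)

- `E(λ)`: smooth daylight-like downwelling spectrum.
- `Kd(λ)`: clear-water-like diffuse attenuation, 0.03 m⁻¹ at 400 nm rising
  through 0.5 m⁻¹ at 700 nm to 2.5 m⁻¹ at 900 nm (fixture constants, not
  site claims).
- The factor 2 approximates the down-and-back path of bottom-reflected
  light with the board on the bottom — a deliberate simplification.
- `R_c(λ)`: baseline − Σ Gaussian dips (center, width, depth) + linear red
  edge beyond 690 nm, clipped at 0.001 — the minimal endmember family that
  exercises the four derivative indices.
- Noise is multiplicative Gaussian (shot-noise-like proportionality),
  seeded; layouts are non-overlapping ellipses placed by seeded rejection
  sampling, plus a background class and a top-left board rectangle.
- The matching 1-Hz sensor track is generated from the prescribed seafloor
  function and altitude profile (depth = bottom − altitude), with small
  seeded noise on the PAR/O₂/pH channels.

The **reef11** reference scene is 200 × 640 × 480 at SNR 50, eleven classes
(ten benthic classes with distinct feature sets plus the board), imaging
altitude 1.0 ± 0.2 m swinging along the track, 12.5 m transect in 35 s
(~21 m/min, matching a realistic swim). Sparse annotation places seeded
rectangles strictly inside class regions, quota proportional to class
abundance with a 40-pixel floor, totaling ≈ 1.8–1.9% of the scene.

The altitude experiment re-scans the same layout from 2× altitude with a
1.5× wider swath (layout shrunk laterally, background-padded, doubled water
path). Doubling the path re-weights `exp(−2·Kd·h)` non-uniformly across
400–750 nm, so Z-normed spectra genuinely change shape — which is why a
model trained at normal altitude degrades on the elevated scene and why
retraining on the pooled annotations recovers it. This reproduces the
structure of the field observation, not its exact numbers.

What the simulator does *not* model: surface glint, inter-pixel scattering
or motion blur, bidirectional reflectance, spectral mixing at class
boundaries, and noise whose SNR falls with attenuation. Passing tests on
synthetic scenes therefore demonstrate correctness of the pipeline under
its own assumptions and the qualitative physics of the altitude/water
effects — not field performance.

## Problem sizes and determinism

The test suite and the acceptance script run the full reef11 experiment
(128k pixels × 480 bands, six classifier fits, plus the altitude twin) in
tens of seconds on one CPU; unit tests use 40 × 100-pixel scenes. Every
stochastic step — scene noise, layout, annotation placement, splits,
classifier initialization — flows from explicit integer seeds, and
identical seeds give bit-identical cubes and byte-identical metrics files.

## Known limitations

- Constant-speed distance mapping distorts rugosity where swim speed varied.
- A single transect-wide board correction leaves altitude-dependent tilt in
  the corrected spectra (visible in the reef11 scene's QC mask).
- Index maps are relative; absolute pigment quantification would require
  bio-optical calibration against extracted samples.
- Classification is purely per-pixel spectral; no spatial context is used.
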
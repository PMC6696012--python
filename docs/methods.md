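# Methods

This note documents the models, conventions, parameter choices and known
limitations of `ms3d`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Image registration (`ms3d.imreg`)

A transform `(dx, dy, θ0, σ)` describes the content mapping from the
reference image A (depth camera) to the moving image B (reflectance
imager): a feature at position p in A appears in B at
`σ·R(θ0)·(p − c) + c + (dx, dy)`, with c the image center and x = column,
y = row, origin top-left.  Parameterizing about the center makes the
inverse center-independent, so transforms can be composed and inverted
without carrying a grid around.

Estimation is the classical two-stage Fourier scheme:

1. **Rotation/scale** from the log-polar resampling of the centered,
   high-pass-filtered Fourier magnitude of each (Hann-windowed) image.  The
   magnitude spectrum of a real image is point-symmetric, so the θ axis
   covers [0°, 180°); the resulting 180° ambiguity is resolved by de-rotating
   with both candidates and keeping the one whose subsequent translation
   correlation peaks higher.  Defaults: 256 log-radius bins from 1 px to the
   Nyquist radius, 360 angle bins (0.5°/bin) with parabolic subpixel
   refinement.  An estimated σ outside [1/4, 4] raises a range error — at
   such zoom ratios the overlap is too small to trust the measurement.
2. **Translation** by phase correlation of the reference against the
   de-rotated/de-scaled moving image (both Hann-windowed); the measured
   shift s maps back to the content translation via `d = σ·R(θ0)·s`.

Two numerical choices matter in practice:

* The normalized cross-power spectrum weights every frequency bin equally,
  including bins that carry only interpolation noise on band-limited
  images.  A Gaussian low-pass (`LOWPASS_SIGMA = 0.1` cycles/px) is applied
  to the cross-power before the inverse FFT; the surface is renormalized so
  an exact circular shift still yields peak 1 at exactly the true integer
  shift (the low-pass is real and symmetric, so peak positions of exact
  shifts are untouched).
* `phase_correlation` itself applies no window: windowing is the caller's
  job (the similarity pipeline windows internally), which keeps integer
  circular shifts recoverable exactly — bit-for-bit integer results.

Subpixel refinement is a separable 3×3 parabolic fit around the integer
peak, clamped to ±0.5 bin; offsets below 1e-9 snap to zero so exact-shift
results stay integer.  Warping uses bilinear interpolation with a
configurable fill value; out-of-coverage pixels become NaN when the fill is
NaN.  Grayscale reduction for registration: mean of RGB for the depth-camera
image, a configured single band (default NIR) for the reflectance cube.

## Reflectance mapping (`ms3d.spectral_map`)

All bands of a cube are warped with the *same* calibrated transform (the
rig is rigid; the transform is estimated once per rig, typically from a
calibration-board pair).  NaN handling: the source is warped twice, once
value-filled and once as a coverage mask, and any output pixel whose
bilinear support touched a missing source pixel is set NaN — this prevents
NaN poisoning while keeping missingness conservative.  Reflectance attaches
to points by nearest-neighbor through each point's source pixel (one pixel
↔ one point); no interpolation happens across depth discontinuities.
Values outside [0, 1] are clipped with a logged warning.

## Turntable calibration (`ms3d.turntable`)

Sticker detection thresholds the cloud's RGB attributes in HSV space
(yellow hue 0.10–0.22; red hue wrapping 0.95–0.04; saturation ≥ 0.35,
value ≥ 0.25) and returns the inlier centroid; fewer than 20 inliers is a
detection failure.  For a 180° table rotation each sticker's chord midpoint
lies exactly on the axis, so the center M is the mean of the two midpoints.
The normal is the average of the two cross products `(R−M)×(Y−M)` at the
two rotations, oriented so its angle with the camera +Y axis is acute (the
sensor always looks down on the table in this rig).  Degenerate inputs —
sticker within 5 mm of the axis, or the four centers within 1 mm RMS of
collinear — raise errors rather than returning garbage.  With more than two
views, all 180°-pair midpoints are averaged and the plane normal comes from
an SVD fit of all sticker centers.

The calibration quality reachable at the default synthetic conditions is
measured, not assumed: the acceptance suite reports mean center error
≈ 2 mm and normal error ≪ 1° over 20 random rig poses at 1.5 mm depth
noise.  The residual center bias is a property of grazing-angle depth
imaging of a horizontal disc (pixel-footprint averaging), not of the axis
estimator, which is exact on noiseless centroids.

## Point-cloud chain (`ms3d.pointcloud`)

* **Unprojection** keeps the y sign flip (`y = −(j−c_y)z/f_y`) so +Y points
  up in camera space; depth 0/NaN and readings outside the sensor's
  0.50–4.50 m trusted range produce no point.  Pixel provenance (i, j) and
  the view id ride along with every point.
* **Common frame**: translate by −M, rotate about X
  (cos α = b/√(b²+c²)) then about Z (cos β = √(b²+c²)) so the unit axis
  normal lands exactly on (0, 1, 0), then rotate about Y by the inverse
  spin angle γ = view_index·360°/V_N·spin_sign.  The rotation matrices are
  written so that the normal genuinely maps to +Y (verified to 1e-9 for
  1000 random axes in the test suite).  `spin_sign` is configurable (+1
  default) because the table's rotation direction is a rig property.
* **ICP** is point-to-point: nearest-neighbor correspondences gated at
  10 mm, closed-form SVD rigid fit, iterated until the correspondence RMS
  changes by < 1e-6 m or 50 iterations.  Zero gated correspondences at the
  initial pose raise a no-overlap error.
* **Fusion** merges views sequentially (model + next view, re-registered
  each step).  The incoming view is the cloud that moves; the accumulated
  model stays fixed.  This anchors the fused model in the rough common
  frame — if instead the accumulated model is dragged toward each new view,
  per-view sensor biases compound into a global offset of several mm, which
  we measured directly against synthetic ground truth.  The relative
  pairwise alignment is identical either way.
* **Voxel downsampling** (2 mm default) averages XYZ/RGB/reflectance and
  any extra attributes NaN-aware and majority-votes the view id.
* **Outlier removal** is the statistical k-NN criterion (k = 20,
  std_ratio = 2): discard points whose mean k-NN distance exceeds the
  global mean by more than 2 standard deviations.
* Views are ROI-cropped *before* ICP, so the table and stickers never take
  part in plant registration.

## Indices and statistics (`ms3d.indices`)

The nine indices are computed per point; a plant-level scalar is the mean
of per-point values (average-of-index, not index-of-average).  Any index is
NaN where a required band is NaN or a denominator magnitude is below 1e-9.
Canopy statistics use the sample (n−1) standard deviation and
CV = STD/mean × 100%; a zero mean makes CV NaN with a warning, and an
all-NaN input is an error rather than a silent empty row.

## SPAD calibration (`ms3d.spad`)

Prototype forms: M1 `a·x + b`, M2 `a·x² + b·x + c`, M3 `c·10^(k·x)`,
M4 `c·x^k` (x > 0, c > 0).  M1/M2 are ordinary polynomial least squares;
M3/M4 are nonlinear least squares on the original scale initialized from
the log-linearized OLS solution — noiseless data is recovered to machine
precision while noisy fits minimize the untransformed residual (a pure
log-space fit would weight low-SPAD points more).  Diagnostics:
R² = 1 − SS_res/SS_tot (squared Pearson correlation available via
`r2_mode="pearson"`); RMSE uses denominator n, not n − p.  The registry of
published fused-canopy equations stores coefficients digit-exact and keeps
the published R²/RMSE as metadata only — they describe the original
60-plant study data, which is not distributed, and are never recomputed
here.

## Synthetic scenes (`ms3d.synth`)

The generator's defaults are the study conditions: a 20 cm table with two
5 cm stickers, a pot (radius 5 cm, height 12 cm), a stem with 8 arched
elliptic leaves (~13 × 5.5 cm), camera ~1.08 m from the table center
looking down at it, V_N = 4 views at 90° steps, Gaussian depth noise
σ = 1.5 mm (typical time-of-flight noise), per-point SPAD uniform over
[31.46, 60.90] (the observed range of the emulated study), and a spectral
imager offset by the fixture transform (dx = 8 px, dy = −5 px, θ = 4°,
σ = 0.85), chosen to exercise all four similarity parameters.  The image
grid is 320×240 at f = 300 px — Kinect-like geometry at reduced
resolution, which keeps the full 4-view reconstruction suite fast while
preserving the ~3 mm pixel footprint regime of the real sensor at 1 m.

Rendering is occlusion-correct point splatting: each surface sample
projects to its pixel and the nearest sample wins.  The reported depth is
the *mean* over all samples within 5 mm of the per-pixel minimum, because a
real depth camera integrates over the pixel footprint; a pure min-depth
z-buffer systematically biases oblique surfaces toward the camera by a few
mm, which we measured and removed.  Depth noise is added per pixel in mm
and rounded to uint16.  The reflectance cube is rendered by pushing the
truth-aligned planes through the scene's similarity transform, with mild
band noise.  Axis calibration views are rendered bare-table (plant and pot
removed), matching the acquisition protocol in which the axis is calibrated
before the plant is placed; with the plant present the pot occludes the far
sticker at this camera geometry.

The reflectance↔SPAD link inverts one published exponential curve
(default: the CIG model): a plant point's SPAD determines its NIR/green
ratio; NIR is drawn near 0.72, green follows from the ratio, red/blue are
low, red-edge intermediate, all with ~0.01 additive noise and clipped to
[0, 1].  What passing tests therefore show: the geometry chain, the
registration chain and the index/SPAD algebra are correct and recover known
ground truth under realistic noise.  What they do not show: performance on
real leaf optics (no radiative-transfer model, no specularities, no
multi-path depth artifacts, no illumination gradients), real sticker
print colors, or real turntable wobble.

## Problem sizes

Default test problem sizes: 128×128 registration textures; ~45 000 surface
samples per scene; ~3 000 points per view cloud after cropping; ~11 000
fused points; 20-pose calibration and 20-transform registration recovery
suites; 100-seed × 4-prototype SPAD Monte Carlo; 10⁶-draw index identity
checks.  The full suite runs in well under a minute on one CPU.

## Known limitations

* The similarity registration assumes the sensors are related by a 2D
  similarity; projective or lens-distortion effects are out of scope.
* Sequential pairwise ICP has no loop closure; drift across views is
  bounded by the turntable rough registration but not globally optimized.
* Sticker "centers" are color-threshold centroids; a circle fit could
  reduce partial-occlusion bias but is not implemented (centroid is the
  configurable default).
* Single-frame depth per view; multi-frame per-view fusion would reduce
  noise on thin stems.
* RMSE of SPAD fits uses denominator n; comparisons against tools using
  n − p will differ slightly at small n.
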
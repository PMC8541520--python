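# Methods

## Photometric model

The simulator renders a gradient test-sheet pixel at image column `c` as

    pixel(r, c) = clip(gain · L(t_c)^gamma + offset + ε, 0, saturation)

with `t_c = c/(cols−1)`, `L(t) = (pwm/100) · s(t)` the relative scene
radiance, `s(t)` a spatial illumination profile, and `ε ~ N(0, noise_sigma²)`
additive read noise. Rows are noise replicates: the scene varies only along
the gradient axis.

Assumptions baked into this model, and why:

* **LED radiance is exactly proportional to PWM duty.** The LED is the
  reference standard of the whole evaluation; making it ideal means any
  nonlinearity the analysis finds is attributable to the camera alone. A real
  LED's small duty-to-radiance deviation would be misattributed to the camera
  — a limitation shared by the physical measurement this emulates.
* **The camera's only distortions are gain, gamma, offset, clipping and
  Gaussian read noise.** No Poisson shot noise, lens vignetting, PSF, Bayer
  mosaic, or auto white balance. Gaussian noise is sufficient for the
  residual-variance error metric, which only sees second moments; vignetting
  would fold into the spatial profile and be absorbed by the polynomial fit.
* **Images circulate as float64 clipped to [0, saturation].** Quantization to
  8/16-bit integers happens only at PNG/TIFF write time. The in-memory model
  therefore preserves exact proportionalities (a PWM-50 frame is exactly half
  a PWM-100 frame for a γ=1 noise-free camera); quantization error appears,
  realistically, only on the file-based path.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| PWM levels | 100, 80, 60, 40, 20 | duty % | the five-level series the evaluation is designed around; 100 is the reference |
| `gain` | 230 | counts per unit radiance | puts the brightest pixel near, but under, 8-bit saturation |
| `gamma` | 1.0 | — | ideal linear sensor; the quantity the methods score |
| `offset` | 0 | counts | black level; nonzero values genuinely break proportional scaling and are reported as such |
| `noise_sigma` | 2.0 | counts | typical read noise at 8-bit scale; row-averaging reduces it by √rows on profiles |
| `saturation` | 255 | counts | 8-bit default; 16-bit (65535) supported |
| spatial profile `s(t)` | 0.35 + 0.30·t + 0.20·t² + 0.15·t³ | relative radiance | a smooth *monotone cubic*: real gel-box lighting is non-uniform, and a cubic exercises polynomial order selection realistically (order 3 is the correct answer by construction of the lighting, not of the analysis) |
| gradient image shape | 64 × 256 | px | 256 profile points condition fits up to order 6 well; 64 replicate rows suppress profile noise |
| fit order (scaling stage) | 3 | — | order selection on gradient series plateaus at the cubic |
| plateau tolerance | 5% | relative error improvement | numeric stand-in for the visual "no further change" judgement; with an absolute floor of 1e-9 counts² below which an error counts as converged (relative changes of epsilon-sized errors are float noise) |
| concentrations | 1, 1/2, 1/5, 1/10, 1/20 | relative | the dilution series loaded into the five gel lanes |
| `band_peak` | 180 | counts | with background 30, the strongest band tops out at 210 < 255: no clipping, so volume stays proportional to concentration |
| `background_level` | 30 | counts | dim but nonzero gel autofluorescence/illumination floor |
| band σ (rows × cols) | 6 × 10 | px | bands wider than tall, well separated at 80 px lane pitch |
| ROI margin | 3.5 σ | — | captures 99.9% of the Gaussian volume while leaving a clean border for background estimation |
| `border_width` | 3 | px | background = median of this frame around the ROI |

## Analysis procedures

**Profiles and fits.** A profile is the column-wise mean of the image (green
channel for RGB input — gel illumination here is a green LED; both axis and
channel are configurable). Fits are ordinary least squares on the monomial
basis of t ∈ [0, 1] via `numpy.polynomial` — at orders ≤ 6 on [0, 1] the
Vandermonde system is well conditioned, so no basis orthogonalization is
used. Coefficients are stored lowest-order first; a converter to the
highest-first convention is provided. The error metric is the *population*
variance (divisor N) of the residuals. Note its blind spot: a constant
residual offset has zero variance and is invisible to every stage that uses
this metric; this is a property of the metric, preserved deliberately.

**Reflectance constancy.** The level-ω fit is compared against the reference
fit scaled by ω/100, evaluating the fitted curve on a 100-point grid and the
scaled baseline on a 10-point grid; the deviation summary (max-abs, and also
variance so a single bad region cannot be averaged away) is computed on the
10-point grid where both curves are defined.

**Scaling constants.** `d_ω = argmin_d var(y_ω − d·ŷ₁₀₀)` has the closed form
`cov(y_ω, ŷ₁₀₀)/var(ŷ₁₀₀)` because the objective is quadratic in d; the
brute-force grid search (step 1e-4 over [0, 1.5]) is retained purely as a
test oracle. A flat reference (var(ŷ₁₀₀) ≤ machine-epsilon relative to its
magnitude) leaves d undetermined and raises an error. d is unconstrained;
values outside [0, 1.5] are flagged as suspicious, never clipped. The scalar
camera score is the RMS of d_ω − ω/100 over non-reference levels — a
package-level summary of a comparison that is otherwise judged by eye.

**Band volumes.** background = median of the border frame around the ROI;
volume = Σ max(pixel − background, 0). The negative-clamp makes volumes
robust to background over-estimates at the cost of a small positive bias in
pure noise; with the default ROI and border the bias is negligible against
the weakest band. An optional automatic band finder (smoothed column-profile
peaks, window 5 px, prominence 5% of dynamic range) exists for convenience;
annotated ROIs are the primary path, and at the default prominence the 1/20
band sits right at the detection limit — by design it is a *faint* band.

**Ranking and ties.** Shots are ranked by R² (1 = best); exact ties are
broken in favour of the earlier shot (less UV exposure) and flagged. R² = 1
reports SNR = ∞ with a degenerate flag and is treated as maximal by ranking.
An R² that is undefined (all volumes identical) is a degenerate result, not
an error.

**Rectification.** The 3×3 homography from the four annotated gel corners to
the target rectangle (8 unknowns from 4 point pairs) is estimated with
`skimage.transform.ProjectiveTransform` and applied with bilinear
resampling; an 8×8 direct-linear-transform solve is kept as an independent
oracle in the tests.

**Slope comparison across cameras.** Regression slopes are rescaled by
per-shot exposure-normalization factors from the experiment definition
(default 1) before forming the flank/centre slope ratio, since absolute
slopes are exposure-dependent.

## What the simulator does and does not emulate

It emulates: PWM-proportional illumination with a smooth non-uniform spatial
profile; a parameterized nonlinear camera response with clipping and read
noise; gel bands with exactly concentration-proportional integrated
intensity; projective camera geometry; deterministic per-level noise streams
(`SeedSequence(base_seed, level)`) so a series is reproducible level by
level.

It does not emulate: Poisson shot noise, optics (PSF, vignetting, defocus),
sensor fixed-pattern noise, demosaicing, JPEG artifacts, UV-induced band
fading within a shot sequence (available as an explicit per-shot
`fading_per_shot` multiplier, default off), or gel artifacts (smiling lanes,
streaks, dust). Passing tests therefore demonstrate that the *analysis
chain* recovers known ground truth under the stated photometric model — they
do not certify performance on real photographs, where band segmentation and
background structure are the dominant error sources.

## Numerical choices

* Population variance everywhere (divisor N), matching the error definition.
* An exact dilution fit snaps R² within 1e-12 of 1 to exactly 1 (SNR = ∞,
  flagged) rather than reporting float jitter.
* Saturated pixels are *not* excluded from profiles; if more than 1% of
  contributing pixels are saturated a warning is emitted.
* Degenerate inputs raise `ValueError` with specific messages (flat
  reference, missing reference level, mismatched t grids, non-convex corner
  quads, out-of-bounds ROIs); degenerate *results* (undefined R², infinite
  SNR, all-equal slopes) are flagged, not raised.
* Problem sizes: gradient fixtures 64×256 (32×128 in unit tests), gels
  200×400, 20-seed batteries for stochastic properties — all sized so the
  full suite and the acceptance script each run in a few seconds.

## Known limitations

* The constancy/scaling metrics cannot distinguish a camera offset from an
  illumination pedestal; both appear as non-constancy.
* The variance error metric ignores constant residual offsets (documented
  above); a camera whose only defect is a level-dependent DC shift would
  score as perfectly linear under method 2 while failing method 1's
  constancy check — running both is the point.
* Band volumes assume bands stay inside their ROIs; the simulator enforces
  this, real gels do not.
* With only three shots per experiment, flank-vs-centre comparisons are
  indicative, not inferential; no significance testing is attempted.
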
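# Methods

This note records the model, the numerical scheme, the synthetic study
conditions and the design choices that were genuinely open, in enough
detail that a maintainer can predict the package's behavior without
reading the code.

## The model

The contour is embedded as the zero level set of a scalar field φ on
the ROI grid, **negative inside** the disc (the sign convention is
asserted throughout the tests; the opposite convention flips the sign
of the region and balloon forces but nothing else). The energy has four
ingredients:

- **Distance regularizer** `μ ∫ p(|∇φ|)` with the double-well potential
  whose derivative is `p'(s) = sin(2πs)/2π` for `s ≤ 1` and `s − 1`
  beyond. The flow `μ div(p'(|∇φ|)/|∇φ| ∇φ)` restores `|∇φ|` toward 1
  (for `s ∈ (0.5, 1)` it acts as a mild backward diffusion toward the
  well at 1), so φ stays signed-distance-like and is never
  reinitialized. The function is implemented as the *derivative* of the
  potential: as a potential it would not be minimized at `s = 1`, which
  contradicts its stated purpose.
- **Length and balloon terms** `α ∫ δ_ε(φ)|∇φ| + β ∫ H_ε(φ)`. The
  length term's descent is `α δ_ε(φ) κ` (curvature flow restricted to
  the contour band) and smooths vessel notches. Under the
  negative-inside convention `H_ε(φ)` integrates the *outside* area, so
  `β > 0` expands the contour; the sign of β sets the balloon
  direction, which the tests assert directly rather than by
  convention.
- **Region (Chan-Vese) term** with `u0` the per-pixel intensity and
  `c1, c2` the smoothed inside/outside means. The descent force at a
  pixel is `λ_in (u0−c1)² − λ_out (u0−c2)²` (weighted as described
  under *Region force weighting*): pixels resembling the inside mean
  join the inside. A configuration flag `u0_mode="global_mean"`
  replaces `u0` by the image mean — a degenerate variant kept only for
  comparison, since it makes the integrand spatially constant.
- **Shape prior** `λ_shape ∫ (H_ε(φ) − H_ε(φ_init))²` with φ_init the
  SDF of the fitted ellipse. Its force `−2 λ_shape (H_ε(φ) −
  H_ε(φ_init)) δ_ε(φ)` saturates at `≈ 2 λ_shape δ_ε` once the contour
  is a few ε from the prior.

**Force balance on [0,1] intensities.** With the default weights
(μ=0.1, α=3.0, β=0.2, λ_in=4.3, λ_out=2.0, λ_shape=1.1) and intensities
normalized to [0,1], the saturated shape force (≈2.2·δ) exceeds the
largest region force a realistic fundus contrast can produce (≈0.3–0.8·δ).
The model is therefore **prior-dominated**: the evolution refines the
fitted ellipse by fractions of a pixel and blocks gross excursions
(bright blobs, PPA), but it cannot correct a prior that is wrong by
several pixels. This is a property of the method, not of the
implementation; it is why initialization quality decides final
accuracy, and why the accuracy ceiling discussed under *Known
limitations* exists.

## Numerical scheme

Explicit gradient descent, `dt = 0.2`, `ε = 1.5` px for the smoothed
Heaviside/Dirac pair, at most 500 iterations by default. Three
safeguards:

- the stiff shape term is treated semi-implicitly (the update is
  divided by `1 + 2 λ_shape dt δ_ε²`, the diagonal of its
  linearization), so arbitrarily large shape weights converge smoothly
  to the prior instead of chattering;
- the whole update is rescaled so its largest entry never exceeds
  `max_step = 1` px — a global rescale, preserving the descent
  direction;
- `|∇φ|` is floored at 1e-8 before any division.

Convergence is declared when fewer than `tol = 10` pixels change sign
over a 10-iteration window (per-iteration flip counts are bursty near
equilibrium). Non-convergence returns the last mask with a warning
rather than raising. The discrete energy is logged every 10 iterations;
on band-mode runs it is non-increasing to within 1% (explicit-scheme
jitter), and the mean `|∇φ|` over pixels within 3 px of the zero set
stays in [0.7, 1.3].

**Region force weighting.** By default the region force is weighted by
`δ_ε(φ)` (curve-evolution form): only the contour band moves, which is
what preserves the distance field and the energy monotone. The
alternative `region_mode="full"` applies it over the whole domain (the
classical Chan-Vese gradient flow). Full mode converges orders of
magnitude faster on flat bright regions — a disconnected bright blob
flips wholesale instead of waiting for the contour to creep across a
bridge at the regularizer-limited rate (~4 px per 1000 iterations) —
at the cost of degrading `|∇φ|` away from the contour and of the
energy-monotonicity guarantee. The shape-prior ablation
(with/without λ_shape on a blob fused to the disc) is therefore run in
full mode for both arms; the regularity monitors apply to band-mode
runs.

## The pipeline around the model

- **Localization**: the assumed mean OD radius is R_fov/3 for posterior
  images and R_fov/8 for wide-angle, where R_fov is the radius of the
  visible circular area (both exposed as configuration). The top-hat
  structuring disc is od_radius/10; the 20 vessel-density candidate
  windows are chosen greedily with centers at least one radius apart;
  the bright-pixel population is the top 2% of the value channel within
  the field of view, with massive ties restricted to strictly brighter
  pixels; the Hough search covers radii in [0.5, 1.5]×od_radius on a
  Canny edge map, falling back (with a warning) to the vessel/brightness
  center when no circle is supported. ROI crops are clamped to the grid
  and zero-padded.
- **Preprocessing**: Gaussian 17×17 (σ=1), grayscale closing then
  opening with a 15×15 elliptical element and 3 iterations — iterations
  compose the elementary dilations/erosions, so the closing reach is
  about element-radius × iterations and must exceed the vessel width —
  then a hard FFT low-pass keeping a 40×40 square at DC. These sizes
  are stated for a ~600 px reference ROI; the two *spatial* kernels
  scale linearly with the actual ROI side (`PreprocParams.scaled_for`),
  while the *frequency-domain* side stays fixed because a fixed bin
  count already selects the same relative cutoff at any grid size. The
  pass region is realized symmetrically about DC (|k| < side/2), which
  keeps the kept spectrum Hermitian and the output exactly real and
  band-limited; an asymmetric even-sided square would leak ~1e-4 of the
  energy outside the band.
- **Initialization**: the adaptive threshold selects pixels at least as
  bright as the local mean over a half-ROI window (offset C = 0; the
  sign is such that C → +∞ selects everything). When the square ROI
  contains out-of-aperture black, the local mean is normalized over a
  validity mask so the dark padding cannot drag the threshold down.
  Binary opening (5×5), largest 4-connected component, outer-contour
  tracing and a direct least-squares conic fit (constrained to an
  ellipse, axes normalized a ≥ b) complete the prior.

## Synthetic study conditions

The generator renders, deterministically from (spec, seed): a bright
elliptical disc (intensity ≈0.88) on a darker retina (≈0.42) with a
radial gradient; vessels as smoothed polylines with Gaussian
cross-sections (width 3–5 px); an optional PPA crescent as a partial
annulus hugging the disc; optional bright blobs; per-channel sensor
noise; and for wide-angle style a circular aperture with black surround
and no blue channel. Posterior frames are 320 px (disc radius ≈ R_fov/3,
matching the localization assumption), wide-angle frames 640 px (disc
≈ R_fov/8) so the disc stays well above the preprocessing kernel scale.
These sizes keep the full test suite and the acceptance script within a
few minutes on one CPU; all geometry is specified relative to the disc
radius, so conclusions transfer across scales.

Two confound regimes are deliberately distinguished:

- the **standard suite** places PPA crescents at bg + (0.15–0.25) ×
  contrast and bright blobs 14–20 px off the disc — the *separable*
  regime in which the adaptive threshold isolates the disc blob and the
  method is designed to succeed;
- the **ablation fixture** fuses a dimmer blob (0.75) to the disc
  through a 6 px gap that the closing stage bridges — the regime where
  only the shape prior prevents the contour from absorbing the noise. A
  crescent or blob bright enough to threshold together with the disc
  corrupts the prior and yields oversegmentation; that is the method's
  documented failure mode and is excluded from the standard suite.

What passing on these fixtures does **not** show: robustness to real
texture, illumination fields, camera vignetting, pathology other than
the three modeled confounds, or annotation ambiguity in clinical ground
truth.

## Known limitations

- **Accuracy ceiling from the threshold level.** The adaptive threshold
  binarizes at the local mean, which sits well below the disc-edge
  midlevel; across the preprocessed (low-pass-blurred) edge ramp this
  inflates the fitted ellipse by roughly 3% of the disc radius, and the
  prior-dominated evolution preserves that bias. Clean synthetic cases
  therefore plateau at IoU ≈ 0.92–0.95 rather than approaching 1; the
  effect is scale-invariant (the ramp and the disc scale together).
- The FSE scores 0 vs 1 both mean "no accurate sector" and cannot be
  assigned objectively; they are recorded from rater input only.
- Sector boundaries are fixed at the ±45° diagonals (superior facing
  up, half-open intervals); nasal/temporal follow eye laterality, which
  is taken from configuration, never inferred from the image.
- The evolution is single-resolution and dense; no narrow-band or
  multigrid acceleration.
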
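# Methods

## Model

RACC visualises the spatial distribution of *correlated* colocalisation in a
two-channel fluorescence volume. Each voxel i carries a joint intensity
**q**ᵢ = (xᵢ, yᵢ) with both components in [0, I_max] (255 for 8-bit data,
65535 for 16-bit). The method assumes that where two labelled structures
genuinely associate, their intensities rise and fall together, so the
interesting voxels cluster around a line in the joint-intensity plane.

Because both channels are measured with error, that line is estimated by
Deming regression rather than ordinary least squares. The error-variance
ratio λ = σ²_η/σ²_ε defaults to 1 (orthogonal regression), appropriate when
both channels are acquired under comparable conditions; it is exposed for
unequal acquisition settings. Only voxels *strictly* above both background
thresholds (T_ch1, T_ch2) enter the moment estimates; the thresholds are
user-supplied and mandatory, since silent background defaults make runs
irreproducible. Covariances use the unbiased n−1 divisor. The slope is the
positive root of the Deming quadratic in all cases: the two roots always
have opposite signs (their product is −1/λ), and a negative-covariance
sample — which signals essentially uncorrelated channels — still yields a
positive-slope line, with a warning.

The final per-voxel value composes three steps, evaluated in one closed
form:

- **Span.** p₀ is the line's crossing of the binding threshold line, p₁ its
  crossing of the intensity ceiling. The perpendicular projection parameter
  t ∈ ℝ locates each voxel along p₀ → p₁.
- **Rescale.** p_max = p₀ + t_max(p₁ − p₀), with t_max the nearest-rank 99th
  percentile of the projection parameters, clamped to (0, 1]. Projections
  beyond p_max saturate at 1; below p₀, clamp to 0. The toggle `rescale=False`
  retains p₁ instead (useful when an unsaturated, strictly monotone mapping
  is wanted, e.g. for profile analyses).
- **Attenuate and cut.** The normalized distance d = |qᵢ − pᵢ|/I_max reduces
  the value by d·tan θ, θ ∈ [0, 90) degrees (default 45°, the only tunable
  display parameter; 0 disables attenuation, values near 90 suppress
  everything off the line). Voxels with d above the distance threshold d_t —
  the nearest-rank 99th percentile of the masked voxels' distances — are
  suppressed entirely.

The base position along p₀ → p_max is computed as t/t_max rather than as an
x-coordinate ratio; the two are identical for any finite positive slope, but
the former has no division blow-up for steep lines. Note an intentional
normalization asymmetry, implemented as designed: d is normalized by I_max
while the base value is normalized by the p₀ → p_max segment length, so with
very large thresholds the attenuation is relatively stronger.

### nMDP reference

The normalized mean deviation product is computed per voxel over the *union*
region of interest (at least one channel above its threshold), with the
channel means taken over that ROI. The normalizing maxima default to the
within-ROI maxima — the natural reading once manual thresholding performs
the background removal — with a `max_scope="global"` switch for whole-image
maxima. nMDP > 0 is read as colocalised. The classification comparison
labels each voxel agree / RACC-only / nMDP-only / neither, and reports the
percentage of all voxels classified differently.

## Choices on degenerate and edge inputs

- Fewer than 3 above-both-thresholds voxels: error (no meaningful moments).
- s_xx = 0, s_yy = 0, or |s_xy| < 10⁻¹²·s_xx: error. A vanishing covariance
  admits no regression direction, and a vertical/horizontal line breaks the
  x-parameterisation of the colour value; the error message tells the user
  the method is not meaningful for such data rather than guessing.
- θ = 90° exactly is rejected (tan diverges); the valid range is [0, 90).
- If the thresholds push p₀ at or beyond p₁ (no intensity span left below
  the ceiling), the pipeline errors out rather than producing an empty map.
- Nearest-rank percentiles (rank = ⌈0.99·n⌉) are used for both d_t and
  t_max so the ≥ 99% inclusion guarantee holds exactly for any sample size;
  both are computed independently from the same masked-voxel statistics.
- An optional ROI bounding box refits the whole model on the sub-volume;
  regional analyses should always refit, since different subcellular regions
  can have different regression lines.

## Synthetic phantoms

The generator emulates the canonical validation geometries: solid spheres
and finite cylinders whose intensity is maximal at the centre/axis and
decays *linearly* to zero at the surface — the simplest monotone profile
with closed-form expectations; real point-spread functions are smoother but
share the centre-bright structure. Scenes are rendered on a 64³ isotropic
grid at 8-bit depth by default, each channel the voxel-wise maximum over its
primitives, with optional seeded additive Gaussian noise (clipped, then
quantized). Presets:

- `overlapping_cylinders`: one radius-10, length-48 cylinder in both
  channels — perfectly correlated by construction (slope 1, intercept 0,
  PCC 1, all voxels exactly on the line).
- `partial_spheres`: radius-16 spheres with centres 8 voxels apart. The
  offset matters: with linear falloff, offsets beyond ~12 voxels make the
  lens intensities *negatively* correlated (the along-axis anticorrelation
  r₁ + r₂ ≈ const dominates), which is the degenerate regime the method
  warns about. Half-a-radius separation keeps the overlap substantially,
  positively correlated (lens PCC ≈ +0.27), as expected of a genuine fusion
  event.
- `cylinder_sphere`: a radius-8 cylinder and radius-12 sphere whose surfaces
  barely interpenetrate (overlap ≈ 0.8% of the sphere's voxels).

Noisy variants used in the validation runs add noise_sd = 8 (≈3% of the
8-bit range) and are thresholded at 25 ≈ 3σ, the standard background cut.
The phantoms deliberately omit point-spread blur, Poisson photon statistics
and chromatic shift, so passing tests demonstrate the correctness of the
mapping pipeline, not robustness to real acquisition physics.

## What the validation runs measure

Problem sizes were chosen to exercise every code path at desk scale: 64³
volumes (≈2.6·10⁵ voxels, of which ~7·10³ are above both thresholds on the
noisy spheres phantom), and 100 random 50-point samples for the
closed-form-vs-numeric regression cross-check (grid search plus Nelder–Mead
on the profiled errors-in-variables loss; agreement to |Δβ₁| < 10⁻⁶). The
99% inclusion guarantees of d_t and t_max are verified by direct counting;
the single-formula colour value is checked against the sequential
project → attenuate → cut composition to 10⁻¹²; and the identical-cylinders
phantom verifies the exact perfect-correlation invariants.

One caveat surfaced by the comparison tests: voxels above both thresholds
whose distance exceeds d_t (by construction ≈1% of the masked set) can
carry a positive deviation product, so nMDP calls a small number of
both-channel voxels colocalised that RACC deliberately suppresses as
coincidental — on the noisy spheres phantom, a few tens out of ~2.6·10⁵.
These are exactly the high/low-intensity outlier pairs the distance
threshold exists to remove; the overwhelming majority (>99%) of
nMDP-only voxels nevertheless lie where only one channel is present.

## Rendering

Score volumes are rendered with the perceptually uniform Magma colourmap
(black at 0, bright yellow at 1; any named matplotlib map can be
substituted), non-visualised voxels in a configurable background colour.
nMDP uses a diverging blue / red→yellow map with a deliberate discontinuity
at zero, linearly scaled between manual display bounds (default −1, 1) —
nMDP values can exceed these, so they are clipped. Difference maps follow
the magenta (RACC-only) / yellow (nMDP-only) convention, agreement in white.
Interactive 3D rendering is out of scope; per-slice RGB export plus maximum
intensity projections reproduce every figure type at desk scale.

## Limitations

- The method presumes a meaningful *positive* linear trend; anticorrelated
  or trendless data trigger warnings/errors rather than producing maps.
- d_t and t_max are sample percentiles: with heavy ties or tiny n they can
  include more than 99%, never less.
- The colour value is a display quantity, not a calibrated statistic; use
  scalar coefficients (PCC reported alongside) for quantitative claims.
- TIFF input only (8/16-bit grayscale stacks or a two-channel stack);
  proprietary microscope formats should be converted upstream.
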
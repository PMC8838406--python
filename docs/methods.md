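# Methods

This note documents the models, parameters and numerical choices behind
`vesselseg`, and what the synthetic phantoms do and do not establish
about performance on real fundus photographs.

## Image model and preprocessing

Images are 2-D float arrays in [0, 1] (gray) or (H, W, 3) RGB. The
Retinex decomposition `S = i · R` treats the observed image as
illumination times reflectance; Multi-Scale Retinex recovers a
reflectance estimate as `Σₙ wₙ (log S − log(S ∗ Fₙ))` with normalized
Gaussian surrounds `Fₙ`.

- **Surround scales** default to (15, 80, 250) px — the customary
  small/medium/large triple spanning fine detail to global
  illumination. Weights default to 1/3 each. Both are configurable
  (`msr.scales`, `msr.weights`).
- **Log stabilization.** Pixel values are floored at
  `epsilon = 1/255` before logs. A floor (rather than an additive
  shift) keeps the log-ratio exactly invariant to a global
  multiplicative gain on images bounded below by epsilon, which is the
  property that makes MSR an illumination corrector; an additive shift
  would break that invariance at the ~1e-3 level.
- **Normalization.** The raw MSR response is signed and unbounded; it
  is min–max rescaled to [0, 1] per channel because downstream
  histogramming needs a fixed range. This is a pragmatic choice — the
  rescaling constants are image-dependent, so absolute MSR values are
  not comparable across images (threshold selection is per-image
  anyway).
- MSR runs on the full color image first; the green channel is
  extracted afterwards. Convolution uses reflective boundaries at
  every scale, avoiding dark-rim artifacts at the image border.

## Matched-filter bank

The kernel at orientation θ is `−exp(−u²/2σ²)` evaluated at every
integer pixel offset whose rotated coordinates satisfy `|u| ≤ 3σ`,
`|v| ≤ L/2`, with the in-support mean subtracted. Mean subtraction is
essential: without it the response tracks local brightness rather than
vessel contrast, and the response to a constant image would not be
zero. Because vessels are dark, the negative kernel gives positive
responses at vessel centers; responses are clamped at zero from below
before fusion so only vessel evidence accumulates.

- **Length L = 9 px** — the segment length over which a vessel is
  treated as straight. **12 orientations** at 15° steps span 180°.
- **Scales (1.9, 0.5, 0.13)**: coarse trunk extraction, intermediate,
  and fine capillary detail. Fusion weights default to uniform 1/3.
- **σ = 0.13 degeneracy.** 3σ ≈ 0.39 < 0.5, so at axis-aligned angles
  (0°, 90°) the integer support collapses to a single line of constant
  u = 0 and mean subtraction annihilates the kernel: those two
  orientations contribute exactly zero at this scale. At oblique
  angles the support is a thin rotated strip with genuine
  cross-section variation, and the scale acts as an oriented
  line/edge detector. This is what the template definition yields at
  that scale and is deliberately not patched; the other two scales
  cover axis-aligned vessels.
- Per-scale responses are *not* individually rescaled before fusion;
  only the fused map is min–max normalized. Rescaling per scale would
  re-weight the scales in an image-dependent way.
- Kernels are point-symmetric, so correlation equals convolution;
  boundaries are reflective, matching preprocessing.

## Threshold search

The m-threshold Otsu objective is the between-class variance
`σ_B²(t₁..t_m) = Σₖ wₖ(uₖ − u_T)²` over the 256-bin in-FOV histogram.
Identities `Σ wₖ = 1` and `Σ wₖuₖ = u_T` hold exactly and are enforced
by tests. Quantization is `floor(v·255)` with a 1e-6 guard inside the
floor so values that are exact multiples of 1/255 land on their
intended level despite float rounding.

Single-threshold Otsu is an exhaustive scan (smallest threshold wins
ties — deterministic and testable). For m = 3 the search uses a
canonical PSO:

- **Particles move in continuous [0, 254]³**; fitness is evaluated on
  the repaired projection (round, clip, sort, bump duplicates up one
  level). This keeps the velocity/position update intact while the
  objective stays defined on strictly ordered integer triples.
- **Settings**: 40 particles, inertia w = 0.5, acceleration
  c₁ = c₂ = 2, 20 iterations. Velocities are clamped to ±20% of the
  gray range and positions reflected at the bounds; at these settings
  the swarm would otherwise diverge.
- **Reproducibility**: one seeded generator per search; random draw
  order is fixed (r₁ before r₂, particle-major, dimension-minor).
- On four-mode test histograms the swarm attains the exhaustive
  ~2.7M-triple optimum to within 1e-9 in ≥ 95% of seeded runs (and
  within 0.1% in all observed runs): the 800-evaluation budget is
  ample because the objective's plateaus are wide.

The four classes are rendered at equally spaced gray levels
({0, 85, 170, 255} for m = 3) and re-binarized with single-threshold
Otsu. On vessel-response histograms the background class dominates, so
the re-binarization typically splits directly above class 0 — the
mechanism by which three-threshold segmentation keeps faint vessels
that a single global threshold discards.

## Post-processing

One cleanup pass applies, in order: 3×3 median filter (speckle removal
and small-gap bridging), morphological closing (disk radius 1,
reconnection), removal of 8-connected components below 30 px, and
zeroing of everything on or outside the dilated (radius 3) FOV
boundary ring. All sizes are configurable and sized for 565×585
images.

The full `postprocess` operator iterates this pass to a fixed point. A
single pass is not a root of itself — a binary median keeps shaving
corners newly exposed by the edge subtraction, so a second application
would still change the map. Every step is monotone on the binary
lattice, which guarantees the iteration terminates: if a cycle is
detected (binary medians admit short oscillations), the cycle states
are intersected, giving a contracting point from which the iteration
decreases monotonically to a genuine fixed point. The result is a
proper idempotent morphological filter, at the cost of a small
sensitivity reduction (~0.01–0.02 on phantoms) relative to one pass.

The FOV mask itself comes from Otsu-thresholding the red channel
(bright across the whole retina), keeping the largest component and
filling holes; an externally supplied mask bypasses extraction.

## Evaluation metrics

Acc, Se, Sp come from confusion counts inside the FOV (configurable to
whole-image; DRIVE-style masks otherwise inflate both Acc and Sp with
trivially rejected surround pixels). Zero-denominator cases are
reported as missing, never as 0. SSIM uses the reference formulation's
defaults (11×11 Gaussian window, σ = 1.5, C₁ = (0.01R)², C₂ = (0.03R)²).
The S-measure is the standard structure measure
`S = α·S_object + (1−α)·S_region` with α = 0.5: an object-aware term
comparing foreground and background response distributions to the
ideal, and a region-aware term applying an SSIM-form comparison to the
four quadrants about the truth centroid, area-weighted. Degenerate
truths (all background / all foreground) fall back to mean-intensity
agreement.

## Synthetic phantoms

Phantoms emulate exactly the image properties the pipeline's stages
address: dark vessels with **inverted-Gaussian cross-sections**
(σ_v = width/2.355, the FWHM convention) — the profile the matched
filter is derived for, making scale selectivity analytically
predictable; widths graded 1–6 px; a circular FOV on a near-black
surround; a broad off-center Gaussian illumination ramp; additive
Gaussian noise (σ = 0.02 by default, a realistic sensor-noise level
for 8-bit fundus imagery). Ground truth is the half-peak-depth cut of
the noiseless vessel field — deterministic and width-consistent.
Color phantoms put the vessel signal predominantly in the green
channel, with a brighter low-contrast red channel and a dim, noisier
blue channel, mirroring real channel statistics.

The batch generator draws a vessel tree (two-piece mains 4–6 px wide
radiating from an off-center hub, oblique 1–2.5 px branches) with
contrast depths 0.18–0.32 against a 0.55 background — chosen once as
representative of green-channel vessel contrast.

What phantoms do **not** model: optic disc, lesions and exudates,
vessel curvature and caliber variation along a segment, central light
reflex, and spatially correlated noise. Passing the phantom-recovery
tests therefore demonstrates that the stages compose correctly and
recover Gaussian-profile curvilinear structure under noise and uneven
illumination — not that DRIVE/STARE-level scores are matched;
evaluation against real datasets uses the `evaluate` harness with the
datasets supplied by the user.

## Problem sizes in tests

The acceptance suite runs the full pipeline on ten 565×585 phantoms
(the standard fundus resolution) plus a single-threshold ablation;
oracle comparisons use 50 random histograms (single threshold), 20
four-mode histograms at 64 and 256 levels (triple threshold), and
constructed fixtures elsewhere. Unit tests use smaller images
(15–300 px) where the property under test is resolution-independent.

## Known limitations

- Thresholds, and hence segmentation, depend on per-image min–max
  normalizations; absolute response values are not comparable across
  images.
- The σ = 0.13 scale is blind to axis-aligned vessels (see above).
- PSO optimality is statistical, not guaranteed; the exhaustive scan
  remains available for m = 1 and as a test oracle for m = 3.
- The FOV extractor assumes a single bright quasi-circular field; it
  will fail on images without a dark surround (an external mask can
  always be supplied).
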
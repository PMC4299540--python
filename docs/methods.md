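# Methods

This note records the models, parameters and numerical conventions behind
`tumorloc`, the choices made where the design was genuinely open, and what
the synthetic experiments do and do not demonstrate.

## Pipeline model

The framework assumes a *rigid, translation-only* relationship between the
planning CT and the MV-CBCT: offsets are the only registration parameters,
and template matching likewise searches integer translations only. Rotation,
deformation and tumor baseline shape change are out of scope. Alignment is
delivered in two stages on purpose: an exhaustive coarse search on 5 mm
grids (cheap, quantized to 5 mm) whose residual is absorbed by exhaustive
1 mm template matching inside a search region; the final sub-voxel component
comes from the centroid of the Otsu-binarized GTV, not from interpolating
the correlation peak.

Normalized cross-correlation is the sole similarity measure. Its mean/SD
normalization absorbs the global affine intensity mismatch between CT
Hounsfield units and MV-CBCT image values, so no intensity harmonization is
applied anywhere.

## Tunable parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `preprocess.median_size` | 3 | voxels | 3×3×3 median for CBCT quantum noise |
| `preprocess.log_sigma_px` | 0.7 | voxels | LoG scale for edge enhancement |
| `preprocess.log_mode` | `sharpen` | — | see "LoG convention" below |
| `registration.coarse_spacing_mm` | 5.0 | mm | coarse-grid registration spacing |
| `registration.dilation_px` | 20 | voxels | search-region dilation of the GTV cuboid |
| `enhance.gamma` | 1.0 | — | blob-selectivity sharpness |
| `enhance.sigma_mm` | auto (= d/4) | mm | Hessian scale from the GTV effective diameter |

The blob filter is single-scale: one σ per case, derived from the planned
GTV volume, applied identically to template and search region. No
scale-space maximum is taken.

### LoG convention

"Edge enhancement with a Laplacian of Gaussian" admits two readings: emit
the raw LoG response, or sharpen the image by subtracting it (unsharp
masking). The raw response inverts blob polarity — a bright tumor becomes a
dark center ringed by zero crossings — so a raw-intensity or blob-enhanced
template cannot match such a region image (the region's blob response at
the tumor is ≈ 0, and matching fails catastrophically in simulation, mean
errors ~20 mm). The sharpened image keeps HU-like polarity with crisper
edges and behaves well for every template mode, so `sharpen` is the
default; `response` remains available as a config switch for sensitivity
analysis. Preprocessing is applied to the MV-CBCT only; templates come from
the unprocessed 1 mm planning CT (a config flag can extend the chain to the
CT).

## Enhancement filters

The 3D Sobel magnitude uses the three 3×3×3 kernels (central difference ⊗
[1,2,1] ⊗ [1,2,1]) with edge replication.

The blob filter diagonalizes the Gaussian-scale Hessian per voxel. With
eigenvalues ordered λ₃ ≤ λ₂ ≤ λ₁, the response is
`|λ₃|·(λ₂/λ₃)^γ·(λ₁/λ₂)^γ` on the support λ₁ < 0 and zero elsewhere; the
eigenvalue-ratio weights lie in (0, 1], equal 1 for isotropic curvature and
collapse for plate-like (λ₁ ≈ λ₂ ≈ 0) or tube-like (λ₁ ≈ 0) structure. At
γ = 1 the product telescopes to |λ₁| on the support — an identity the test
suite asserts voxelwise. The response is emitted as a nonnegative
bright-blob map; NCC is indifferent to a global sign flip. A strictness
floor of `1e-12 · max|I| / σ²` on λ₁ keeps float-epsilon curvature of flat
regions out of the support.

## Numerical choices

- **Interpolation.** Tricubic = separable Keys cubic convolution
  (a = −0.5), trilinear for the 5 mm registration grids, both with edge
  clamping. Keys interpolation is exact on the grid (weights (0,1,0,0) at
  zero fraction), so a zero-shift resampling is an identity.
- **Gaussian derivatives.** All Gaussian, first- and second-derivative
  kernels are sampled analytically, truncated at 4σ, and moment-corrected:
  unit sum (smoothing), zero sum / unit ramp slope (1st), zero sum / unit
  curvature on quadratics (2nd). At the small scales used here (0.7–1.5 px)
  uncorrected sampled kernels leak DC — a constant −900 HU volume would
  otherwise produce a spurious Laplacian response of several HU.
- **Argmax ties** in registration and matching break to the smallest offset
  in lexicographic (z, y, x) order.
- **Otsu binarization** uses 256 equal-width bins over the min–max of the
  placed-GTV voxel intensities only (not the surrounding cuboid, which a
  config switch enables); the threshold is the upper edge of the last
  background bin and foreground is `value ≥ threshold`. Ties — e.g. cuts
  through an empty inter-class gap — resolve to the lowest cut. Degenerate
  sets (constant intensities, empty foreground) fall back to the full mask
  with a warning.
- **Statistics.** Sample SD (n−1) throughout; pooled-variance two-sample
  t-test (no Welch correction) and two-sided variance-ratio F-test at
  α = 0.05, with no multiple-testing correction.
- **Degenerate inputs.** Zero-variance templates or images raise a
  dedicated error rather than returning NaN correlation.

## The synthetic data model

`phantom.make_phantom_ct` builds a thorax surrogate: a soft-tissue
ellipsoid (+40 HU) in air, two ellipsoidal lung fields (−900 HU), and
anti-aliased spherical tumors rasterized by 3³ voxel supersampling so
ground-truth volumes carry sub-voxel accuracy. Each lung is threaded by
tapered soft-tissue tubes standing in for pulmonary vessels. These tubes
matter: on featureless lungs every template mode localizes perfectly and
the mode comparison is vacuous. The tubes deliberately overshoot the lung
boundary so they merge into the chest wall like vessels entering the hilum
— a free-standing tube end-cap is itself a sphere-like structure that the
blob filter would (correctly) enhance, which no real vasculature presents.

The validation phantom uses the physical test object's values: 10 mm
spheres at +270 HU contrast over lung (−630 HU) at the apex,
tracheal-bifurcation and base stations. The clinical-like cohort instead
uses soft-tissue tumors (≈ +40 HU, contrast 940 over lung), because solid
lung cancers are soft-tissue density; this matters for the two near-wall
cases, where a foam-contrast (−630 HU) tumor against the +40 HU wall is a
*dark* bump with no bright-blob signature and the method rightly fails.

`phantom.degrade_to_cbct` models MV-CBCT character as: contrast scaling
about the lung baseline (×0.6), a known rigid shift (tricubic), Gaussian
blur (FWHM 3 mm), additive white Gaussian noise (SD 20), cropped to a cubic
FOV (128 mm default) about the isocenter. Blur/noise/contrast are
surrogates, not measured values; they were calibrated once — as the
generator's stated design goal — so that edge-template matching visibly
degrades while blob-template matching succeeds, and then frozen. The
clinical-like cohort takes the ten reported effective diameters
(5.38–14.35 mm, mean 10.43 mm), stations 5 upper / 2 middle / 3 lower, two
cases placed 3 mm from the lung wall, four fractions per case with
uniform ±6 mm sub-voxel setup shifts, all seeded through
`numpy.random.SeedSequence` fan-out.

What passing these experiments shows: the pipeline recovers known rigid
shifts to sub-millimetre accuracy under blur, noise and contrast loss, and
the blob filter's shape selectivity is what rescues matching when tube and
plate clutter defeats raw and edge templates. What it does not show:
robustness to scatter and beam-hardening artifacts, respiratory motion,
tumor shape change between planning and treatment, ground-glass opacity,
or observer variability in reference definitions — none of which the
degradation model emulates.

## Known limitations

- Tumors *attached* to the chest wall (buried rather than adjacent) lose
  the all-negative-eigenvalue blob signature at σ = d/4 once σ exceeds a
  few millimetres; in simulation such cases mismatch grossly. The cohort
  therefore places its near-wall tumors with a 3 mm gap, and attached
  lesions should be treated as outside the validated envelope.
- White additive noise is a crude stand-in for correlated CBCT
  reconstruction noise.
- Translation-only matching cannot represent rotational setup error; large
  rotations would degrade both registration and matching.
- The exhaustive searches are pure NumPy/FFT; a whole-volume run at
  clinical matrix sizes is minutes, not seconds. Experiment sizes here
  (176³ CT, 128³ CBCT FOV) were chosen as comfortable desk-scale defaults
  and are config-exposed.
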
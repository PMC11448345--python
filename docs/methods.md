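# Methods

## Model and assumptions

The package treats collagen detection in MIRSI as supervised per-pixel
spectral classification. The assumptions, in order of consequence:

1. **SHG is ground truth.** SHG intensity is specific to fibrillar
   collagen; its binarized, density-filtered image defines the collagen
   class. Errors in SHG acquisition or binarization propagate into the
   labels and are not modeled.
2. **An affine relates the two modalities.** Landmark registration fits
   scaling, rotation, shear, and translation only. Non-affine distortions
   (barrel distortion, coverslip-induced deformation) are deliberately
   not modeled; the boundary F-score's pixel tolerance absorbs the
   residual misalignment instead.
3. **Spectra are i.i.d. given class after preprocessing.** The forest
   sees single-pixel spectra; spatial context enters only through the
   density filter applied to labels and predictions.
4. **One dominant fiber direction per ROI.** The structure tensor is
   averaged uniformly over each ROI, so orientation and coherency are
   ROI-level summaries, not per-pixel fields.

## Parameters that matter

| Parameter | Default | Units | Why |
| --- | --- | --- | --- |
| amide band / reference band | 1655 / 1760 | cm⁻¹ | amide I peak vs non-absorbing reference; their difference detects protein, hence tissue |
| tissue-rule bounds | 0.1–2.0 (inclusive) | a.u. | below: bare substrate; above: saturated/artifact. Inclusivity is a measure-zero choice made explicit |
| excluded region | 1440–1480 (inclusive) | cm⁻¹ | QCL switching instability; inclusive endpoints turn the 426-band grid into exactly 405 features |
| PCA components | 40 | — | noise-reduction reconstruction rank; basis fit per dataset (training and validation separately, a deliberate, enforced choice) |
| SHG binarization | 5% of max | — | removes dark counts while keeping true signal; per-image override available |
| density filter | ≥ 6 of 8 neighbors | px | the only neighborhood convention in which "six neighbors" is a meaningful strict filter; single-pass, anti-extensive |
| trees / mtry | 50 / ⌈√F⌉ = 21 | — | 500 trees give no perceptible OOB advantage; mtry follows the square-root default |
| probability threshold | strict > 0.5 | — | permissive on purpose (catch collagen pixels, then density-filter); strictness matters because 50-tree vote fractions can hit 0.5 exactly |
| ROI size | 480 px (≈ 650 µm at 1.35 µm/px) | px | granularity of orientation/coherency; phantoms use 64 px at their 128-px scale |
| BF tolerance sweep | 1–8 | px | up to roughly the MIRSI diffraction limit |

## Numerical choices

- **Band lookup** snaps to the nearest axis entry within one band
  spacing; farther requests are axis errors, never silent extrapolation.
- **Orientation convention.** The tensor is expressed with x = column,
  y = upward; the reported angle θ = ½·atan2(−2Jxy, Jyy − Jxx) mod 180°
  is the *fiber* (minimal-variation) direction, counterclockwise from
  +x. The convention is pinned by grating tests (a 30° grating reads
  30°) so both modalities are compared under one convention.
- **BF-score distances** use a Euclidean distance transform of each
  boundary — equivalent to the all-pairs definition and verified against
  it in tests; a 1e-9 slack guards float comparisons at exact integer
  radii. Empty-mask conventions: both empty → 1, exactly one → 0.
- **Angle differences** are wrapped into (−90°, 90°]; Bland–Altman uses
  the wrapped signed difference (predicted − SHG) with sample (n−1) sd.
  Pearson correlation of orientations is reported on raw degrees and,
  alongside, as the Fisher–Lee circular coefficient on doubled angles,
  because raw-degree correlation of axial data is convention-sensitive
  near the 0°/180° identification.
- **Degenerate inputs.** Zero-norm spectra, all-zero SHG, collinear
  landmarks, constant ROIs, and empty classes raise errors naming the
  offense; a constant ROI yields "orientation undefined" rather than an
  arbitrary angle; full-rank PCA requests fall back to identity with a
  warning.
- **Ties.** Equal-importance bands rank lower-wavenumber first; the OOB
  majority vote breaks exact ties toward non-collagen (consistent with
  the strict probability threshold).

## The phantom: what it emulates, what it does not

Phantom spectra are sums of Gaussian bands: shared amide I
(1655 cm⁻¹), amide II (1550 cm⁻¹), amide III (1240 cm⁻¹) over a broad
0.15 a.u. baseline, plus a collagen-only excess centered at 1390 cm⁻¹
(width 22 cm⁻¹) emulating the proline/hydroxyproline wagging region —
the planted informative block that importance analyses must recover.
Fibers are anti-aliased line segments with normally distributed angles;
the per-ROI truth is the circular mean of segment angles. The observed
SHG is the true rendering resampled through a known affine, and the
landmark pairs are exact under it.

Defaults are the package's study conditions: 128×128 px frames, 426
bands, 60 fibers of width 3 px around 40° with 10° jitter, a 2°/3 px
misregistration, and per-band noise σ = 0.075 a.u. — calibrated once so
the default classification task sits near 5% OOB error (hard enough to
exercise thresholds, easy enough to be stable across seeds).

Not emulated: Mie and resonant-Mie scattering, baseline drift,
instrument line-shape effects, non-affine distortion, fiber curvature,
collagen subtypes, and the spatial correlation of real detector noise.
Consequently, passing tests demonstrate the *pipeline's* correctness and
self-consistency — not that real FFPE tissue reaches any particular
accuracy. Headline numbers on real pancreas sections require the
original instrument data.

## Problem sizes

The test suite and acceptance script run entirely on phantom data
generated at call time: 128×128×426 cubes (≈ 14 M voxels) for
end-to-end checks, 64×64 frames for orchestration bookkeeping, 32–64 px
tiles for oracle equivalences, and a few thousand spectra per forest
fit. These sizes were chosen to keep every oracle (all-pairs boundary
distances, double-loop tensors, per-pixel neighbor counts) exhaustively
checkable.

## Design choices that were genuinely open

- **Binarize-then-warp vs warp-then-binarize.** Labels use warped
  intensity re-binarized on the MIRSI grid (avoids interpolating binary
  labels); the pre-binarize order is available via config.
- **Importance.** "Remove the feature and measure the drop" is
  implemented as permutation-on-OOB importance — the accepted ensemble
  equivalent; an exact drop-feature-and-refit variant exists
  (`importance_by_refit`) but costs one training per feature.
- **Forest internals.** Bagging and OOB bookkeeping are implemented in
  the package over scikit-learn CART trees, because per-tree OOB index
  retention (needed for permutation importance and honest OOB error) is
  not exposed by stock ensemble classes. Gini splits, unlimited depth,
  leaf size 1; uniform class prior (the training set is balanced by
  construction).
- **PCA per dataset.** The denoising basis is refit on validation data
  rather than reusing the training basis. This is unusual — a config
  switch exists — but it is the behavior the pipeline enforces and
  documents.
- **Probability maps for morphometrics.** Orientation/coherency are
  computed on the continuous probability map (and on registered SHG
  intensity), not on binarized maps; binarized variants are available.

## Known limitations

- OOB error on phantoms does not transfer to tissue; the phantom's class
  contrast is a single smooth band, far simpler than biochemical
  variability.
- The density filter is deliberately single-pass; iterating it would
  remove more pixels and is not what the pipeline does.
- Raw-degree Pearson of orientations degrades when ROIs straddle the
  0°/180° identification; prefer the circular coefficient reported
  alongside.
- Landmark quality is the user's responsibility; the RMS residual is a
  diagnostic (one grossly wrong pair inflates it several-fold), not an
  automatic rejection rule.
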
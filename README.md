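# rfmirsi

Label-free mapping of fibrillar collagen in tissue sections from
mid-infrared spectral imaging (MIRSI), supervised by second-harmonic
generation (SHG) microscopy.

## The problem

Fibrillar (type I) collagen architecture in the tumor microenvironment —
fiber density, orientation, alignment — carries prognostic information,
and SHG microscopy is the gold standard for imaging it. But SHG is slow
and costly, while QCL-based MIRSI collects whole-slide hyperspectral
absorbance cubes (~950–1800 cm⁻¹ fingerprint region) in minutes. This
package implements a multimodal bridge: SHG images of the *same* tissue
section, co-registered to the MIRSI pixel grid, provide per-pixel
collagen/non-collagen labels for a random-forest classifier that then
predicts collagen maps from MIRSI spectra alone. Predicted maps are
validated against SHG by boundary overlap, fiber orientation, and fiber
alignment.

## The method

**Preprocessing.** A pixel is tissue when its amide I contrast
A(1655 cm⁻¹) − A(1760 cm⁻¹) ∈ [0.1, 2.0] a.u. The unreliable
laser-switching region 1440–1480 cm⁻¹ is excluded (426 → 405 bands on a
2 cm⁻¹ grid); each tissue spectrum is scaled to unit ℓ₂ norm and denoised
by reconstruction from the top 40 principal components (basis fit per
dataset, never shared between training and validation).

**Labels and training.** SHG is registered to the MIRSI grid by a
least-squares landmark affine, binarized at ~5% of its maximum, and
cleaned with a density filter keeping only pixels with ≥ 6 true
8-neighbors ("structural" collagen). A class-balanced spectral training
set feeds a 50-tree bagged CART forest with ⌈√405⌉ = 21 candidate
features per split; accuracy is estimated by out-of-bag (OOB) error and
band importance by permutation of OOB samples.

**Mapping and validation.** The forest's vote fraction gives a collagen
probability per tissue pixel; probability > 0.5 plus the same density
filter yields the final map. Agreement with binarized SHG is scored by
the boundary F-score, BF = 2PR/(P+R), where boundary precision/recall
admit a Euclidean pixel tolerance (swept 1–8 px) that absorbs residual
multimodal registration error. Per-ROI dominant orientation (θ ∈
[0°, 180°)) and coherency ((λ_max − λ_min)/(λ_max + λ_min) ∈ [0, 1]) from
the ROI-averaged structure tensor are compared by Pearson correlation and
Bland–Altman statistics of the wrapped angle differences.

Because no instrument data ship with the package, a phantom module
generates the full study from seeds: two-class Gaussian-band spectra
(shared amide I/II/III bands; a collagen-specific proline-region excess
at 1360–1420 cm⁻¹), fibrous SHG texture with known per-ROI orientation, a
known affine offset between modalities, and consistent landmarks.

## Worked example

```python
from rfmirsi.phantom import PhantomSpec, make_bundle
from rfmirsi.pipeline import (TrainingConfig, ValidationConfig,
                              run_training, run_validation)

train_b = make_bundle(PhantomSpec(seed=11))   # one simulated acquisition
val_b = make_bundle(PhantomSpec(seed=22))     # a held-out acquisition

model, log = run_training(TrainingConfig(
    cube=train_b.cube, shg=train_b.shg_observed,
    landmarks=train_b.landmarks, tissue_id="A", seed=3))
print(log["n_collagen"], log["oob_error"], log["mtry"])
# 2838 0.08967582804792107 21

report = run_validation(ValidationConfig(
    cube=val_b.cube, shg=val_b.shg_observed,
    landmarks=val_b.landmarks, tissue_id="B"), model)
print(report.bf_by_tolerance[4])
# (0.7823101294446502, 0.09349380216696923)
print(report.pearson_orientation, report.pearson_coherency)
# 0.9091807905080769 0.9037103183224156
```

Reading the numbers: training used 2838 collagen and 2838 non-collagen
spectra and the forest's internal cross-validation (OOB) error is ~9%
with the default 21 features per split. On held-out data the mean per-ROI
boundary F-score at a 4-pixel tolerance is 0.78 (±0.09 sd across ROIs),
and per-ROI fiber orientation and coherency from the predicted
probability maps correlate with the registered SHG at Pearson R ≈ 0.91
and 0.90. The same workflow is available from the shell via the `rfmirsi`
command (`simulate`, `train`, `predict`, `validate`).

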
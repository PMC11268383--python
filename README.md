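# hsipath

A toolkit for cancer-margin assessment on microscopic **hyperspectral images
(HSI)** of H&E-stained histology slides. Where an RGB scanner records three
colour channels, a microscopic hyperspectral camera records a full
transmission spectrum per pixel (here 84 bands over 467–721 nm), and that
extra spectral contrast between stains measurably improves tumor/normal
discrimination. `hsipath` implements the full analysis chain for such data:

* **Calibration & tiling** — raw sensor counts are converted to transmittance
  with white-reference and dark-current frames,
  `T(λ) = (I_raw − I_dark) / (I_white − I_dark)`, then whole frames are cut
  into non-overlapping patches and resized (anti-aliased) to the network
  input size.
* **Hyperspectral RandAugment** — each training patch receives 3 transforms
  drawn uniformly from a 13-entry set (identity, rotate, shear X/Y,
  translate X/Y, brightness, contrast, sharpen, spectral noise, spectral
  shifting, band zeroing, NMF stain perturbation), each with a random
  strength from its configured range. The NMF transform decomposes optical
  density `OD = −log10 T` into three nonnegative stain components
  (hematoxylin-, eosin-, hemoglobin-like) and gamma-corrects the abundance
  maps to simulate staining variability.
* **Spectral–spatial transformer** — a factorized-attention classifier in
  which every block applies *spectral attention* (tokens attend across
  wavelength bands at a fixed spatial position) followed by *spatial
  attention* (tokens attend across positions within a band),
  `Attention(Q, K, V) = softmax(QKᵀ/√d) V`, with a class token, positional
  and band embeddings, and a softmax head. Exposed as a scikit-learn-style
  estimator (`fit` / `predict` / `predict_proba`). The network and its
  training loop (SGD, Nesterov momentum 0.9, batch 16, lr 10⁻³ halved every
  5 epochs, best-validation-F1 checkpointing, patient-disjoint splits) are
  implemented in NumPy with an in-package reverse-mode autodiff engine, so
  the whole pipeline runs on one CPU with no deep-learning framework.
* **Margin metrics** — patch predictions are assembled onto the slide's
  patch grid, cleaned by morphological opening, and scored against expert
  masks with the Jaccard index `J(A,B) = |A∩B| / |A∪B|` and the symmetric
  Hausdorff distance `d_H(X,Y) = max{sup_x d(x,Y), sup_y d(X,y)}` in
  millimetres (0.139 mm per grid cell: 250 px tiles at 0.556 µm/px).
* **Attention rollout** — per-layer attention maps are head-averaged,
  identity-mixed and chained by matrix product into per-band spatial
  relevance heatmaps, showing which tissue structures (nuclei, follicular
  colloid) the classifier used at which wavelengths.
* **Synthetic data** — a seeded generator renders H&E-like hypercubes from a
  three-stain Beer–Lambert model `T(λ) = 10^(−Σᵢ cᵢ εᵢ(λ))` with
  carcinoma-like (crowded nuclei) and follicular (ring + colloid lumen)
  scene geometry, plus white/dark reference frames, so every stage is
  testable without any slide data.

## Worked example

```python
import numpy as np
from hsipath import (SceneConfig, make_reference_frames, calibrate_transmittance,
                     rand_augment, SlideMask, margin_assessment)

# 1. synthesize a scene with white/dark references and calibrate it
cfg = SceneConfig(patch_px=56, n_bands=8, seed=0)
frames, truth = make_reference_frames(cfg)
trans = calibrate_transmittance(frames)
print(f"calibration error vs rendered truth: {np.abs(trans.data - truth.data).mean():.4f} (mean abs)")

# 2. apply a seeded 3-transform hyperspectral RandAugment draw
aug = rand_augment(trans, rng=7)
print(f"augmented cube: shape {aug.data.shape}, range [{aug.data.min():.3f}, {aug.data.max():.3f}]")

# 3. score a predicted tumor margin against ground truth on a patch grid
truth_mask = np.zeros((12, 12), dtype=int); truth_mask[3:9, 3:9] = 1
pred_mask = truth_mask.copy(); pred_mask[3:9, 8] = 0; pred_mask[0, 11] = 1
res = margin_assessment(SlideMask(pred_mask), SlideMask(truth_mask), open_radius=1)
print(f"margin: Jaccard {res.jaccard:.3f}, Hausdorff {res.hausdorff_mm:.3f} mm")
```

Output:

```
calibration error vs rendered truth: 0.0091 (mean abs)
augmented cube: shape (56, 56, 8), range [0.000, 1.000]
margin: Jaccard 0.833, Hausdorff 0.139 mm
```

The calibration recovers the rendered transmittance to within the simulated
sensor noise (σ = 0.01); the margin score reflects one eroded tumor column
(Jaccard 30/36) after the opening removed the isolated false-positive cell,
leaving a one-cell (0.139 mm) worst-case boundary error.

Training the classifier:

```python
from hsipath import SpectralSpatialTransformerClassifier, make_dataset

X, y, manifest = make_dataset(150, SceneConfig(patch_px=56, n_bands=8), seed=42)
clf = SpectralSpatialTransformerClassifier(
    image_px=56, patch_px=8, n_bands=8, embed_dim=64, n_heads=4, depth=2,
    epochs=20, random_state=0)
clf.fit(X[:200], y[:200])          # ~3 min on one CPU
clf.predict_proba(X[200:300])      # held-out accuracy ~0.9-1.0
```

A `hsipath` command-line interface wraps the same functions
(`hsipath calibrate`, `tile`, `augment`, `synth`, `train`, `evaluate`,
`margin`, `rollout`); see `hsipath --help`.

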
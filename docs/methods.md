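# Methods

This note documents the models, numerical choices and limitations behind
`hsipath`. It is the package's own account of its science; every number
quoted here is computed by the test suite or by `scripts/acceptance.py`.

## Imaging model and calibration

A microscopic hyperspectral frame is an `H × W × B` cube of per-pixel
spectra with a strictly increasing wavelength axis in nm (the reference
configuration is 84 bands over 467–721 nm). Raw counts are calibrated to
transmittance per pixel and band:

    T(λ) = (I_raw(λ) − I_dark(λ)) / (I_white(λ) − I_dark(λ))

Numerical choices: the denominator is clamped below at `denom_floor`
(default 10⁻⁶) to guard dead pixels where white ≈ dark; negative numerators
(noise below the dark level) are clamped to 0. Transmittance **above 1 is
kept**: tissue can genuinely transmit more than the blank-slide reference
region, and discarding that information would bias bright structures. The
one place this matters downstream is the NMF stain transform, which clamps
T to ≤ 1 before taking logarithms so optical density stays nonnegative.

Whole frames are tiled into non-overlapping square patches in row-major
order with 0-based, half-open pixel intervals; partial tiles at the
bottom/right edge are dropped (a 2000-px frame with 250-px patches tiles
exactly into 64). An optional mean-intensity filter can drop
background-only tiles; no claim is made that any particular threshold
reproduces a specific dataset's patch count. Patch resizing (e.g.
250→224 px) uses anti-aliased bilinear interpolation per band with no
cross-band smoothing, clipped to the input range.

Display RGB uses multi-lobe Gaussian approximations of CIE-1931-style
colour-matching functions sampled at the cube's wavelengths, trapezoid
quadrature, the linear sRGB matrix, and per-channel normalization by the
response to a flat unit spectrum (so spectrally uniform cubes render
neutral grey), followed by the sRGB transfer curve.

## Hyperspectral RandAugment

Each augmented cube receives exactly 3 transforms drawn uniformly **with
replacement** from the 13-entry list (identity; rotate; shear X/Y;
translate X/Y; brightness; contrast; sharpen; spectral noise; spectral
shifting; zeroing; NMF), with strengths uniform in their ranges
(rotate [0, π/2] rad; translate/shear [0, 0.5] of image length; contrast
C ∈ [0, 2]; sharpen [0, 5]; spectral noise [0, 0.5] of max intensity;
shifting A ∈ [0, 2]; zeroing 0–3 bands; brightness [0, 1] of max intensity;
NMF gamma [0.5, 1.5]). All stochastic choices happen at plan-sampling time;
applying a plan is deterministic, which is what makes per-sample child
seeding (and hence batch-order-independent reproducibility) possible.

Per-transform conventions and the decisions behind them:

* **Geometric** maps use bilinear interpolation identically on every band;
  out-of-frame regions are filled with 1.0, the bright slide background in
  transmittance. Rotation is clockwise about the image centre; quarter-turn
  roundoff (cos π/2 ≈ 6·10⁻¹⁷) is snapped so exact grid rotations remain
  exact index permutations.
* **Brightness** is additive — `I′ = I + s·max(I)` — reflecting a strength
  specified as a fraction of the image's maximum intensity; a
  multiplicative reading would duplicate contrast.
* **Contrast** applies `I′ = 1.0157 (C+1)(I−0.5)/(1.0157−C) + 0.5`. The
  printed constant places a pole at C = 1.0157, inside the sampled range;
  the denominator is clamped to ≥ 0.01 to keep the map finite (an extreme
  but bounded contrast stretch), then output is clipped to [0, 1].
  Midpoint I = 0.5 is a fixed point for every C, and C = 0 is the identity.
* **Sharpen** is unsharp masking per band, `I′ = I + s·(I − blur(I))`, with
  a fixed 3×3 mean blur (nearest-edge padding).
* **Spectral noise** draws one offset per band, δ_b ~ U[0, s·max(I)], and
  adds it to all pixels of that band — a band-wise gain/offset error model;
  a single global offset was rejected as it duplicates brightness.
* **Shifting** (spectral tilt): the strength-A ramp is implemented with
  unit gain at 600 nm, `I′(λ) = I(λ)·max(0, 1 + A(λ−600)/(λ_max−λ_min))`.
  A literal multiplicative factor `A·(λ−600 nm)` is not usable (A = 0 would
  blacken the image and the units are unnormalized), so the package defines
  the normalized, anchored form and documents it as its convention.
* **Zeroing** blackens up to three distinct randomly chosen bands exactly
  (a spectral occlusion/cutout analogue); all other bands are bit-identical.
* **NMF stain perturbation** works in optical density, where Beer–Lambert
  absorbances add: `OD = −log10(clip(T, 10⁻⁴, 1))` is factorized as
  `OD ≈ W·S` with rank 3 (hematoxylin-, eosin-, hemoglobin-like),
  multiplicative updates, tolerance 10⁻⁴, at most 200 iterations. Abundance
  columns are scaled to unit maximum, raised to γ, restored, and the cube
  reconstructed as `10^(−W′S)`. γ = 1 returns the plain rank-3
  reconstruction. Initialization is **NNDSVDA** (deterministic,
  SVD-seeded): purely random initialization occasionally converges to a
  local minimum that mixes the two overlapping dye endmembers, which is a
  failure of the optimizer rather than of the model; NNDSVDA removed every
  such failure in our checks while keeping the solver and all other
  settings unchanged. Random init remains available via `NMFConfig.init`.

One documented exception to the "low-end strength = identity" rule: the
NMF transform is not the identity at any γ, because even γ = 1 returns the
rank-3 reconstruction rather than the input. Its correctness is checked
against that reconstruction instead.

## Spectral–spatial transformer

Input cubes are cut into a `g × g` grid of square patches per band
(reference scale: 224 px images, 16 px patches, 14×14 grid; CPU scale:
56 px, 8 px, 7×7). A single linear patch embedding is shared across bands;
a spatial positional embedding is shared across bands; a learnable band
positional embedding is added per band (optional, and disabled when testing
the band-permutation equivariance that factorized attention should have
without it). One learnable class token feeds the classification head.

Each of the `depth` blocks applies, in pre-norm residual form:

1. spectral attention — sequence axis = bands, batched over the spatial
   positions, with its own Q/K/V/O projections;
2. spatial attention — sequence axis = the `g² + 1` tokens of one band
   (class token prepended to every band's sequence; its per-band updates
   are averaged), separate projections;
3. a feed-forward sub-layer with 4× expansion and GELU.

The class token bypasses spectral attention through its residual path,
mirroring standard divided space-time attention practice. Attention scores
are scaled by `1/√d_head` — the standard scaling of this architecture
family — rather than `1/d`; the two differ only by a reparameterization of
Q at initialization, and `1/√d` keeps gradient magnitudes
dimension-independent. Initialization is seeded truncated-normal (±2σ,
σ = 0.02) for weights, zeros for biases, ones for layer-norm gains.
Checkpoints are flat key→array archives (`.npz`) carrying the
configuration; an import hook accepts externally trained weights with
matching keys and shapes (no pretrained weights ship with the package).

The network, backpropagation and optimizer are implemented in NumPy on a
small in-package reverse-mode autodiff engine (`hsipath.autodiff`),
gradient-checked against central finite differences. This keeps the whole
pipeline runnable and exactly reproducible on a single CPU.

## Training protocol

SGD with Nesterov momentum 0.9, batch size 16, initial learning rate 10⁻³
with `lr(e) = lr₀ · 0.5^⌊e/5⌋`, 15 epochs by default, unweighted
cross-entropy (the synthetic classes are balanced; the reference datasets
of this problem family are near-balanced). The checkpoint from the epoch
with the highest validation **weighted F1** is selected; ties keep the
earliest epoch. Augmentation, when enabled, applies only to training
batches, with one child seed per (epoch, sample) so results do not depend
on batch composition. Shuffling is seeded per epoch; end-to-end runs are
bit-reproducible on one CPU.

Inputs are standardized per band with training-set statistics
(`(T − μ_b)/σ_b`) inside the estimator, after augmentation (which operates
on raw [0, 1] transmittance). Transmittance cubes are dominated by the
bright background common mode; standardization removes it, and without it
the discriminative signal reaching the class token is orders of magnitude
too small for plain SGD to amplify within a short schedule.

Splitting is patient-disjoint: patients are grouped by majority label,
shuffled within each label group (seeded), and dealt greedily to the split
with the largest remaining record deficit, so per-split class proportions
track the global ones as closely as the patient block structure allows.

## Evaluation

Patch-level metrics: accuracy; support-weighted F1; sensitivity (recall of
the cancer class); AU-ROC by the rank statistic with tie averaging
(undefined and reported as NaN for single-class label vectors, and
invariant under strictly monotone score transforms). Slide-level margin
assessment assembles patch predictions onto the patch grid (missing cells
default to normal; duplicate cells are an error), applies a morphological
opening whose structuring element is a Chebyshev-metric disk — a
`(2r+1)²` square, radius 1 by default — so solid tumor regions pass
unchanged while isolated speckle is removed, then computes the Jaccard
index (both-empty defined as 1.0: identical masks) and the symmetric
Hausdorff distance between foreground **cell-centre point sets** (not
boundaries), Euclidean, scaled by the cell pitch. The default pitch,
0.139 mm, is 250 px × 0.556 µm/px; grids and pitch are exposed so margins
can be computed at other resolutions.

## Attention rollout

Per layer, head attentions are averaged and convexly mixed with the
identity, `Â = normalize(0.5·mean_heads(A) + 0.5·I)`, which accounts for
residual paths while preserving row-stochasticity (a literal `I + mean`
would make rows sum to 2). The rollout is the ordered matrix product
`Â₁Â₂…Â_depth` (the "⊙" of the rollout literature is matrix
multiplication). Because this model has two attention streams, the package
rolls out the **spatial** stream independently per band and weights each
band's class-token relevance map by the head- and query-averaged attention
mass that band receives in the final **spectral** layer (scaled to unit
maximum); the combined grid × band map is min–max scaled to [0, 1]
(constant maps return zeros with a warning). This combination rule is a
package convention — factorized attention admits several defensible
reductions to a single heatmap.

## Synthetic data generator

The generator emulates the features of stained-tissue microscopy that the
pipeline depends on, and nothing more:

* **Optics** — three-stain Beer–Lambert transmittance
  `T(λ) = 10^(−Σᵢ cᵢ(x,y) εᵢ(λ))`, additive Gaussian sensor noise on T
  (σ = 0.01 default), clipped to [0, 1].
* **Endmembers** — unit-peak Gaussian absorbance bumps at 590 nm
  (hematoxylin-like; the hematein–aluminium complex absorbs near 590 nm,
  width 45 nm), 520 nm (eosin-like, 25 nm) and 575 nm (hemoglobin-like,
  oxyhemoglobin Q band, 12 nm). These widths/peaks keep the sampled curves
  pairwise distinguishable (cosine < 0.9) and the rank-3 factorization
  identifiable even on the coarse 8-band default grid — with much narrower,
  closely spaced bumps the hematoxylin curve becomes numerically a convex
  combination of the other two when sampled at 8 bands, and no solver can
  recover it.
* **Scene geometry** — `cancer` patches: densely packed hematoxylin-rich
  nuclear disks (density 0.25 of area, radii 2–4.5 px) over a smooth eosin
  stroma field, plus 2–4 hemoglobin-rich vessel blobs (carcinoma is
  vascularized, and the third endmember needs spatial support to be
  recoverable); `normal` patches: follicle rings of eosin-dominant
  epithelium around a nearly transparent colloid lumen with a faint
  hemoglobin tint, plus sparse nuclei. The classes therefore differ both
  spatially and in mean hematoxylin abundance — they are separable by
  construction, which is what makes the scaled-down learnability check a
  check of the *pipeline* (embedding, factorized attention, optimizer,
  checkpoint selection) rather than of the problem's difficulty.
* **References** — white frames carry a smooth lamp profile around 4000
  counts, dark frames ≈ 100 counts, and raw frames are
  `dark + (white − dark)·T` plus noise, so calibration recovers the
  rendered T up to noise.
* **Patients** — synthetic patients own blocks of 10 consecutive same-class
  patches, giving patient-stratified splitting real structure to respect.

What the generator does **not** model: optical blur and chromatic
aberration, stain co-localization textures, slide artefacts (folds, dust,
coverslip edges), spatial autofocus errors, camera spectral response
curves, or class-imbalanced cohorts. Passing tests on synthetic data
therefore demonstrate correctness of the algorithms and the trainability of
the architecture at small scale — not clinical-grade performance on real
slides, which requires the private whole-slide datasets and GPU-scale
training that are outside this package's scope.

## Problem sizes used by the acceptance script

Chosen so a full run completes in a few minutes on one CPU: calibration
identities on 64×64×84 cubes; RandAugment contract over 40 seeded runs at
224×224×84 plus one repeated-seed bit-identity check; attention oracle on
20 random instances (≤ 8 tokens, ≤ 4 heads); margin-metric oracles on 100
random 20×20 mask pairs; NMF recovery on five 64×64×8 noiseless scenes;
learnability with the 2-block / 64-dim / 4-head / 8-band / 56-px model
trained 20 epochs on 200 patches and evaluated on 100 held-out patches
(~3 minutes). The reference-scale model configuration (12 blocks, 224 px,
84 bands) is constructible and runs forward passes, but training it is a
GPU-scale exercise and is not part of any test.

## Known limitations

* Training the reference-scale configuration is impractical in NumPy; the
  package targets CPU-scale scientific validation and small studies.
* The rollout combination rule for factorized attention is one defensible
  choice among several; users comparing against other implementations
  should check which reduction they use.
* ENVI support covers BSQ/BIL/BIP uncompressed files with standard headers
  (data types: int16, uint16, float32, float64).
* `split_by_patient` assigns each patient by majority label; patients with
  strongly mixed labels make per-split class proportions coarser.
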
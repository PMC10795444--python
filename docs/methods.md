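# Methods

## Scope and shape

`hnseg` implements a per-organ binary segmentation pipeline for
head-and-neck CT and the uncertainty-guided fine-tuning workflow that
adapts it to a new institution's data. One model instance is trained per
organ-at-risk; all organs share the architecture and differ only in
weights and in the HU window applied during preprocessing. The model is
2-D (slice-based): every geometric operation is in-plane, and volumetric
quantities are obtained by stacking slice predictions.

The core is exposed as a scikit-learn style estimator
(`HNNetSegmenter.fit/predict/predict_proba`, `get_params`/`set_params`,
fitted attributes `model_` and `history_`), with module-level functions
(`train`, `fine_tune`, `predict_probability`, `run_selection_workflow`)
as thin wrappers, so the pieces compose with standard model-selection
tooling.

## Preprocessing

Order of operations: in-plane bilinear resampling to a common pixel
spacing (default 1 mm) → zero-pad / center-crop to a fixed slice size
(default 512) → HU windowing with linear rescaling to [0, 1].

* Resampled size per axis is round-half-up of
  `old_size × old_spacing / target`; nearest-integer rounding minimizes
  the change in physical field of view. Sampling uses the pixel-center
  convention with edge clamping; masks travel through the identical
  geometry with nearest-neighbour interpolation so labels stay in {0, 1}.
* Pad/crop parity: when the margin is odd, the extra pixel is added to
  (or removed from) the high-index side. Any fixed convention works;
  this one is asserted by tests.
* Windows: soft tissue [−140, 210] HU (brain stem, parotid, esophagus,
  optic nerve, optic chiasm, pharyngeal constrictor), skeletal
  [−350, 1250] HU (mandible); presets live in a YAML file keyed by organ.
  Rescaling to [0, 1] matches the sigmoid output head. Interpolation is
  done in HU space (before windowing): windowing is a monotone affine
  clip, so the order only matters where values clip, and resampling raw
  HU avoids committing to a window early.
* Slice thickness is never resampled — the model is 2-D.

## Architecture

U-shaped encoder–decoder. Each stage is a residual block: two rounds of
(convolution → batch norm → ReLU) plus an identity shortcut, with a 1×1
projection when the channel count changes. Convolutions are depthwise
separable (3×3 depthwise + 1×1 pointwise), which is what makes the
network lightweight — the test suite verifies the parameter count is
strictly below the same topology with full 3×3 convolutions. The encoder
downsamples with 2×2 max pooling and doubles channels per stage; the
decoder mirrors it with learned 2×2-stride-2 transposed convolutions.
Each skip connection passes through a CBAM gate (channel attention:
shared two-layer bottleneck MLP over global average- and max-pooled
descriptors, summed, sigmoid; spatial attention: 7×7 convolution over the
stacked channel-wise mean and max maps, sigmoid) before concatenation
into the decoder. The spatial convolution uses replicate padding so that
a spatially uniform input produces a constant attention map. A final 1×1
convolution + sigmoid yields per-pixel probabilities.

Configurable choices where the design was open: stage count (default 4,
tests use 2), base width (default 16), attention on all skips or only the
deepest one (`cbam_scope`), attention removable entirely (`use_cbam`,
shapes unchanged — the gate is a drop-in), ReLU nonlinearity, transposed
convolution upsampling. Defaults are declared, not claimed canonical; no
multi-resolution inputs or deep supervision are implemented.

The network and its training run on `hnseg.nn`, a small NumPy
reverse-mode autodiff and layer library written for this package. All
arithmetic is float64 and every operation's backward pass is checked
against central finite differences in the test suite, so training is
exact gradient descent and bit-reproducible for a fixed seed.

## Training

Loss: soft Dice, `1 − (2·Σ p·t + ε) / (Σ p + Σ t + ε)` with ε = 1e-6 so
empty slices do not produce 0/0; slices with empty masks are kept by
default (a config flag drops them). Optimizer: Adam with β₁ = 0.9,
β₂ = 0.999, initial learning rate 0.01, multiplied by 0.8 every 10 epochs
(both configurable). The decay constant is interpreted as a
learning-rate schedule multiplier: 0.8 would be implausibly large as an
L2 coefficient, and the optimizer's β parameters are stated explicitly,
so Adam plus stepwise LR decay is the consistent reading. Batch size and
epoch count are left to configuration. No data augmentation.

After the last epoch, batch-norm running statistics are replaced by exact
statistics of the training set computed in one extra forward sweep
("precise BN"). With short schedules the exponential running estimates
lag the activations badly enough to corrupt inference-mode predictions;
the recalibration makes inference a deterministic function of the final
weights and the training data.

Fine-tuning continues from the current weights on the union of the base
dataset and the added samples — weights are never re-initialized. A fresh
Adam moment state is created for each fine-tuning phase (moments of a
finished run describe a different loss surface; restarting them is the
conventional choice).

Cross-validation splits at case level only — all slices of a case land in
the same fold — ruling out within-case leakage. Fold assignment is a
seeded permutation, so it is reproducible.

## Uncertainty scoring and candidate selection

Pixel uncertainty `u = min(p, 1 − p)` (≤ 0.5, zero at confident pixels);
edge map `G = |∇²u|` with the discrete 4-neighbour Laplacian (replicate
borders: constant maps give zero everywhere); per-image score
`Un = mean(G)` over all m pixels of the slice; per-case score = mean of
per-slice scores.

Decisions taken where the formulation was ambiguous:

* **Magnitude, not signed Laplacian.** A signed mean across a symmetric
  edge profile cancels toward zero and would destroy the ranking; the
  magnitude is also what an edge map depicts.
* **Mean over all pixels**, not only edge pixels — m is the pixel count
  of the image. Background dilutes every sample's score equally, so the
  ranking is unaffected; an option restricts scoring to a slice subset.
* **Per-case aggregation is the mean of slice scores** (scale-free in
  slice count); max is available by option for catching single bad
  slices.
* **Each round selects floor(0.30 × remaining-pool) samples** (minimum
  1), ties broken by case id. Two rounds on a pool of 30 select 9 then
  6 — exactly half the pool — which is what makes the two-round loop
  equivalent in budget to a single 50% selection while letting the model
  adapt between rounds.

The workflow keeps a full audit trail (`SelectionRound` records: pool,
ranking, selected ids per iteration), so which external sample entered
training at which round is exactly reconstructible.

## Evaluation metrics

Dice, Jaccard, Precision, Recall over voxel counts; Jaccard ≤ Dice,
Dice = 2J/(1+J), and Dice = harmonic mean of Precision and Recall are
used as algebraic cross-checks in tests. Conventions the formulas leave
open: both masks empty → all rates 1 (perfect agreement); exactly one
empty → Dice = Jaccard = 0 and the undefined rate reported as 0.
Predictions are binarized at probability 0.5 (configurable) before
metric computation. Metrics are volumetric (slices stacked per case),
not per-slice averages.

Hausdorff distance: classic symmetric maximum (100th percentile, not
95%) between boundary voxel sets, with Euclidean distances in mm using
the voxel spacing. Boundaries are foreground voxels removed by one step
of face-connected binary erosion (border treated as background). Empty
masks make the distance undefined; it is reported as missing, never 0.

## Synthetic phantoms

Each phantom case is a random ellipsoid "organ" (HU ~ Normal(organ_hu,
noise_sd) inside, Normal(background_hu, noise_sd) outside) with its exact
mask. Defaults: 64×64 slices at 1 mm in-plane, 3 mm thickness, organ
60 HU, background −20 HU, noise SD 20 HU — a soft-tissue-like contrast
that is clearly separable but not noise-free. The domain shift adds
+80 HU, +10 HU noise SD, and scales organs by 1.25, making the shifted
background as bright as the local organ after soft-tissue windowing — a
deliberately hard shift that collapses the un-adapted model and gives the
fine-tuning workflow something real to fix.

The corruption generator turns a perfect mask into a graded probability
map: Gaussian blur of the mask controls boundary uncertainty (and, once
the 0.5 level set moves, Dice), and a random pixel fraction is pushed 80%
of the way toward 0.5, raising uncertainty without crossing the
threshold. The two knobs induce a known quality ranking used to test that
Un tracks segmentation error (Spearman ≥ 0.8 across a corruption
gradient).

What the phantoms do **not** emulate: anatomy (organs are convex
ellipsoids), CT physics (no beam hardening, streaks, or HU calibration
error), inter-observer label noise, multiple organs per scan, and the
class imbalance of very small structures. Passing phantom tests therefore
demonstrates that the algorithms are implemented correctly and that the
workflow behaves as designed under a controlled domain shift — not that
clinical-grade accuracy is attained on real CT.

## Scaled-down study sizes

The bundled studies (`hnseg.experiments`) use: 5 local cases × 4 slices
(20 training slices), a 30-case candidate pool, 10 held-out test cases,
network depth 2 with 8 base channels at 64×64, 20 training epochs and 8
fine-tuning epochs per round, batch size 8. These sizes keep one full
study around a minute on a single CPU core while preserving the workflow
arithmetic (9 + 6 selected of 30 = 50%).

## Known limitations

* 2-D slice model: no through-plane context; volumetric consistency
  relies on the data, not the model.
* The NumPy backend is single-threaded BLAS-bound; it is meant for
  method study and testing, not 512×512 clinical-scale training.
* Uncertainty is derived from the sigmoid output of a single model;
  ensemble or MC-dropout estimators are out of scope.
* The candidate pool must be labeled — selection chooses which labels to
  use, it does not generate pseudo-labels.
* DICOM series and RT-STRUCT contours are not read; volumes and masks
  arrive as NIfTI.
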
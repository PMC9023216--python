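# Methods

## Task and data model

The segmentation target is the intracranial aneurysm — a small saccular
bulge on a cerebral artery — in TOF-MRA volumes where both the vasculature
and the lesion are bright and the lesion occupies a minute voxel fraction.
Volumes are held internally as `(depth, height, width)` = (Z, Y, X) arrays
with positive per-axis voxel spacing in mm; NIfTI axis order is mapped to
this convention at the disk boundary and restored on write, and intensities
are never rescaled at I/O time.  All geometry (distance maps, surface
metrics, phantom rasterisation) lives in voxel-index space scaled by
spacing; orientation matrices beyond spacing are carried as opaque metadata
only.  Labels are strictly binary, foreground = aneurysm; vessels belong to
the background class.

## Block preprocessing

A `BlockSpec` defines a block shape (default 64×128×128) and stride.  Block
origins are the per-axis grid {0, s, 2s, …}; when the grid misses the far
edge, a final origin is clamped to `dim − block`, so blocks never contain
invented padding and every voxel is covered.  With stride = block and
divisible dims this is an exact tiling.  Overlapping mode defaults to
stride = block/2 per axis, guaranteeing that interior structure appears
away from a block border in at least one block.  Training pairs whose label
block has no positive voxel are culled; inference partitions
non-overlapping and without culling so the whole volume is predicted.
Reassembly averages all block predictions covering a voxel, which is
order-independent and reduces to pure placement for exact tilings;
probabilities are binarised at 0.5 afterwards.

## Network

The one-two-one network chains three encoder-decoder structures of depths
1, 2, 1.  Building blocks:

- *entry stage*: two 3×3×3 convolutions (ReLU); output = conv1 + conv2
  (element-wise residual).
- *down stage*: stride-2 3×3×3 convolution doubling channels (ReLU), three
  3×3×3 convolutions; output = downsampled features + third convolution.
- *up stage*: stride-2 transposed 3×3×3 convolution halving channels
  (ReLU), channel concatenation with the same-resolution encoder output
  ("stack" skip), three convolutions of which the first restores the
  nominal width; output = upsampled features + third convolution.

With base width 16 the nine stages run at in-plane sizes
128, 64, 128, 64, 32, 64, 128, 64, 128 with widths 16, 32, 16, 32, 64, 32,
16, 32, 16; the depth axis halves isotropically with the in-plane axes.
The output head is a 3×3×3 convolution to one channel plus a sigmoid.  The
network is fully convolutional and accepts any input whose spatial dims are
multiples of 4.

Design choices where the published description is open:

- "Stack" is read as channel concatenation and "adding" as element-wise
  residual addition; after concatenation the first decoder convolution
  reduces the doubled width back to the level's nominal width.
- Down/up-sampling use stride 2 along all three axes — the only reading
  under which a symmetric decoder restores a 64×128×128 input.
- No normalisation layers: the design uses only convolution, ReLU and the
  sigmoid head.
- Dropout (default rate 0.5) is applied after the deepest stage of each of
  the three structures, training only, so it cannot erase shallow skip
  information.
- Weights are He-normal (std = sqrt(2 / fan-in)), biases zero, drawn from a
  seeded generator so builds are reproducible.  The head bias initialises
  to −2 so the sigmoid starts near the background rate of a severely
  imbalanced mask; this only shifts the starting point of training.

The engine underneath is a small numpy reverse-mode autodiff: convolutions
are evaluated as 27 offset-shifted BLAS contractions (no materialised
im2col buffer), the transposed convolution is the exact adjoint of the
stride-2 convolution, and gradients are verified against finite differences
in the test suite.  Arithmetic is float32; the optimiser is Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at the reference learning rate 0.001.

## Losses

All losses are voxel means, so the ensemble weight λ is scale-free across
block sizes.

- **Dice**: `1 − (2Σpg + w)/(Σp² + Σg² + w)`; the smoothing coefficient
  `w = 1e-5` guards the empty/empty case.  Value in [0, 1).
- **Cross-entropy**: two-class one-hot expansion (binary cross-entropy)
  with probabilities clipped to [1e-7, 1 − 1e-7]; a literal
  foreground-only variant (−mean(g log p)) is available behind
  `ce_single_term`, but is degenerate for a sigmoid output, which is why
  the expansion is the default.
- **Boundary**: `mean(φ_G · p)` with φ_G the signed Euclidean distance to
  the nearest opposite-class voxel (voxel-centre to voxel-centre, negative
  inside the mask, computed by `scipy.ndimage.distance_transform_edt`).
  Units are voxels by default; `phi_physical` switches to mm.  Single-class
  masks have no boundary, so φ_G ≡ 0 and the term vanishes — culled
  training blocks always contain foreground, but robustness is required.
- **Ensembles**: `dice`, `dice + λ·ce`, `dice + λ·boundary`, λ = 1 by
  default.  Optionally λ ramps as `λ · min(1, epoch · rate)` with
  rate = 0.01/epoch, the rebalancing schedule of the boundary-loss
  formulation: applied at full strength from the first step the boundary
  term is minimised by the empty prediction long before the overlap term
  finds the foreground, and training collapses.  The ramp is off by
  default and enabled in the learning demonstrations.

Gradients of all losses with respect to p are closed-form and tested
against central differences at 1e-4 relative tolerance.

## Evaluation metrics

Surface points are centres of foreground voxels with a 6-connected
background neighbour (volume faces count as background), scaled by spacing.
ASD is the symmetric mean nearest-neighbour distance
`(Σ_a min_b‖a−b‖ + Σ_b min_a‖b−a‖)/(|S_A|+|S_B|)`; HD takes the maximum of
the two directed distances, each at a configurable quantile of the
per-point nearest-neighbour distances (linear interpolation; 1.0 gives the
classical maximum, evaluation uses 0.95).  DSC is computed on binarised
masks; two empty masks score 1.0 with a warning.  "Accuracy" follows the
literal target-coverage definition `|P∩G|/|G|` (foreground recall), which
differs from voxel-wise accuracy; an empty prediction yields DSC 0,
accuracy 0 and infinite surface distances in a report.  The RSS statistic
fits an ordinary least-squares line to (epoch, loss) and returns the sum of
squared residuals; for i.i.d. noise of variance σ² about a line its
expectation is σ²(n−2), which the tests exercise.

Nearest-neighbour queries use a k-d tree; every metric is checked exactly
against O(N²) brute-force oracles on enumerated small masks and point sets
(all masks of 2×2×3 and 1×3×3 blocks, all non-empty mask pairs of 1×2×3
blocks, plus seeded samples of 2×3×3 masks and 2×2×3 pairs — sizes chosen
so the exhaustive checks stay within a routine test run).

## Synthetic phantoms

`generate_case` emulates the statistical structure of the clinical task,
not MR physics: smooth random-walk centrelines rasterised as capsule chains
(sphere-swept segments, exact point-to-segment distances in mm) form bright
vessels on a dim background; spherical aneurysms of 3-7 mm diameter attach
to vessel walls at the same brightness; i.i.d. Gaussian noise is added.
Only aneurysm voxels are labelled.  The default configuration is a full
acquisition-size volume, 128×512×512 voxels at (0.8, 0.5, 0.5) mm, six
vessels of 0.8-1.6 mm radius and three aneurysms — under which the labelled
fraction is ~3e-5 and non-overlapping 64×128×128 partitioning leaves >75%
of blocks lesion-free, the imbalance regime the method is designed for.
A `toy_config` (48×96×96, isotropic 0.5 mm, two vessels, two large
well-separated aneurysms, high contrast, low noise) supports CPU-scale
training demonstrations.

What passing tests on phantoms do **not** show: performance on real TOF-MRA
(no flow artifacts, Rician noise, skull/soft-tissue background, anatomical
vessel trees, or realistic lesion morphology), nor the published
clinical-data scores, which required private datasets and multi-day GPU
training.  The phantom results demonstrate that the implementation is
correct and that the pipeline can learn the discrimination it claims to
address.

## Problem sizes and numerical choices

Tests and the acceptance script run on one CPU at reduced scale, a
deliberate configuration of this package: base width 4 (instead of 16),
32×64×64 blocks, 3 training phantoms, 10 epochs with batch size 2 and the
λ-ramped Dice + boundary ensemble.  Under these conditions the held-out
phantom DSC is ~0.7 (seed-dependent; the dice-only baseline is similar),
versus 0 for the empty predictor — a learnability property, not a
reproduction of the clinical-data scores.  Per-volume min-max normalisation
to [0, 1] is applied at training/inference time (I/O stays lossless).
Prediction thresholds at 0.5.  The sigmoid input is clipped to ±60 to avoid
overflow at saturation; probabilities are clipped only inside the
cross-entropy.  Determinism: phantom generation, weight initialisation,
batch shuffling and dropout all draw from seeded generators, and two runs
with identical configuration produce identical loss curves and files.

## Known limitations

- The numpy engine is single-threaded BLAS-bound; full-width training at
  64×128×128 is out of scope on CPU (full-width single forward passes run
  in minutes).
- Training uses no validation split, early stopping, or augmentation, per
  the reference protocol.
- Toy-scale training is high-variance: with tens of gradient steps the
  held-out DSC moves substantially across seeds.
- The "accuracy" metric is recall of the target and can exceed what
  voxel-wise accuracy intuition suggests; it is reported per case.
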
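# otoseg

Automated segmentation of intracranial aneurysms in time-of-flight MR
angiography (TOF-MRA), built around a *one-two-one* fully convolutional
network: three chained encoder-decoder structures of depths 1, 2 and 1.
The package is aimed at researchers who want the complete method — block
preprocessing, network, loss ensembles, surface-distance evaluation — as
tested, reusable Python, runnable end to end on synthetic vascular phantoms
without any clinical data.

Aneurysms are tiny, bright, saccular bulges on bright tubular vessels; in a
full 512×512×128 scan the lesion occupies a vanishing fraction of the
voxels.  The pipeline addresses this imbalance at three levels:

- **Block preprocessing.**  Volumes are cut into 64×128×128 sub-blocks
  (non-overlapping for inference; overlapping, stride = half block, for
  training), and training blocks whose label contains no foreground are
  discarded (*disequilibrium culling*).
- **The network.**  All stages use 3×3×3 SAME convolutions with ReLU;
  stride-2 convolutions halve resolution and double width (16→32→64),
  transposed convolutions invert this; within a stage the stage input is
  added residually to the last convolution, and across resolutions the
  same-resolution encoder output is concatenated onto the decoder.  A
  1-channel convolution with a sigmoid yields per-voxel foreground
  probabilities.  The whole network is implemented in numpy, including
  backpropagation and Adam.
- **Loss ensembles.**  Dice loss
  `L_dice = 1 − (2Σ p_i g_i + w) / (Σ p_i² + Σ g_i² + w)`
  optionally combined with binary cross-entropy or with the boundary loss
  `L_B = mean(φ_G · p)`, where φ_G is the signed Euclidean distance map of
  the true mask (negative inside).  The boundary weight can ramp up
  linearly per epoch, which prevents the collapse-to-empty failure of a
  full-strength boundary term.

Evaluation metrics: Dice similarity `DSC = 2|P∩G|/(|P|+|G|)`, symmetric
average surface distance (ASD, mm), Hausdorff distance at the 95% quantile
(HD95, mm), target-coverage accuracy `|P∩G|/|G|`, and the residual sum of
squares (RSS) of a training-loss curve about its least-squares line as a
volatility statistic.

## Worked example

```python
import dataclasses
from otoseg import (BlockSpec, LossConfig, ModelConfig, TrainConfig,
                    evaluate, generate_dataset, predict, read_mask,
                    read_volume, toy_config, train)

# four small high-contrast phantoms: 3 train, 1 held out
manifest = generate_dataset(toy_config(0), 4, "scratch/demo", train_fraction=0.75)

model, record = train(
    manifest,
    ModelConfig(base_channels=4, seed=0),
    TrainConfig(epochs=10, block_shape=(32, 64, 64), seed=0,
                loss=LossConfig(mode="dice+boundary", aux_ramp=True)),
)
print([round(c["dice"], 3) for c in record.epoch_components])

entry = manifest.subset("test")[0]
prob = predict(read_volume(entry.image), model, BlockSpec((32, 64, 64)))
print(evaluate(prob, read_mask(entry.label)))
```

On one CPU this takes a few minutes and prints the per-epoch Dice component
falling as the network learns,

```
[0.877, 0.773, 0.7, 0.651, 0.619, 0.613, 0.599, 0.592, 0.562, 0.573]
```

followed by the held-out scores

```
MetricsReport(dsc=0.7396..., asd=0.5368..., hd95=1.1180..., accuracy=0.5921...)
```

i.e. the trained network overlaps the true aneurysm mask with Dice 0.74 and
its surface stays within ~1 mm of the true surface — far better than the
empty prediction (Dice 0) or a coin-flip mask (Dice ≈ 0.01) on the same
phantom.  Numbers move with the seeds; at this tiny scale run-to-run spread
is large.

The same workflow is available from the shell:

```
otoseg simulate --out scratch/demo --cases 4 --toy --seed 0
otoseg train --manifest scratch/demo/manifest.csv --out scratch/run \
       --loss dice+boundary --base-channels 4 --block-shape 32 64 64 --epochs 10
otoseg predict --image scratch/demo/case003_image.nii.gz \
       --checkpoint scratch/run/model.npz --out scratch/prob.nii.gz \
       --block-shape 32 64 64
otoseg evaluate --pred scratch/prob.nii.gz --label scratch/demo/case003_label.nii.gz
otoseg montage --block scratch/prob.nii.gz --out scratch/montage.png
```

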
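"""End-to-end orchestration: preprocess -> train -> predict -> evaluate.

Training follows the reference protocol: volumes are min-max normalised,
partitioned into blocks (overlapping by default for training, to correlate
structure across block borders), lesion-free blocks are culled, and the
network is optimised with Adam at learning rate 0.001 under the configured
loss ensemble, logging one mean loss row per epoch.  Inference partitions
without overlap or culling, forward-passes every block, and stitches the
probabilities back by averaging; evaluation binarises at 0.5 and computes
DSC, ASD, HD95 and target-coverage accuracy.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import losses as L
from . import metrics as M
from .blocking import BlockSpec, BlockSet, cull_empty, partition, reassemble
from .io_volumes import DatasetManifest, LabelMask, Volume, read_mask, read_volume
from .nn import Adam
from .oto_model import ModelConfig, OTONet, build_model, save_checkpoint

__all__ = ["TrainConfig", "RunRecord", "normalize", "train", "predict", "evaluate", "montage"]


@dataclass
class TrainConfig:
    """Training hyperparameters (reference defaults: lr 0.001, dropout 0.5,
    batch size 2; epochs are experiment-specific)."""

    epochs: int = 10
    learning_rate: float = 0.001
    batch_size: int = 2
    loss: L.LossConfig = field(default_factory=L.LossConfig)
    seed: int = 0
    optimizer: str = "adam"
    block_shape: tuple[int, int, int] = (64, 128, 128)
    overlap_training: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("need learning_rate > 0, batch_size >= 1, epochs >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class RunRecord:
    """Per-epoch mean losses plus the artefact paths of one training run."""

    epoch_losses: list[float]
    epoch_components: list[dict[str, float]]
    checkpoint_path: str | None
    config: dict

    @property
    def loss_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.epoch_losses) + 1),
                "total": self.epoch_losses,
                "dice": [c["dice"] for c in self.epoch_components],
                "aux": [c["aux"] for c in self.epoch_components],
            }
        )


def normalize(data: np.ndarray) -> np.ndarray:
    """Per-volume min-max scaling to [0, 1]; constant volumes map to 0."""
    data = np.asarray(data, dtype=np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def _training_blocks(
    manifest: DatasetManifest, cfg: TrainConfig
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    spec = (
        BlockSpec.overlapping(cfg.block_shape)
        if cfg.overlap_training
        else BlockSpec(cfg.block_shape)
    )
    imgs: list[np.ndarray] = []
    labs: list[np.ndarray] = []
    for entry in manifest.subset("train"):
        vol = read_volume(entry.image)
        lab = read_mask(entry.label)
        data = normalize(vol.data) if cfg.normalize else vol.data.astype(np.float32)
        bi, bl = cull_empty(
            partition(Volume(data, vol.spacing, vol.source_id), spec),
            partition(lab, spec),
        )
        imgs += bi.blocks
        labs += [b.astype(np.float32) for b in bl.blocks]
    return imgs, labs


def train(
    manifest: DatasetManifest,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    out_dir: str | os.PathLike | None = None,
) -> tuple[OTONet, RunRecord]:
    """Train on the culled training blocks of a manifest.

    Returns the fitted model and a RunRecord with one mean loss per epoch;
    when ``out_dir`` is given, also writes ``loss_curve.csv``, a checkpoint
    and a JSON config snapshot there.
    """
    if not manifest.subset("train"):
        raise ValueError("manifest contains no training cases")
    imgs, labs = _training_blocks(manifest, train_cfg)
    if not imgs:
        raise ValueError(
            "no training blocks survived disequilibrium culling; the labels carry "
            "no foreground — add lesions or use smaller blocks"
        )
    model = build_model(model_cfg)
    opt = Adam(model.parameters, lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    phis = [
        L.signed_distance(lb) if train_cfg.loss.mode == "dice+boundary" else None
        for lb in labs
    ]

    epoch_losses: list[float] = []
    epoch_components: list[dict[str, float]] = []
    n = len(imgs)
    for _epoch in range(train_cfg.epochs):
        lcfg = dataclasses.replace(
            train_cfg.loss,
            aux_weight=train_cfg.loss.effective_aux_weight(_epoch, train_cfg.epochs),
            aux_ramp=False,
        )
        order = rng.permutation(n)
        tot = dice_sum = aux_sum = 0.0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            x = np.stack([imgs[i] for i in idx])[:, None]
            g = np.stack([labs[i] for i in idx])[:, None]
            opt.zero_grad()
            p_t = model.forward_tensor(x, training=True)
            p = p_t.data.astype(np.float64)
            phi = (
                np.stack([phis[i] for i in idx])[:, None]
                if lcfg.mode == "dice+boundary"
                else None
            )
            loss, comps = L.ensemble_loss(p, g, lcfg, phi)
            p_t.backward(L.ensemble_loss_grad(p, g, lcfg, phi))
            opt.step()
            k = len(idx)
            tot += loss * k
            dice_sum += comps["dice"] * k
            aux_sum += comps["aux"] * k
        epoch_losses.append(tot / n)
        epoch_components.append({"dice": dice_sum / n, "aux": aux_sum / n})

    ckpt = None
    snapshot = {"model": asdict(model_cfg), "train": asdict(train_cfg)}
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        ckpt = os.path.join(out_dir, "model.npz")
        save_checkpoint(model, ckpt)
        record = RunRecord(epoch_losses, epoch_components, ckpt, snapshot)
        record.loss_frame.to_csv(os.path.join(out_dir, "loss_curve.csv"), index=False)
        with open(os.path.join(out_dir, "config.json"), "w") as fh:
            json.dump(snapshot, fh, indent=2, default=str)
        return model, record
    return model, RunRecord(epoch_losses, epoch_components, ckpt, snapshot)


def predict(
    volume: Volume,
    model: OTONet,
    block_spec: BlockSpec | None = None,
    do_normalize: bool = True,
) -> Volume:
    """Block-wise inference: non-overlapping partition (no culling), forward
    pass per block, mean-stitched probability volume of the input's shape."""
    if block_spec is None:
        block_spec = BlockSpec()
    if any(b > d for b, d in zip(block_spec.block_shape, volume.shape)):
        raise ValueError(
            f"volume shape {volume.shape} smaller than block {block_spec.block_shape}"
        )
    data = normalize(volume.data) if do_normalize else volume.data.astype(np.float32)
    blocks = partition(Volume(data, volume.spacing, volume.source_id), block_spec)
    preds = BlockSet(
        [model.predict_block(b).astype(np.float32) for b in blocks.blocks],
        blocks.origins,
        blocks.source_shape,
        blocks.spec,
        blocks.spacing,
        volume.source_id + "-prob",
    )
    return reassemble(preds)


def evaluate(
    pred_prob: Volume, g: LabelMask, threshold: float = 0.5
) -> M.MetricsReport:
    """Binarise a probability volume and score it against the ground truth."""
    if pred_prob.shape != g.shape:
        raise ValueError(f"shape mismatch: {pred_prob.shape} vs {g.shape}")
    p_bin = (pred_prob.data > threshold).astype(np.uint8)
    return M.compute_report(p_bin, g.data, g.spacing)


def montage(block: np.ndarray) -> np.ndarray:
    """Tile the depth slices of a block into a square 2D grid, row-major.

    A 64x128x128 block becomes an 8x8 grid of 128x128 slices, i.e. a
    1024x1024 image; generally the slice count must be a perfect square.
    """
    block = np.asarray(block)
    if block.ndim != 3:
        raise ValueError("montage expects a 3D (depth, height, width) block")
    d, h, w = block.shape
    side = int(round(np.sqrt(d)))
    if side * side != d:
        valid = [k * k for k in range(1, 17)]
        raise ValueError(
            f"slice count {d} is not a perfect square; valid depths include {valid}"
        )
    out = np.empty((side * h, side * w), dtype=block.dtype)
    for k in range(d):
        r, c = divmod(k, side)
        out[r * h : (r + 1) * h, c * w : (c + 1) * w] = block[k]
    return out
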
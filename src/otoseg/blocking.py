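"""Block preprocessing: partition, disequilibrium culling, reassembly.

Full TOF-MRA volumes do not fit accelerator memory, so volumes are cut into
fixed-size (Z, Y, X) blocks — by default 64x128x128 — either edge-to-edge
(non-overlapping) or with a stride smaller than the block (overlapping), and
block-wise predictions are stitched back by averaging.  Training pairs whose
label block contains no foreground are discarded ("disequilibrium culling")
to counter the extreme aneurysm/background imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_volumes import Volume

__all__ = ["BlockSpec", "BlockSet", "partition", "cull_empty", "reassemble"]

DEFAULT_BLOCK_SHAPE = (64, 128, 128)


@dataclass(frozen=True)
class BlockSpec:
    """Geometry of a block decomposition.

    ``stride == block_shape`` tiles without overlap; any smaller stride
    overlaps neighbouring blocks.  :meth:`overlapping` gives the half-block
    stride default.
    """

    block_shape: tuple[int, int, int] = DEFAULT_BLOCK_SHAPE
    stride: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        bs = tuple(int(b) for b in self.block_shape)
        st = bs if self.stride is None else tuple(int(s) for s in self.stride)
        if len(bs) != 3 or any(b < 1 for b in bs):
            raise ValueError(f"block_shape must be 3 positive ints, got {self.block_shape}")
        if len(st) != 3 or any(not (1 <= s <= b) for s, b in zip(st, bs)):
            raise ValueError(f"stride {st} must satisfy 1 <= stride <= block_shape {bs}")
        object.__setattr__(self, "block_shape", bs)
        object.__setattr__(self, "stride", st)

    @classmethod
    def overlapping(cls, block_shape: tuple[int, int, int] = DEFAULT_BLOCK_SHAPE) -> "BlockSpec":
        """Half-block stride along every axis."""
        return cls(block_shape, tuple(max(1, b // 2) for b in block_shape))


@dataclass
class BlockSet:
    """An ordered set of equally sized sub-volumes with their voxel origins."""

    blocks: list[np.ndarray]
    origins: list[tuple[int, int, int]]
    source_shape: tuple[int, int, int]
    spec: BlockSpec
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.blocks) != len(self.origins):
            raise ValueError("blocks and origins differ in length")
        if len(set(self.origins)) != len(self.origins):
            raise ValueError("duplicate block origins")
        bs = self.spec.block_shape
        for o in self.origins:
            if any(c < 0 or c + b > d for c, b, d in zip(o, bs, self.source_shape)):
                raise ValueError(f"block at origin {o} exceeds source shape {self.source_shape}")

    def __len__(self) -> int:
        return len(self.blocks)


def _axis_origins(dim: int, block: int, stride: int) -> list[int]:
    """Grid {0, s, 2s, ...} clamped so the last block ends at the volume edge."""
    origins = list(range(0, dim - block + 1, stride))
    if origins[-1] != dim - block:
        origins.append(dim - block)
    return origins


def partition(v: Volume | np.ndarray, spec: BlockSpec) -> BlockSet:
    """Cut a volume into blocks on the stride grid.

    Origins are the per-axis grid {0, s, 2s, ...}; when the grid does not land
    exactly on the far edge a final origin is clamped to ``dim - block`` so no
    voxel is left uncovered and no padding is ever invented.  With
    ``stride == block_shape`` and evenly divisible dims this is an exact
    tiling covering every voxel exactly once.
    """
    if isinstance(v, Volume):
        data, spacing, source_id = v.data, v.spacing, v.source_id
    else:
        data, spacing, source_id = np.asarray(v), (1.0, 1.0, 1.0), ""
    if any(b > d for b, d in zip(spec.block_shape, data.shape)):
        raise ValueError(
            f"block shape {spec.block_shape} exceeds volume shape {data.shape} on some axis"
        )
    grids = [
        _axis_origins(d, b, s)
        for d, b, s in zip(data.shape, spec.block_shape, spec.stride)
    ]
    bz, by, bx = spec.block_shape
    origins = [(z, y, x) for z in grids[0] for y in grids[1] for x in grids[2]]
    blocks = [np.ascontiguousarray(data[z : z + bz, y : y + by, x : x + bx]) for z, y, x in origins]
    return BlockSet(blocks, origins, data.shape, spec, spacing, source_id)


def cull_empty(images: BlockSet, labels: BlockSet) -> tuple[BlockSet, BlockSet]:
    """Drop paired blocks whose label block has no voxel > 0.

    Retains exactly the pairs with at least one positive label voxel, in the
    original order; the image and label sets stay aligned.
    """
    if images.origins != labels.origins or images.spec != labels.spec:
        raise ValueError("image and label block sets are not paired (origins/spec differ)")
    keep = [i for i, lb in enumerate(labels.blocks) if lb.max() > 0]

    def _take(bs: BlockSet) -> BlockSet:
        return BlockSet(
            [bs.blocks[i] for i in keep],
            [bs.origins[i] for i in keep],
            bs.source_shape,
            bs.spec,
            bs.spacing,
            bs.source_id,
        )

    return _take(images), _take(labels)


def reassemble(preds: BlockSet) -> Volume:
    """Stitch blocks back into a full volume.

    Each voxel receives the arithmetic mean of every block prediction that
    covers it, so non-overlapping tilings are pure placement and overlapping
    predictions are averaged order-independently.
    """
    acc = np.zeros(preds.source_shape, dtype=np.float64)
    cnt = np.zeros(preds.source_shape, dtype=np.int32)
    bz, by, bx = preds.spec.block_shape
    for (z, y, x), blk in zip(preds.origins, preds.blocks):
        acc[z : z + bz, y : y + by, x : x + bx] += blk
        cnt[z : z + bz, y : y + by, x : x + bx] += 1
    if (cnt == 0).any():
        raise ValueError("block origins do not cover the full source volume")
    out = acc / cnt
    in_dtype = preds.blocks[0].dtype if preds.blocks else np.dtype(np.float64)
    if np.issubdtype(in_dtype, np.integer) and np.array_equal(out, np.rint(out)):
        out = out.astype(in_dtype)  # exact integer placement/averaging round-trips
    elif in_dtype == np.float32:
        out = out.astype(np.float32)
    return Volume(out, preds.spacing, preds.source_id or "reassembled")
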
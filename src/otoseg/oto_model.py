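"""The one-two-one (OTO) fully convolutional segmentation network.

Three complete encode-decode structures are chained: the first and third
descend one resolution level, the middle one descends two.  Every stage uses
3x3x3 SAME convolutions with ReLU; downsampling is a stride-2 convolution
doubling the channel count, upsampling a stride-2 transposed convolution
halving it.  Within a stage the stage input is added residually to the last
convolution output; across resolutions the same-resolution encoder output is
concatenated ("stacked") onto the upsampled decoder features.  The output
head is a single-channel convolution with a sigmoid, so each voxel gets a
foreground probability.

With base width 16 the nine stages run, in order, at in-plane sizes
128, 64, 128, 64, 32, 64, 128, 64, 128 with channel widths
16, 32, 16, 32, 64, 32, 16, 32, 16 for a 64x128x128 input block.

The network is fully convolutional: any input whose spatial dims are
divisible by 4 (two halvings) works, which is what makes CPU-scale testing
on small blocks possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = ["ModelConfig", "OTONet", "build_model", "shape_trace", "count_parameters",
           "save_checkpoint", "load_checkpoint"]

#: (stage name, resolution level 0/1/2, channel multiple of base) in forward order
STAGE_PLAN = [
    ("OI-Stage1", 0, 1),
    ("OI-Stage2", 1, 2),
    ("T-Stage1", 0, 1),
    ("T-Stage2", 1, 2),
    ("T-Stage3", 2, 4),
    ("T-Stage4", 1, 2),
    ("T-Stage5", 0, 1),
    ("OII-Stage1", 1, 2),
    ("OII-Stage2", 0, 1),
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    base_channels is the full-resolution width (16 in the reference design;
    widths double per downsampling: 16 -> 32 -> 64).  dropout_rate applies
    after the deepest stage of each encode-decode structure, training only.
    head_bias initialises the output convolution bias; a negative value
    starts the sigmoid near the background probability, which suits the
    extreme foreground/background imbalance of aneurysm masks.
    """

    in_channels: int = 1
    base_channels: int = 16
    kernel: tuple[int, int, int] = (3, 3, 3)
    dropout_rate: float = 0.5
    padding_mode: str = "SAME"
    seed: int = 0
    head_bias: float = -2.0

    def __post_init__(self) -> None:
        if self.base_channels < 1 or self.in_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if len(set(self.kernel)) != 1 or self.kernel[0] % 2 != 1 or self.kernel[0] < 1:
            raise ValueError(f"kernel must be cubic with odd positive size, got {self.kernel}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.padding_mode != "SAME":
            raise ValueError("only SAME padding is supported")


class _Entry:
    """Stage at full resolution: two convs; output = conv1 + conv2 (residual)."""

    def __init__(self, in_ch: int, ch: int, k: int, rng):
        self.c1 = nn.Conv3d(in_ch, ch, k, rng=rng)
        self.c2 = nn.Conv3d(ch, ch, k, rng=rng)

    def __call__(self, x):
        a = nn.relu(self.c1(x))
        b = nn.relu(self.c2(a))
        return nn.add(a, b)

    @property
    def parameters(self):
        return self.c1.parameters + self.c2.parameters


class _Down:
    """Stride-2 conv doubling channels, then three convs; residual add of the
    downsampled features and the third conv output."""

    def __init__(self, in_ch: int, k: int, rng):
        out_ch = 2 * in_ch
        self.down = nn.Conv3d(in_ch, out_ch, k, stride=2, rng=rng)
        self.convs = [nn.Conv3d(out_ch, out_ch, k, rng=rng) for _ in range(3)]

    def __call__(self, x):
        d = nn.relu(self.down(x))
        h = d
        for c in self.convs:
            h = nn.relu(c(h))
        return nn.add(d, h)

    @property
    def parameters(self):
        ps = self.down.parameters
        for c in self.convs:
            ps += c.parameters
        return ps


class _Up:
    """Stride-2 transposed conv halving channels, concat with the
    same-resolution skip, three convs (the first restoring the nominal
    width), residual add of the upsampled features."""

    def __init__(self, in_ch: int, k: int, rng):
        out_ch = in_ch // 2
        self.up = nn.ConvTranspose3d(in_ch, out_ch, k, rng=rng)
        self.convs = [
            nn.Conv3d(2 * out_ch, out_ch, k, rng=rng),
            nn.Conv3d(out_ch, out_ch, k, rng=rng),
            nn.Conv3d(out_ch, out_ch, k, rng=rng),
        ]

    def __call__(self, x, skip):
        u = nn.relu(self.up(x))
        h = nn.concat(u, skip)
        for c in self.convs:
            h = nn.relu(c(h))
        return nn.add(u, h)

    @property
    def parameters(self):
        ps = self.up.parameters
        for c in self.convs:
            ps += c.parameters
        return ps


class OTONet:
    """One-two-one encoder-decoder; see module docstring for the layout."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        C, k = cfg.base_channels, cfg.kernel[0]
        # structure O^I: entry, one down, one up
        self.entry = _Entry(cfg.in_channels, C, k, rng)       # L1
        self.o1_down = _Down(C, k, rng)                        # L2
        self.o1_up = _Up(2 * C, k, rng)                        # L3
        # structure T: two downs, two ups
        self.t_down1 = _Down(C, k, rng)                        # L4
        self.t_down2 = _Down(2 * C, k, rng)                    # L5
        self.t_up1 = _Up(4 * C, k, rng)                        # L6
        self.t_up2 = _Up(2 * C, k, rng)                        # L7
        # structure O^II: one down, one up
        self.o2_down = _Down(C, k, rng)                        # L8
        self.o2_up = _Up(2 * C, k, rng)                        # L9
        self.head = nn.Conv3d(C, 1, k, rng=rng, bias_init=cfg.head_bias)
        self._drop_rng = np.random.default_rng(cfg.seed + 1)

    # -- construction introspection ------------------------------------
    @property
    def parameters(self) -> list[nn.Tensor]:
        blocks = [self.entry, self.o1_down, self.o1_up, self.t_down1, self.t_down2,
                  self.t_up1, self.t_up2, self.o2_down, self.o2_up]
        ps: list[nn.Tensor] = []
        for blk in blocks:
            ps += blk.parameters
        return ps + self.head.parameters

    # -- forward --------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 5 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected input (N, {self.cfg.in_channels}, D, H, W), got {x.shape}"
            )
        if any(d % 4 != 0 or d < 4 for d in x.shape[2:]):
            raise ValueError(
                f"spatial dims must be positive multiples of 4 (two halvings), got {x.shape[2:]}"
            )

    def forward_tensor(self, x: np.ndarray, training: bool = False) -> nn.Tensor:
        """Forward pass returning the probability Tensor (for backprop)."""
        self._check_input(np.asarray(x))
        rate = self.cfg.dropout_rate

        def drop(t):
            return nn.dropout(t, rate, self._drop_rng, training)

        t_in = nn.Tensor(x, requires_grad=False)
        l1 = self.entry(t_in)
        l2 = drop(self.o1_down(l1))
        l3 = self.o1_up(l2, l1)
        l4 = self.t_down1(l3)
        l5 = drop(self.t_down2(l4))
        l6 = self.t_up1(l5, l4)
        l7 = self.t_up2(l6, l3)
        l8 = drop(self.o2_down(l7))
        l9 = self.o2_up(l8, l7)
        return nn.sigmoid(self.head(l9))

    def predict_block(self, block: np.ndarray) -> np.ndarray:
        """Probabilities for one (D, H, W) block, inference mode."""
        x = np.asarray(block, dtype=np.float32)[None, None]
        return self.forward_tensor(x, training=False).data[0, 0]

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward_tensor(x, training=training).data


def build_model(cfg: ModelConfig) -> OTONet:
    """Construct a trainable network from its configuration."""
    return OTONet(cfg)


def shape_trace(
    model: OTONet, input_shape: tuple[int, int, int]
) -> list[tuple[str, tuple[int, int, int], int]]:
    """Stage-by-stage (name, spatial shape, channels) for a given input size.

    Raises before any computation if a spatial dim is not divisible by 4.
    """
    if len(input_shape) != 3 or any(d % 4 != 0 or d < 4 for d in input_shape):
        raise ValueError(
            f"input spatial dims must be positive multiples of 4, got {input_shape}"
        )
    C = model.cfg.base_channels
    rows = []
    for name, level, mult in STAGE_PLAN:
        sp = tuple(d // (2**level) for d in input_shape)
        rows.append((name, sp, mult * C))
    return rows


def count_parameters(model: OTONet) -> int:
    """Total trainable scalar count; deterministic for a fixed config."""
    return int(sum(p.data.size for p in model.parameters))


def save_checkpoint(model: OTONet, path) -> None:
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters)}
    cfg = model.cfg
    meta = np.array(
        [cfg.in_channels, cfg.base_channels, cfg.kernel[0], cfg.seed], dtype=np.int64
    )
    np.savez_compressed(
        path, __meta=meta, __dropout=np.float64(cfg.dropout_rate),
        __head_bias=np.float64(cfg.head_bias), **arrays
    )


def load_checkpoint(path) -> OTONet:
    with np.load(path) as z:
        meta = z["__meta"]
        cfg = ModelConfig(
            in_channels=int(meta[0]), base_channels=int(meta[1]),
            kernel=(int(meta[2]),) * 3, dropout_rate=float(z["__dropout"]),
            seed=int(meta[3]), head_bias=float(z["__head_bias"]),
        )
        model = OTONet(cfg)
        for i, p in enumerate(model.parameters):
            arr = z[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint parameter {i} shape mismatch")
            p.data = arr.astype(np.float32)
    return model
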
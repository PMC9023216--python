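"""Training objectives: Dice, cross-entropy, boundary loss, and ensembles.

Aneurysm foreground occupies a minute fraction of each block, so a plain
voxel-wise objective is dominated by background.  Dice loss measures overlap
directly; the two ensembles add either binary cross-entropy or the boundary
loss — the prediction integrated against the signed Euclidean distance map
phi_G of the true mask, which penalises probability mass in proportion to its
distance outside the true boundary (and rewards mass inside it).

All reductions are voxel means so the ensemble weight is scale-free across
block sizes.  Every loss returns a float and has a closed-form gradient with
respect to the probability block, checked against finite differences in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "LossConfig",
    "dice_loss",
    "dice_loss_grad",
    "ce_loss",
    "ce_loss_grad",
    "signed_distance",
    "boundary_loss",
    "boundary_loss_grad",
    "ensemble_loss",
    "ensemble_loss_grad",
]

_CE_EPS = 1e-7
MODES = ("dice", "dice+ce", "dice+boundary")


@dataclass(frozen=True)
class LossConfig:
    """Loss-ensemble composition.

    mode
        "dice", "dice+ce", or "dice+boundary".
    smooth_w
        Dice smoothing coefficient w (guards the 0/0 empty-mask case).
    aux_weight
        Weight lambda on the auxiliary term; the ensemble is
        L_dice + lambda * L_aux.
    phi_physical
        Compute phi_G in mm (spacing-scaled) instead of voxel units.
    ce_single_term
        Use the literal foreground-only cross-entropy -mean(g log p) instead
        of the two-class expansion.
    aux_ramp
        Ramp the auxiliary weight linearly: at epoch e (1-based) the
        effective weight is ``aux_weight * min(1, e * aux_ramp_rate)``.  This
        follows the rebalancing schedule of the boundary-loss formulation,
        which grows the boundary weight by a small fixed fraction per epoch:
        applied at full strength from the first step, the boundary term can
        collapse the prediction to empty before the overlap term finds the
        foreground.
    aux_ramp_rate
        Fraction of the full auxiliary weight added per epoch when ramping.
    """

    mode: str = "dice"
    smooth_w: float = 1e-5
    aux_weight: float = 1.0
    phi_physical: bool = False
    ce_single_term: bool = False
    aux_ramp: bool = False
    aux_ramp_rate: float = 0.01

    def effective_aux_weight(self, epoch: int, n_epochs: int) -> float:
        """Auxiliary weight for a 0-based epoch index under the optional ramp."""
        if not self.aux_ramp:
            return self.aux_weight
        return self.aux_weight * min(1.0, (epoch + 1) * self.aux_ramp_rate)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown loss mode {self.mode!r}; expected one of {MODES}")
        if not self.smooth_w > 0:
            raise ValueError("smooth_w must be > 0")
        if self.aux_weight < 0:
            raise ValueError("aux_weight must be >= 0")


def _check_pair(p: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"prediction shape {p.shape} != label shape {g.shape}")
    return p, g


def dice_loss(p: np.ndarray, g: np.ndarray, w: float = 1e-5) -> float:
    """1 - (2*sum(p*g) + w) / (sum(p^2) + sum(g^2) + w)."""
    p, g = _check_pair(p, g)
    if not w > 0:
        raise ValueError("smoothing coefficient w must be > 0")
    num = 2.0 * float((p * g).sum()) + w
    den = float((p * p).sum()) + float((g * g).sum()) + w
    return 1.0 - num / den


def dice_loss_grad(p: np.ndarray, g: np.ndarray, w: float = 1e-5) -> np.ndarray:
    p, g = _check_pair(p, g)
    num = 2.0 * (p * g).sum() + w
    den = (p * p).sum() + (g * g).sum() + w
    return (-2.0 * g * den + 2.0 * p * num) / den**2


def ce_loss(p: np.ndarray, g: np.ndarray, single_term: bool = False) -> float:
    """Voxel-mean binary cross-entropy, probabilities clipped away from {0,1}.

    ``single_term`` gives the literal foreground-only form -mean(g log p).
    """
    p, g = _check_pair(p, g)
    pc = np.clip(p, _CE_EPS, 1.0 - _CE_EPS)
    if single_term:
        return float(-(g * np.log(pc)).mean())
    return float(-(g * np.log(pc) + (1.0 - g) * np.log(1.0 - pc)).mean())


def ce_loss_grad(p: np.ndarray, g: np.ndarray, single_term: bool = False) -> np.ndarray:
    p, g = _check_pair(p, g)
    pc = np.clip(p, _CE_EPS, 1.0 - _CE_EPS)
    inside = (p > _CE_EPS) & (p < 1.0 - _CE_EPS)  # clipped voxels have zero slope
    if single_term:
        grad = -g / pc
    else:
        grad = -g / pc + (1.0 - g) / (1.0 - pc)
    return np.where(inside, grad, 0.0) / p.size


def signed_distance(
    g: np.ndarray, spacing: tuple[float, float, float] | None = None
) -> np.ndarray:
    """Signed Euclidean distance map phi_G of a binary mask.

    phi(q) = +distance to the nearest foreground voxel on background voxels,
    -distance to the nearest background voxel on foreground voxels
    (voxel-centre to voxel-centre), so sign(phi) = 1 - 2g.  ``spacing`` scales
    to physical mm.  Degenerate single-class masks have no boundary and yield
    phi identically 0, making the boundary loss vanish for them.
    """
    g = np.asarray(g)
    if not np.isin(g, (0, 1)).all():
        raise ValueError("signed_distance expects a binary {0,1} mask")
    fg = g.astype(bool)
    if not fg.any() or fg.all():
        return np.zeros(g.shape, dtype=np.float64)
    dist_to_fg = ndimage.distance_transform_edt(~fg, sampling=spacing)
    dist_to_bg = ndimage.distance_transform_edt(fg, sampling=spacing)
    return np.where(fg, -dist_to_bg, dist_to_fg).astype(np.float64)


def boundary_loss(p: np.ndarray, phi: np.ndarray) -> float:
    """Voxel mean of phi_G * p; negative when mass sits inside the true mask."""
    p, phi = _check_pair(p, phi)
    return float((phi * p).mean())


def boundary_loss_grad(p: np.ndarray, phi: np.ndarray) -> np.ndarray:
    p, phi = _check_pair(p, phi)
    return phi / p.size


def _aux(p, g, cfg: LossConfig, phi):
    if cfg.mode == "dice+ce":
        return ce_loss(p, g, cfg.ce_single_term)
    if cfg.mode == "dice+boundary":
        if phi is None:
            phi = signed_distance(g)
        return boundary_loss(p, phi)
    return 0.0


def ensemble_loss(
    p: np.ndarray,
    g: np.ndarray,
    cfg: LossConfig,
    phi: np.ndarray | None = None,
) -> tuple[float, dict[str, float]]:
    """Total loss and its components.

    For "dice+boundary" a precomputed ``phi`` (cached per label block) avoids
    recomputing the distance transform each step; otherwise it is derived
    from ``g`` on the fly.
    """
    d = dice_loss(p, g, cfg.smooth_w)
    a = _aux(p, g, cfg, phi)
    return d + cfg.aux_weight * a, {"dice": d, "aux": a}


def ensemble_loss_grad(
    p: np.ndarray,
    g: np.ndarray,
    cfg: LossConfig,
    phi: np.ndarray | None = None,
) -> np.ndarray:
    grad = dice_loss_grad(p, g, cfg.smooth_w)
    if cfg.aux_weight > 0:
        if cfg.mode == "dice+ce":
            grad = grad + cfg.aux_weight * ce_loss_grad(p, g, cfg.ce_single_term)
        elif cfg.mode == "dice+boundary":
            if phi is None:
                phi = signed_distance(g)
            grad = grad + cfg.aux_weight * boundary_loss_grad(p, phi)
    return grad
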
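"""Segmentation evaluation: DSC, surface distances, accuracy, loss-curve RSS.

Surface-distance metrics operate on the surface point sets of the two masks:
the centres (in mm, spacing-scaled) of foreground voxels having at least one
6-connected background neighbour, with the volume faces counted as
background.  ASD is the symmetric mean nearest-neighbour distance; HD is the
maximum of the two directed distances, each taken at a configurable quantile
(default the classical maximum; evaluation uses the 95% quantile to damp
outlier surface points).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "MetricsReport",
    "dsc",
    "surface_points",
    "asd",
    "hd",
    "accuracy",
    "rss_of_loss_curve",
    "compute_report",
]


@dataclass(frozen=True)
class MetricsReport:
    dsc: float
    asd: float       # mm
    hd95: float      # mm
    accuracy: float

    def __post_init__(self) -> None:
        if not (np.isnan(self.dsc) or 0.0 <= self.dsc <= 1.0):
            raise ValueError(f"dsc out of [0,1]: {self.dsc}")
        for name in ("asd", "hd95"):
            v = getattr(self, name)
            if not (np.isnan(v) or v >= 0.0):
                raise ValueError(f"{name} must be >= 0, got {v}")


def _binary_pair(p: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p)
    g = np.asarray(g)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    for name, m in (("prediction", p), ("label", g)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    return p.astype(bool), g.astype(bool)


def dsc(p_bin: np.ndarray, g: np.ndarray) -> float:
    """Dice similarity 2|P∩G| / (|P|+|G|); two empty masks score 1.0."""
    p, g = _binary_pair(p_bin, g)
    np_, ng = int(p.sum()), int(g.sum())
    if np_ == 0 and ng == 0:
        warnings.warn("dsc of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((p & g).sum()) / (np_ + ng)


def surface_points(
    m: np.ndarray, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> np.ndarray:
    """(K, 3) array of surface-voxel centres in mm, ordered (z, y, x).

    A surface voxel is a foreground voxel with a 6-connected background
    neighbour; voxels on the volume faces always qualify.
    """
    m = np.asarray(m).astype(bool)
    if m.ndim != 3:
        raise ValueError("mask must be 3D")
    if not m.any():
        raise ValueError("cannot extract surface points from an empty mask")
    padded = np.pad(m, 1, constant_values=False)
    interior = np.ones_like(m)
    for ax in range(3):
        for shift in (1, -1):
            interior &= np.roll(padded, shift, axis=ax)[1:-1, 1:-1, 1:-1]
    surf = m & ~interior
    idx = np.argwhere(surf).astype(np.float64)
    return idx * np.asarray(spacing, dtype=np.float64)


def _directed_nn(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return cKDTree(b).query(a)[0]


def _check_points(s: np.ndarray, name: str) -> np.ndarray:
    s = np.asarray(s, dtype=np.float64)
    if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] == 0:
        raise ValueError(f"{name} must be a non-empty (K, 3) point set, got shape {s.shape}")
    return s


def asd(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric average surface distance:
    (sum_a min_b ||a-b|| + sum_b min_a ||b-a||) / (|A|+|B|)."""
    A = _check_points(A, "A")
    B = _check_points(B, "B")
    return float((_directed_nn(A, B).sum() + _directed_nn(B, A).sum()) / (len(A) + len(B)))


def hd(C: np.ndarray, D: np.ndarray, quantile: float = 0.95) -> float:
    """Quantile Hausdorff distance max(h_q(C,D), h_q(D,C)).

    h_q is the ``quantile``-th percentile (linear interpolation) of the
    per-point nearest-neighbour distances; quantile 1.0 is the classical
    Hausdorff maximum.
    """
    C = _check_points(C, "C")
    D = _check_points(D, "D")
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    return float(
        max(
            np.quantile(_directed_nn(C, D), quantile),
            np.quantile(_directed_nn(D, C), quantile),
        )
    )


def accuracy(p_bin: np.ndarray, g: np.ndarray) -> float:
    """|P∩G| / |G| — the fraction of the target covered by the prediction.

    This is the literal "correct prediction area over target area" reading,
    i.e. foreground recall; it is not voxel-wise accuracy.
    """
    p, g = _binary_pair(p_bin, g)
    ng = int(g.sum())
    if ng == 0:
        raise ValueError("accuracy undefined for an empty target mask")
    return int((p & g).sum()) / ng


def rss_of_loss_curve(losses: np.ndarray) -> float:
    """Residual sum of squares about the OLS line fit to (epoch index, loss).

    A volatility statistic for training curves: lower means the curve hugs
    its linear trend more tightly.
    """
    y = np.asarray(losses, dtype=np.float64).ravel()
    if y.size < 3:
        raise ValueError("need at least 3 loss values to assess curve stability")
    x = np.arange(y.size, dtype=np.float64)
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    return float((resid**2).sum())


def compute_report(
    p_bin: np.ndarray,
    g: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    hd_quantile: float = 0.95,
) -> MetricsReport:
    """All metrics for one binarized prediction against its ground truth.

    An empty prediction against a non-empty truth has no surface, so the
    surface distances are reported as +inf (worst case) rather than raising.
    """
    p, g = _binary_pair(p_bin, g)
    d = dsc(p, g)
    acc = accuracy(p, g)
    if p.any():
        sp, sg = surface_points(p, spacing), surface_points(g, spacing)
        a, h = asd(sp, sg), hd(sp, sg, hd_quantile)
    else:
        a = h = float("inf")
    return MetricsReport(dsc=d, asd=a, hd95=h, accuracy=acc)
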
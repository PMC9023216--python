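"""Synthetic TOF-MRA-like phantoms: bright tubular vessels, tiny bright
saccular aneurysms, severe class imbalance.

The generator emulates the statistical structure the segmentation task
assumes rather than MR physics: on a dim noisy background it rasterises a
few smooth random-walk vessels as capsule chains (sphere-swept segments) at
a bright flow-like intensity, then attaches spherical aneurysm bulges to
vessel walls at the same brightness.  Only the aneurysm voxels are labelled
foreground — the vasculature belongs to the background class, exactly as in
the clinical task — so the labelled fraction of a default volume is tiny and
most training blocks carry no lesion at all.

Geometry is computed in millimetres using the anisotropic voxel spacing, so
configured radii/diameters are physical sizes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .io_volumes import DatasetManifest, LabelMask, ManifestEntry, Volume, save_manifest, write_volume

__all__ = ["PhantomConfig", "PhantomCase", "generate_case", "generate_dataset", "toy_config"]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one phantom volume.

    Defaults mirror a full-size clinical TOF-MRA acquisition: a 512x512
    in-plane, 128-slice volume (z, y, x order) with sub-millimetre in-plane
    spacing, a handful of vessels ~1 mm in radius, and a few aneurysms in
    the clinically common 3-7 mm diameter class.  Intensities are arbitrary
    units in [0, 1] before additive Gaussian noise.
    """

    volume_shape: tuple[int, int, int] = (128, 512, 512)
    spacing: tuple[float, float, float] = (0.8, 0.5, 0.5)  # mm (z, y, x)
    n_vessels: int = 6
    vessel_radius_mm: tuple[float, float] = (0.8, 1.6)
    n_aneurysms: int = 3
    aneurysm_diameter_mm: tuple[float, float] = (3.0, 7.0)
    vessel_intensity: float = 0.8
    background_intensity: float = 0.1
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.volume_shape) < 8:
            raise ValueError("volume_shape axes must be >= 8")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for name in ("vessel_radius_mm", "aneurysm_diameter_mm"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be an increasing positive range")
        if self.n_vessels < 1 and self.n_aneurysms > 0:
            raise ValueError("aneurysms need at least one vessel to attach to")


@dataclass
class PhantomCase:
    image: Volume
    label: LabelMask
    truth_meta: list[tuple[tuple[float, float, float], float]]  # (centre voxel zyx, diameter mm)


def toy_config(seed: int = 0) -> PhantomConfig:
    """A small high-contrast configuration for CPU-scale training demos:
    a 48x96x96 volume (a handful of overlapping 32x64x64 blocks), isotropic
    0.5 mm voxels, thin vessels, two large well-separated aneurysms, low
    noise."""
    return PhantomConfig(
        volume_shape=(48, 96, 96),
        spacing=(0.5, 0.5, 0.5),
        n_vessels=2,
        vessel_radius_mm=(0.5, 0.9),
        n_aneurysms=2,
        aneurysm_diameter_mm=(4.0, 7.0),
        vessel_intensity=0.9,
        background_intensity=0.1,
        noise_sigma=0.04,
        seed=seed,
    )


def _mm_coords(shape, spacing):
    """Per-axis voxel-centre coordinates in mm."""
    return [np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)]


def _paint_ball(mask: np.ndarray, centre_mm, radius_mm, spacing) -> None:
    """Set voxels whose centre lies within radius_mm of centre_mm (in mm)."""
    shape = mask.shape
    lo = [max(0, int((c - radius_mm) / s) - 1) for c, s in zip(centre_mm, spacing)]
    hi = [min(n, int((c + radius_mm) / s) + 2) for c, s, n in zip(centre_mm, spacing, shape)]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    ax = [np.arange(l, h) * s - c for l, h, s, c in zip(lo, hi, spacing, centre_mm)]
    d2 = ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub |= d2 <= radius_mm**2


def _paint_capsule(mask: np.ndarray, a_mm, b_mm, radius_mm, spacing) -> None:
    """Rasterise a sphere-swept segment from a_mm to b_mm (coordinates in mm)."""
    a = np.asarray(a_mm)
    b = np.asarray(b_mm)
    lo_mm = np.minimum(a, b) - radius_mm
    hi_mm = np.maximum(a, b) + radius_mm
    lo = [max(0, int(l / s) - 1) for l, s in zip(lo_mm, spacing)]
    hi = [min(n, int(h / s) + 2) for h, s, n in zip(hi_mm, spacing, mask.shape)]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    ax = [np.arange(l, h) * s for l, h, s in zip(lo, hi, spacing)]
    pz, py, px = np.meshgrid(*ax, indexing="ij")
    p = np.stack([pz, py, px], axis=-1)
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    d2 = ((p - closest) ** 2).sum(axis=-1)
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub |= d2 <= radius_mm**2


def _random_walk_vessel(rng, shape_mm, radius_mm, step_mm=None, max_steps=400):
    """Smooth random-walk centreline: unit direction perturbed each step.

    The step length adapts to small volumes so a walk always fits."""
    if step_mm is None:
        step_mm = float(np.clip(min(shape_mm) / 8.0, 0.5, 4.0))
    margin = radius_mm + step_mm
    start = np.array([rng.uniform(margin, e - margin) for e in shape_mm])
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pts = [start.copy()]
    p = start
    for _ in range(max_steps):
        d = d + 0.35 * rng.normal(size=3)
        d /= np.linalg.norm(d)
        q = p + step_mm * d
        if ((q < radius_mm) | (q > shape_mm - radius_mm)).any():
            break
        pts.append(q.copy())
        p = q
    return np.array(pts)


def generate_case(cfg: PhantomConfig, seed: int | None = None) -> PhantomCase:
    """One paired image/label volume, deterministic given the seed."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    shape = cfg.volume_shape
    spacing = np.asarray(cfg.spacing, dtype=np.float64)
    shape_mm = (np.asarray(shape) - 1) * spacing

    vessel_mask = np.zeros(shape, dtype=bool)
    centrelines: list[tuple[np.ndarray, float]] = []
    for _ in range(cfg.n_vessels):
        r = rng.uniform(*cfg.vessel_radius_mm)
        line = _random_walk_vessel(rng, shape_mm, r)
        if len(line) < 2:
            continue
        for a, b in zip(line[:-1], line[1:]):
            _paint_capsule(vessel_mask, a, b, r, spacing)
        centrelines.append((line, r))
    if cfg.n_aneurysms > 0 and not centrelines:
        raise RuntimeError("no vessel could be placed; enlarge the volume")

    label = np.zeros(shape, dtype=bool)
    truth_meta: list[tuple[tuple[float, float, float], float]] = []
    placed: list[tuple[np.ndarray, float]] = []  # (centre mm, radius mm)
    for _ in range(cfg.n_aneurysms):
        ok = False
        for _attempt in range(200):
            diam = rng.uniform(*cfg.aneurysm_diameter_mm)
            r_an = diam / 2.0
            line, r_v = centrelines[rng.integers(len(centrelines))]
            pt = line[rng.integers(len(line))]
            # random direction perpendicular-ish to nothing in particular:
            # offset so the sphere sits on the vessel wall (centre at wall + r_an)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            centre = pt + (r_v + 0.8 * r_an) * u
            pad = r_an + 1.0  # keep a 1 mm clearance from the volume faces
            if ((centre < pad) | (centre > shape_mm - pad)).any():
                continue
            # keep aneurysms disjoint so connected components equal the count
            if any(np.linalg.norm(centre - c) < r_an + r0 + 2.0 for c, r0 in placed):
                continue
            _paint_ball(label, centre, r_an, spacing)
            placed.append((centre, r_an))
            truth_meta.append((tuple(centre / spacing), diam))
            ok = True
            break
        if not ok:
            raise RuntimeError(
                "could not place an aneurysm on a vessel wall after bounded retries"
            )

    bright = vessel_mask | label
    image = np.full(shape, cfg.background_intensity, dtype=np.float32)
    image[bright] = cfg.vessel_intensity
    image += rng.normal(0.0, cfg.noise_sigma, shape).astype(np.float32)

    sid = f"phantom-{seed}"
    return PhantomCase(
        image=Volume(image, cfg.spacing, sid),
        label=LabelMask(label.astype(np.uint8), cfg.spacing, sid + "-label"),
        truth_meta=truth_meta,
    )


def generate_dataset(
    cfg: PhantomConfig,
    n_cases: int,
    out_dir: str | os.PathLike,
    train_fraction: float = 0.6,
) -> DatasetManifest:
    """Write ``n_cases`` image/label NIfTI pairs plus a train/test manifest.

    Per-case seeds derive deterministically from ``cfg.seed``, so the same
    configuration always regenerates byte-identical files.  The first
    ``ceil(train_fraction * n_cases)`` cases form the training split.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    n_train = int(np.ceil(train_fraction * n_cases))
    entries = []
    for i in range(n_cases):
        case_seed = int(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(i,)).generate_state(1)[0]
            % (2**31)
        )
        case = generate_case(cfg, seed=case_seed)
        img_path = os.path.join(out_dir, f"case{i:03d}_image.nii.gz")
        lab_path = os.path.join(out_dir, f"case{i:03d}_label.nii.gz")
        write_volume(case.image, img_path)
        write_volume(case.label, lab_path)
        entries.append(
            ManifestEntry(img_path, lab_path, "train" if i < n_train else "test")
        )
    manifest = DatasetManifest(entries)
    save_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    return manifest
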
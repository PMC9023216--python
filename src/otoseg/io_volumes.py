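"""NIfTI volume/mask I/O and dataset manifests.

Arrays are held internally in (depth, height, width) = (Z, Y, X) order, the
order in which the network consumes 64x128x128 blocks.  NIfTI stores data
(X, Y, Z)-fastest, so axes are transposed at the disk boundary; voxel spacing
is reordered accordingly.  Intensities are never rescaled at I/O time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "LabelMask",
    "ManifestEntry",
    "DatasetManifest",
    "read_volume",
    "read_mask",
    "write_volume",
    "load_manifest",
    "save_manifest",
]


@dataclass
class Volume:
    """A 3D scalar image.

    Parameters
    ----------
    data
        3D array indexed (z, y, x).
    spacing
        Millimetres per voxel along (z, y, x); all entries positive.
    source_id
        Free-form provenance identifier.
    affine
        Optional NIfTI affine carried through as opaque metadata.  All
        geometry in this package lives in voxel-index space scaled by
        ``spacing``; the affine is only used to round-trip files faithfully.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    source_id: str = ""
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"volume data must be 3D with positive extents, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelMask(Volume):
    """A binary mask aligned to a :class:`Volume`; foreground = aneurysm."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"label mask values must be exactly 0/1, found {vals[:10]}")


@dataclass(frozen=True)
class ManifestEntry:
    image: str
    label: str | None
    split: str  # "train" or "test"


@dataclass
class DatasetManifest:
    """Pairs image files with label files and a train/test split tag."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.split not in ("train", "test"):
                raise ValueError(f"split must be train/test, got {e.split!r} for {e.image}")
            if e.split == "train" and not e.label:
                raise ValueError(f"train entry {e.image!r} has no label path")
            for p in (e.image, e.label):
                if p:
                    if p in seen:
                        raise ValueError(f"duplicate path in manifest: {p!r}")
                    seen.add(p)

    def subset(self, split: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == split]

    def __len__(self) -> int:
        return len(self.entries)


def _check_readable(path: str | os.PathLike) -> str:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    return path


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI file into the internal (z, y, x) convention.

    The header's voxel spacing is carried over; intensities are returned
    exactly as stored (no rescale beyond NIfTI's own scl_slope/inter, which
    nibabel applies only when set).
    """
    path = _check_readable(path)
    try:
        img = nib.load(path)
        raw = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several types for bad headers
        raise ValueError(f"malformed NIfTI file {path!r}: {exc}") from exc
    if raw.ndim != 3:
        raise ValueError(f"{path!r}: expected a 3D image, got {raw.ndim} axes")
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    return Volume(
        data=np.ascontiguousarray(raw.transpose(2, 1, 0)),
        spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        source_id=os.path.basename(path),
        affine=np.asarray(img.affine),
    )


def read_mask(path: str | os.PathLike) -> LabelMask:
    v = read_volume(path)
    return LabelMask(np.rint(v.data).astype(np.uint8), v.spacing, v.source_id, v.affine)


def write_volume(v: Volume, path: str | os.PathLike) -> None:
    """Write a Volume (or LabelMask) as NIfTI, restoring (x, y, z) disk order."""
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    sz, sy, sx = v.spacing
    affine = v.affine if v.affine is not None else np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(v.data.transpose(2, 1, 0)), affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, path)


def load_manifest(path: str | os.PathLike) -> DatasetManifest:
    """Load a CSV manifest with columns image,label,split (label may be empty)."""
    path = _check_readable(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"image", "split"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path!r} lacks required columns {sorted(missing)}")
    if "label" not in df.columns:
        df["label"] = ""
    entries = [
        ManifestEntry(r.image, r.label or None, r.split) for r in df.itertuples(index=False)
    ]
    return DatasetManifest(entries)


def save_manifest(m: DatasetManifest, path: str | os.PathLike) -> None:
    pd.DataFrame(
        [(e.image, e.label or "", e.split) for e in m.entries],
        columns=["image", "label", "split"],
    ).to_csv(path, index=False)
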
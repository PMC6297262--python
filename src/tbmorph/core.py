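"""Core image containers and NIfTI-1 I/O.

The unit of all image exchange in this package is :class:`ImageVolume`: a 3-D
scalar grid together with its voxel spacing (mm) and a 4x4 grid-index -> world-mm
affine. Label atlases are carried by :class:`LabelVolume`, which adds an integer
label grid and a label -> ROI-name lookup table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "default_affine",
    "load_volume",
    "save_volume",
    "load_labels",
    "save_labels",
]


def default_affine(spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Axis-aligned grid-index -> world-mm affine."""
    aff = np.eye(4)
    aff[:3, :3] = np.diag(np.asarray(spacing, dtype=float))
    aff[:3, 3] = np.asarray(origin, dtype=float)
    return aff


def _check_geometry(data: np.ndarray, spacing: np.ndarray, affine: np.ndarray) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D grid, got shape {data.shape}")
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError(f"spacing must be 3 positive components, got {spacing}")
    if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine must be an invertible 4x4 matrix")


@dataclass
class ImageVolume:
    """3-D scalar image with geometry and an optional brain mask."""

    data: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        _check_geometry(self.data, self.spacing, self.affine)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask and data must share the grid shape")

    @classmethod
    def from_spacing(cls, data, spacing, origin=(0.0, 0.0, 0.0), mask=None) -> "ImageVolume":
        return cls(data=np.asarray(data), spacing=np.asarray(spacing, float),
                   affine=default_affine(spacing, origin), mask=mask)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def with_data(self, data, mask="keep") -> "ImageVolume":
        """New volume on the same grid; mask kept unless overridden."""
        m = self.mask if isinstance(mask, str) and mask == "keep" else mask
        return ImageVolume(data=np.asarray(data), spacing=self.spacing.copy(),
                           affine=self.affine.copy(), mask=m)

    def same_grid(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.affine, other.affine))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) grid indices to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class LabelVolume:
    """Integer label grid with a label-id -> ROI-name lookup table.

    Background is label 0 and never appears in the lookup table.
    """

    labels: np.ndarray
    lut: dict[int, str]
    spacing: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer grid")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        _check_geometry(self.labels.astype(np.float32), self.spacing, self.affine)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.lut)
        if missing:
            raise ValueError(f"label ids present in grid but absent from lut: {sorted(missing)}")
        names = list(self.lut.values())
        if len(names) != len(set(names)):
            raise ValueError("duplicate ROI names in lut")

    @property
    def shape(self):
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def roi_mask(self, name: str) -> np.ndarray:
        ids = [k for k, v in self.lut.items() if v == name]
        if not ids:
            raise KeyError(f"unknown ROI name: {name!r}")
        return self.labels == ids[0]

    def roi_voxel_counts(self) -> dict[str, int]:
        out = {}
        for lab, name in sorted(self.lut.items()):
            out[name] = int(np.count_nonzero(self.labels == lab))
        return out

    def with_labels(self, labels) -> "LabelVolume":
        return LabelVolume(labels=np.asarray(labels), lut=dict(self.lut),
                           spacing=self.spacing.copy(), affine=self.affine.copy())


# ---------------------------------------------------------------------------
# NIfTI-1 I/O

def save_volume(vol: ImageVolume, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


def load_volume(path, mask: np.ndarray | None = None) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return ImageVolume(data=data, spacing=spacing, affine=np.asarray(img.affine), mask=mask)


def save_labels(lab: LabelVolume, label_path, lut_path) -> None:
    img = nib.Nifti1Image(lab.labels.astype(np.int32), lab.affine)
    img.header.set_zooms(tuple(lab.spacing))
    nib.save(img, str(label_path))
    lines = [f"{k}\t{v}" for k, v in sorted(lab.lut.items())]
    Path(lut_path).write_text("\n".join(lines) + "\n")


def load_labels(label_path, lut_path) -> LabelVolume:
    img = nib.load(str(label_path))
    labels = np.asanyarray(img.dataobj).astype(np.int32)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    lut: dict[int, str] = {}
    for line in Path(lut_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, v = line.split("\t") if "\t" in line else line.split(",", 1)
        lut[int(k)] = v.strip()
    return LabelVolume(labels=labels, lut=lut, spacing=spacing, affine=np.asarray(img.affine))
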
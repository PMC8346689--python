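"""Core image containers: scalar volumes and integer label maps on a voxel grid.

The NIfTI affine is the single source of world coordinates.  Voxel indices
are 0-based; all crop intervals elsewhere in the package are half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: canonical tissue label scheme (T1 brain segmentation)
TISSUE_SCHEME: dict[int, str] = {
    0: "background",
    1: "csf",
    2: "cortical_gm",
    3: "white_matter",
    4: "deep_gm",
    5: "brainstem",
    6: "cerebellum",
}

#: tissue classes (excluding background), in label order
TISSUE_CLASSES: tuple[int, ...] = (1, 2, 3, 4, 5, 6)


def spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel size in mm (column norms of the linear part)."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


@dataclass
class Volume:
    """3-D scalar image with voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data must be finite everywhere")

    @property
    def spacing(self) -> np.ndarray:
        return spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())


@dataclass
class LabelMap:
    """3-D integer image on the same grid conventions as :class:`Volume`."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    scheme: dict[int, str] = field(default_factory=lambda: dict(TISSUE_SCHEME))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"LabelMap data must be 3-D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("LabelMap data must be integer-valued")
            self.data = np.round(self.data).astype(np.int16)
        unknown = set(np.unique(self.data)) - set(self.scheme)
        if unknown:
            raise ValueError(f"label codes {sorted(unknown)} not in scheme")

    @property
    def spacing(self) -> np.ndarray:
        return spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def copy(self) -> "LabelMap":
        return LabelMap(self.data.copy(), self.affine.copy(), dict(self.scheme))


def same_grid(a: Volume | LabelMap, b: Volume | LabelMap, atol: float = 1e-4) -> bool:
    return a.shape == b.shape and np.allclose(a.affine, b.affine, atol=atol)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def load_volume(path) -> Volume:
    img = nib.load(str(path))
    return Volume(np.asarray(img.dataobj, dtype=np.float32), img.affine)


def load_labels(path, scheme: dict[int, str] | None = None) -> LabelMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.round(data).astype(np.int16)
    if scheme is None:
        codes = np.unique(data)
        scheme = dict(TISSUE_SCHEME)
        for c in codes:  # tolerate extra codes from external schemes
            scheme.setdefault(int(c), f"label_{int(c)}")
    return LabelMap(data, img.affine, scheme)


def save_volume(vol: Volume, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine), str(path))


def save_labels(lab: LabelMap, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(lab.data, dtype=np.int16), lab.affine), str(path))
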
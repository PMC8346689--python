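"""Preprocessing geometry: foreground crop, cube resampling, z-score
normalization, random-affine augmentation, and the exact inverse mapping of
predictions back to the native grid.

Fixed order used by the pipeline: crop -> resample -> z-score.  Intensities
are interpolated trilinearly; label maps travel as smoothed one-hot
indicators followed by a voxelwise argmax, so no operation can introduce a
label code absent from its input.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import LabelMap, Volume


@dataclass
class CropRecord:
    """Everything needed to map a cube-grid prediction back to native space."""

    original_shape: tuple[int, int, int]
    crop_bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open
    resample_target_shape: tuple[int, int, int] | None = None
    original_affine: list | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "original_shape": list(self.original_shape),
                "crop_bounds": [list(b) for b in self.crop_bounds],
                "resample_target_shape": list(self.resample_target_shape)
                if self.resample_target_shape
                else None,
                "original_affine": self.original_affine,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CropRecord":
        d = json.loads(text)
        return cls(
            tuple(d["original_shape"]),
            tuple(tuple(b) for b in d["crop_bounds"]),
            tuple(d["resample_target_shape"]) if d["resample_target_shape"] else None,
            d["original_affine"],
        )

    @property
    def crop_shape(self) -> tuple[int, ...]:
        return tuple(b1 - b0 for b0, b1 in self.crop_bounds)


def crop_foreground(
    vol: Volume,
    labels: LabelMap | None = None,
    margin: int = 0,
    mask: np.ndarray | None = None,
):
    """Tight bounding box (plus margin) around the foreground.

    Foreground is ``mask`` if given, else voxels with intensity > 0
    (matching skull-stripped inputs).  Returns the cropped volume, cropped
    labels (if provided) and a :class:`CropRecord` for inversion.
    """
    fg = mask if mask is not None else (vol.data > 0)
    if not np.any(fg):
        raise ValueError("empty foreground: nothing to crop")
    bounds = []
    for ax in range(3):
        nz = np.any(fg, axis=tuple(a for a in range(3) if a != ax))
        idx = np.nonzero(nz)[0]
        lo = max(int(idx[0]) - margin, 0)
        hi = min(int(idx[-1]) + 1 + margin, vol.shape[ax])
        bounds.append((lo, hi))
    sl = tuple(slice(lo, hi) for lo, hi in bounds)

    new_affine = vol.affine.copy()
    new_affine[:3, 3] = (vol.affine @ np.array([bounds[0][0], bounds[1][0], bounds[2][0], 1.0]))[:3]
    out_vol = Volume(vol.data[sl].copy(), new_affine)
    out_lab = None
    if labels is not None:
        out_lab = LabelMap(labels.data[sl].copy(), new_affine.copy(), dict(labels.scheme))
    record = CropRecord(
        original_shape=tuple(vol.shape),
        crop_bounds=tuple(bounds),
        original_affine=[list(r) for r in vol.affine.tolist()],
    )
    return out_vol, out_lab, record


def _zoom_affine(affine: np.ndarray, in_shape, out_shape) -> np.ndarray:
    """Affine after endpoint-aligned resampling (scipy zoom convention)."""
    scale = np.array(
        [(i - 1) / (o - 1) if o > 1 else 1.0 for i, o in zip(in_shape, out_shape)]
    )
    new = affine.copy()
    new[:3, :3] = affine[:3, :3] @ np.diag(scale)
    return new


def _resample_labels_data(data: np.ndarray, out_shape, sigma_vox: float = 0.5) -> np.ndarray:
    """Smoothed-one-hot argmax resampling of an integer label array."""
    codes = np.unique(data)
    zoom = [o / i for i, o in zip(data.shape, out_shape)]
    best = np.full(out_shape, -np.inf, dtype=np.float32)
    out = np.zeros(out_shape, dtype=data.dtype)
    for code in codes:
        ind = (data == code).astype(np.float32)
        if sigma_vox > 0:
            ind = ndimage.gaussian_filter(ind, sigma=sigma_vox)
        w = ndimage.zoom(ind, zoom, order=1, mode="nearest", grid_mode=False,
                         output=np.float32)
        # zoom may be off by one voxel on odd ratios; enforce the target shape
        w = _fit_shape(w, out_shape)
        take = w > best
        out[take] = code
        best[take] = w[take]
    return out


def _fit_shape(arr: np.ndarray, shape) -> np.ndarray:
    if arr.shape == tuple(shape):
        return arr
    out = np.zeros(shape, dtype=arr.dtype)
    sl = tuple(slice(0, min(a, s)) for a, s in zip(arr.shape, shape))
    out[sl] = arr[sl]
    return out


def resample_to_cube(obj: Volume | LabelMap, target: int = 128):
    """Resample to an isotropic ``target``-cube grid.

    Trilinear for intensities, smoothed-one-hot argmax for labels; the
    affine is updated so world coordinates are preserved (endpoint-aligned
    convention).
    """
    if target <= 0:
        raise ValueError("target must be positive")
    out_shape = (target,) * 3
    new_affine = _zoom_affine(obj.affine, obj.shape, out_shape)
    if isinstance(obj, LabelMap):
        data = _resample_labels_data(obj.data, out_shape)
        return LabelMap(data, new_affine, dict(obj.scheme))
    zoom = [o / i for i, o in zip(obj.shape, out_shape)]
    data = ndimage.zoom(obj.data.astype(np.float32), zoom, order=1, mode="nearest",
                        grid_mode=False, output=np.float32)
    data = _fit_shape(data, out_shape)
    return Volume(data, new_affine)


def resample_to_shape(obj: Volume | LabelMap, out_shape):
    """General-shape variant of :func:`resample_to_cube` (used for inversion)."""
    out_shape = tuple(int(s) for s in out_shape)
    new_affine = _zoom_affine(obj.affine, obj.shape, out_shape)
    if isinstance(obj, LabelMap):
        data = _resample_labels_data(obj.data, out_shape)
        return LabelMap(data, new_affine, dict(obj.scheme))
    zoom = [o / i for i, o in zip(obj.shape, out_shape)]
    data = ndimage.zoom(obj.data.astype(np.float32), zoom, order=1, mode="nearest",
                        grid_mode=False, output=np.float32)
    return Volume(_fit_shape(data, out_shape), new_affine)


def standardize_prior_channel(codes: np.ndarray, n_classes: int = 6) -> np.ndarray:
    """Encode integer prior labels as one network channel: codes scaled to
    [0, 1] then standardized, so the prior and the z-scored image carry
    comparable dynamic range."""
    x = np.asarray(codes, dtype=np.float32) / float(n_classes)
    sd = float(x.std())
    if sd == 0:
        return x - float(x.mean())
    return (x - float(x.mean())) / sd


def zscore(vol: Volume, eps: float = 1e-8) -> Volume:
    """Normalize to zero mean, unit SD over the whole (cropped) volume."""
    sd = float(vol.data.std())
    if sd < eps:
        raise ValueError("constant volume: standard deviation is zero")
    data = (vol.data.astype(np.float32) - float(vol.data.mean())) / sd
    return Volume(data, vol.affine.copy())


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AffineAugmentParams:
    """Bounds for the random affine draw (defaults; upstream conventions vary)."""

    rotation_deg: float = 10.0
    scale: float = 0.10
    translation_vox: float = 5.0
    shear: float = 0.0


def _rotation_matrix(angles_rad) -> np.ndarray:
    ax, ay, az = angles_rad
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    return rz @ ry @ rx


def sample_affine(params: AffineAugmentParams, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw (3x3 matrix, translation) in voxel coordinates about the center."""
    ang = np.deg2rad(rng.uniform(-params.rotation_deg, params.rotation_deg, 3))
    mat = _rotation_matrix(ang)
    scale = 1.0 + rng.uniform(-params.scale, params.scale, 3)
    mat = mat @ np.diag(scale)
    if params.shear > 0:
        sh = np.eye(3)
        sh[0, 1], sh[0, 2], sh[1, 2] = rng.uniform(-params.shear, params.shear, 3)
        mat = mat @ sh
    trans = rng.uniform(-params.translation_vox, params.translation_vox, 3)
    return mat, trans


def apply_affine_voxel(data: np.ndarray, mat: np.ndarray, trans: np.ndarray,
                       order: int, is_labels: bool = False,
                       sigma_vox: float = 0.5) -> np.ndarray:
    """Apply a voxel-space affine about the volume center (pull-back)."""
    center = (np.asarray(data.shape) - 1) / 2.0
    offset = center - mat @ center + trans
    if not is_labels:
        return ndimage.affine_transform(data.astype(np.float32), mat, offset=offset,
                                        order=order, mode="constant", cval=0.0)
    codes = np.unique(data)
    best = np.full(data.shape, -np.inf, dtype=np.float32)
    out = np.zeros_like(data)
    for code in codes:
        ind = (data == code).astype(np.float32)
        if sigma_vox > 0:
            ind = ndimage.gaussian_filter(ind, sigma=sigma_vox)
        w = ndimage.affine_transform(ind, mat, offset=offset, order=1,
                                     mode="constant", cval=1.0 if code == 0 else 0.0)
        take = w > best
        out[take] = code
        best[take] = w[take]
    return out


def random_affine_augment(
    vol: Volume,
    labels: LabelMap | None,
    params: AffineAugmentParams | None = None,
    seed: int = 0,
):
    """Apply one random affine jointly to image and labels (seeded)."""
    params = params or AffineAugmentParams()
    rng = np.random.default_rng(seed)
    mat, trans = sample_affine(params, rng)
    out_vol = Volume(apply_affine_voxel(vol.data, mat, trans, order=1), vol.affine.copy())
    out_lab = None
    if labels is not None:
        out_lab = LabelMap(
            apply_affine_voxel(labels.data, mat, trans, order=1, is_labels=True),
            labels.affine.copy(),
            dict(labels.scheme),
        )
    return out_vol, out_lab


# ---------------------------------------------------------------------------
# inverse mapping
# ---------------------------------------------------------------------------

def to_native(pred: LabelMap, record: CropRecord, native_shape=None,
              native_affine=None) -> LabelMap:
    """Map a cube-grid prediction back onto the original native grid.

    Inverts the resample (back to the crop shape) and the crop (placing the
    block at its recorded bounds); voxels outside the crop are background.
    """
    native_shape = tuple(native_shape) if native_shape is not None else tuple(record.original_shape)
    if native_shape != tuple(record.original_shape):
        raise ValueError(
            f"record original shape {record.original_shape} does not match "
            f"requested native shape {native_shape}"
        )
    crop_shape = record.crop_shape
    on_crop = resample_to_shape(pred, crop_shape)
    out = np.zeros(native_shape, dtype=pred.data.dtype)
    sl = tuple(slice(lo, hi) for lo, hi in record.crop_bounds)
    out[sl] = on_crop.data
    affine = (
        np.asarray(native_affine, dtype=float)
        if native_affine is not None
        else np.asarray(record.original_affine, dtype=float)
    )
    return LabelMap(out, affine, dict(pred.scheme))
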
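"""Synthetic brain phantoms: template + subject cohorts with lesions.

The phantom emulates the statistical structure of a clinical T1 brain MRI
cohort: six tissue compartments (CSF incl. ventricles, a thin cortical
gray-matter shell, white matter, low-contrast deep gray-matter nuclei, an
inferior brainstem cylinder and a posterior cerebellum lobe), per-tissue
intensity means and texture, a smooth multiplicative bias field, additive
noise, per-subject smooth random deformations and T1-hypointense lesions
placed inside white or gray matter.  Geometry is parametric (ellipsoids and
cylinders) so the module needs no downloaded atlas; the cortical shell is
deliberately thin (a hard class) and the deep gray nuclei sit at low
contrast against white matter, the classic failure mode of intensity-only
segmentation.

All randomness flows through one seeded ``numpy.random.Generator`` per
call; identical seeds give bit-identical phantoms.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import LabelMap, TISSUE_CLASSES, Volume, save_labels, save_volume

__all__ = [
    "PhantomSpec",
    "Subject",
    "make_template",
    "sample_subject",
    "generate_cohort",
    "make_cohort",
    "random_displacement",
    "invert_displacement",
    "warp_image",
    "warp_labels_smooth",
]


@dataclass
class PhantomSpec:
    """Parameters controlling phantom geometry, contrast and corruption.

    ``contrast_scale`` multiplies the deep-gray-vs-white-matter intensity
    gap: at 1.0 the deep nuclei have their nominal mean, at 0.0 they are
    isointense with white matter and only a spatial prior can find them.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # T1-like means: WM bright, GM intermediate, CSF dark
    tissue_means: dict[int, float] = field(
        default_factory=lambda: {1: 30.0, 2: 70.0, 3: 100.0, 4: 85.0, 5: 90.0, 6: 75.0}
    )
    tissue_sds: dict[int, float] = field(
        default_factory=lambda: {1: 2.0, 2: 2.0, 3: 2.0, 4: 2.0, 5: 2.0, 6: 2.0}
    )
    contrast_scale: float = 1.0
    #: per-subject multiplicative jitter of tissue means (scanner variability)
    intensity_jitter: float = 0.05
    bias_amplitude: float = 0.10
    noise_sd: float = 2.0
    deform_sd_mm: float = 3.0
    deform_smooth_mm: float = 8.0
    # per-subject head pose (clinical scans are not pose-normalized)
    pose_rotation_deg: float = 12.0
    pose_scale: float = 0.08
    lesion_count: int = 2
    lesion_radius_range_mm: tuple[float, float] = (2.0, 5.0)
    lesion_intensity_shift: float = -30.0
    lesion_tissue: str = "mixed"  # {"WM", "GM", "mixed"}
    seed: int = 0


@dataclass
class Subject:
    """One synthetic subject: image, ground-truth labels, lesion masks."""

    subject_id: str
    image: Volume
    labels: LabelMap
    gm_lesion: np.ndarray
    wm_lesion: np.ndarray
    split: str = ""


# ---------------------------------------------------------------------------
# template geometry
# ---------------------------------------------------------------------------

def _frac_coords(shape):
    axes = [np.arange(n, dtype=float) / (n - 1) for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(fx, fy, fz, center, semi):
    r2 = ((fx - center[0]) / semi[0]) ** 2 + ((fy - center[1]) / semi[1]) ** 2 + (
        (fz - center[2]) / semi[2]
    ) ** 2
    return r2


def make_template(spec: PhantomSpec) -> tuple[Volume, LabelMap]:
    """Canonical phantom: undeformed, lesion-free, bias-free.

    Nested ellipsoidal CSF / cortical-GM / WM shells with central deep-GM
    nuclei and ventricles, an inferior brainstem cylinder and a posterior
    cerebellum lobe.  The label map covers exactly the brain region.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    if min(shape) < 32:
        raise ValueError(
            f"grid_shape {shape} too small: every axis must be >= 32 voxels "
            "to host all six tissue compartments"
        )
    fx, fy, fz = _frac_coords(shape)

    labels = np.zeros(shape, dtype=np.int16)
    # outer brain ellipsoid: CSF shell, cortical GM shell, WM core
    r2 = _ellipsoid(fx, fy, fz, (0.5, 0.5, 0.5), (0.42, 0.40, 0.40))
    r = np.sqrt(r2)
    labels[(r <= 1.0)] = 1                       # CSF outer shell
    labels[(r <= 0.92)] = 2                      # cortical GM shell (thin)
    labels[(r <= 0.80)] = 3                      # WM interior
    # deep gray nuclei: paired para-central ellipsoids (~4% of brain volume,
    # the anatomical share of thalamus + basal ganglia)
    for cx in (0.395, 0.605):
        d2 = _ellipsoid(fx, fy, fz, (cx, 0.50, 0.52), (0.095, 0.135, 0.105))
        labels[(d2 <= 1.0) & (labels == 3)] = 4
    # ventricles (CSF) between the nuclei
    v2 = _ellipsoid(fx, fy, fz, (0.5, 0.48, 0.54), (0.045, 0.10, 0.06))
    labels[(v2 <= 1.0) & (labels == 3)] = 1
    # cerebellum: posterior-inferior lobe
    c2 = _ellipsoid(fx, fy, fz, (0.5, 0.74, 0.28), (0.17, 0.13, 0.11))
    labels[c2 <= 1.0] = 6
    # brainstem: inferior cylinder (~3% of brain volume)
    s2 = ((fx - 0.5) / 0.09) ** 2 + ((fy - 0.52) / 0.09) ** 2
    labels[(s2 <= 1.0) & (fz >= 0.10) & (fz <= 0.44)] = 5

    missing = [c for c in TISSUE_CLASSES if not np.any(labels == c)]
    if missing:
        raise ValueError(f"grid {shape} too small: classes {missing} are empty")

    means = _effective_means(spec)
    image = np.zeros(shape, dtype=np.float32)
    for c in TISSUE_CLASSES:
        image[labels == c] = means[c]
    # mild smoothing so edges carry usable registration gradients
    image = ndimage.gaussian_filter(image, sigma=0.5).astype(np.float32)

    affine = np.diag(list(spec.spacing_mm) + [1.0])
    return Volume(image, affine), LabelMap(labels, affine.copy())


def _effective_means(spec: PhantomSpec) -> dict[int, float]:
    """Tissue means after applying the deep-GM contrast scale."""
    means = dict(spec.tissue_means)
    wm, dgm = means[3], means[4]
    means[4] = wm + float(spec.contrast_scale) * (dgm - wm)
    return means


# ---------------------------------------------------------------------------
# smooth random warps
# ---------------------------------------------------------------------------

def random_displacement(shape, spacing, sd_mm, smooth_mm, rng) -> np.ndarray:
    """Random smooth displacement field, shape (3, X, Y, Z), in voxels.

    The field is the curl of a Gaussian-smoothed random vector potential,
    so it is divergence-free (volume-preserving to first order): subjects
    differ in shape, not in implausible local volume scalings.  Each axis
    is rescaled so the displacement SD equals ``sd_mm``.
    """
    spacing = np.asarray(spacing, dtype=float)
    sigma_vox = smooth_mm / spacing
    pot = np.stack([
        ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
        for _ in range(3)
    ])
    dz = [np.gradient(pot[a], axis=2) for a in range(3)]
    dy = [np.gradient(pot[a], axis=1) for a in range(3)]
    dx = [np.gradient(pot[a], axis=0) for a in range(3)]
    curl = np.stack([dy[2] - dz[1], dz[0] - dx[2], dx[1] - dy[0]])
    disp = np.empty((3,) + tuple(shape), dtype=np.float32)
    for ax in range(3):
        sd = curl[ax].std()
        scale = 0.0 if sd == 0 else (sd_mm / spacing[ax]) / sd
        disp[ax] = (curl[ax] * scale).astype(np.float32)
    return disp


def invert_displacement(disp: np.ndarray, n_iter: int = 15) -> np.ndarray:
    """Fixed-point inverse of a (small, smooth) displacement field.

    Solves inv(x) = -disp(x + inv(x)) by iteration; adequate for the
    subject warps this module generates (diffeomorphic regime).
    """
    shape = disp.shape[1:]
    coords = np.indices(shape, dtype=np.float32)
    inv = np.zeros_like(disp)
    for _ in range(n_iter):
        pts = coords + inv
        sampled = np.stack(
            [ndimage.map_coordinates(disp[a], pts, order=1, mode="nearest") for a in range(3)]
        )
        inv = -sampled
    return inv


def warp_image(data: np.ndarray, disp: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Pull-back warp: out(x) = data(x + disp(x))."""
    coords = np.indices(data.shape, dtype=np.float32) + disp
    return ndimage.map_coordinates(data, coords, order=order, mode="constant", cval=cval)


def warp_labels_smooth(labels: np.ndarray, disp: np.ndarray, sigma_vox: float = 0.5) -> np.ndarray:
    """Label-preserving warp: smooth each class indicator, warp, argmax.

    Never introduces label codes absent from the input.
    """
    codes = np.unique(labels)
    coords = np.indices(labels.shape, dtype=np.float32) + disp
    best_val = np.full(labels.shape, -np.inf, dtype=np.float32)
    out = np.zeros(labels.shape, dtype=labels.dtype)
    for code in codes:
        ind = (labels == code).astype(np.float32)
        if sigma_vox > 0:
            ind = ndimage.gaussian_filter(ind, sigma=sigma_vox)
        w = ndimage.map_coordinates(
            ind, coords, order=1, mode="constant", cval=1.0 if code == 0 else 0.0
        )
        take = w > best_val
        out[take] = code
        best_val[take] = w[take]
    return out


# ---------------------------------------------------------------------------
# subject synthesis
# ---------------------------------------------------------------------------

def _pose_displacement(shape, spec: PhantomSpec, rng) -> np.ndarray:
    """Displacement field of a random rigid+scale pose about the center."""
    ang = np.deg2rad(rng.uniform(-spec.pose_rotation_deg, spec.pose_rotation_deg, 3))
    scale = 1.0 + rng.uniform(-spec.pose_scale, spec.pose_scale, 3)
    ax_, ay, az = ang
    rx = np.array([[1, 0, 0], [0, np.cos(ax_), -np.sin(ax_)], [0, np.sin(ax_), np.cos(ax_)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    mat = (rz @ ry @ rx) @ np.diag(scale)
    center = (np.asarray(shape, dtype=float) - 1) / 2.0
    coords = np.indices(shape, dtype=np.float32)
    rel = coords - center.reshape(3, 1, 1, 1)
    mapped = np.einsum("ab,b...->a...", mat.astype(np.float32), rel)
    return (mapped - rel).astype(np.float32)


def _bias_field(shape, amplitude, rng) -> np.ndarray:
    """exp of a random quadratic polynomial, normalized to +/- amplitude."""
    if amplitude == 0:
        return np.ones(shape, dtype=np.float32)
    fx, fy, fz = _frac_coords(shape)
    basis = [fx - 0.5, fy - 0.5, fz - 0.5,
             (fx - 0.5) ** 2, (fy - 0.5) ** 2, (fz - 0.5) ** 2,
             (fx - 0.5) * (fy - 0.5), (fy - 0.5) * (fz - 0.5), (fx - 0.5) * (fz - 0.5)]
    coef = rng.standard_normal(len(basis))
    poly = sum(c * b for c, b in zip(coef, basis))
    peak = np.abs(poly).max()
    if peak > 0:
        poly = poly / peak
    return np.exp(amplitude * poly).astype(np.float32)


def _place_lesions(labels, spec: PhantomSpec, rng):
    """Place blobby hypointense lesions inside WM (label 3) or deep/cortical GM.

    Returns (gm_mask, wm_mask) boolean arrays.  Lesion masks are subsets of
    the stated tissue class in the ground-truth labels by construction.
    """
    spacing = np.asarray(spec.spacing_mm)
    gm_mask = np.zeros(labels.shape, dtype=bool)
    wm_mask = np.zeros(labels.shape, dtype=bool)
    if spec.lesion_count == 0:
        return gm_mask, wm_mask

    kinds = []
    for i in range(spec.lesion_count):
        if spec.lesion_tissue == "WM":
            kinds.append("WM")
        elif spec.lesion_tissue == "GM":
            kinds.append("GM")
        else:
            kinds.append("WM" if i % 2 == 0 else "GM")

    coords = np.indices(labels.shape, dtype=np.float32)
    for kind in kinds:
        # GM lesions live in the (thick) deep-gray nuclei; cortical shell is
        # too thin to host a sphere at phantom resolution
        tissue_codes = (3,) if kind == "WM" else (4,)
        tissue = np.isin(labels, tissue_codes)
        # interior distance (mm) to non-tissue, so a lesion of radius r fits
        dist_in = ndimage.distance_transform_edt(tissue, sampling=spacing)
        placed = False
        for _ in range(100):
            r = rng.uniform(*spec.lesion_radius_range_mm)
            cand = np.argwhere(dist_in >= r)
            if cand.size == 0:
                continue
            center = cand[rng.integers(len(cand))]
            d = np.sqrt(
                sum(((coords[a] - center[a]) * spacing[a]) ** 2 for a in range(3))
            )
            # irregular boundary: modulate the radius with smoothed noise
            wobble = ndimage.gaussian_filter(rng.standard_normal(labels.shape), 2.0)
            wobble = wobble / (np.abs(wobble).max() + 1e-9)
            blob = (d <= r * (1.0 + 0.3 * wobble)) & tissue
            if blob.any():
                (wm_mask if kind == "WM" else gm_mask)[blob] = True
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place a {kind} lesion inside tissue after 100 attempts"
            )
    return gm_mask, wm_mask


def sample_subject(
    template: tuple[Volume, LabelMap],
    spec: PhantomSpec,
    seed: int,
    subject_id: str = "sub-000",
) -> Subject:
    """Draw one subject: warp the template, re-draw intensities, add
    lesions, bias field and noise.

    The ground-truth label map is the warped template labels; lesion voxels
    keep their underlying tissue class (the lesion alters intensity only),
    exactly the situation intra-lesion accuracy scores.
    """
    rng = np.random.default_rng(seed)
    tvol, tlab = template
    shape = tlab.shape
    spacing = tuple(spacing_from(tlab))

    disp = random_displacement(shape, spacing, spec.deform_sd_mm, spec.deform_smooth_mm, rng)
    disp = disp + _pose_displacement(shape, spec, rng)
    labels = warp_labels_smooth(tlab.data, disp)

    # subject-specific tissue means (scanner/sequence variability), contrast applied
    means = _effective_means(spec)
    subj_means = {}
    for c in TISSUE_CLASSES:
        subj_means[c] = means[c] * (1.0 + spec.intensity_jitter * rng.standard_normal())
    # keep contrast_scale=0 exact: deep GM mean tied to WM mean
    if spec.contrast_scale == 0:
        subj_means[4] = subj_means[3]

    image = np.zeros(shape, dtype=np.float32)
    for c in TISSUE_CLASSES:
        image[labels == c] = subj_means[c]
    # within-class texture: smoothed noise scaled by per-tissue SD
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), 1.0)
    texture = texture / (texture.std() + 1e-9)
    sd_map = np.zeros(shape, dtype=np.float32)
    for c in TISSUE_CLASSES:
        sd_map[labels == c] = spec.tissue_sds.get(c, 0.0)
    image = image + texture.astype(np.float32) * sd_map
    image = ndimage.gaussian_filter(image, sigma=0.5).astype(np.float32)

    gm_mask, wm_mask = _place_lesions(labels, spec, rng)
    image[gm_mask | wm_mask] += spec.lesion_intensity_shift

    image = image * _bias_field(shape, spec.bias_amplitude, rng)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, shape).astype(np.float32)
    image = np.clip(image, 0.0, None).astype(np.float32)
    # keep the true background exactly zero so foreground cropping is exact
    image[labels == 0] = 0.0

    return Subject(
        subject_id=subject_id,
        image=Volume(image, tvol.affine.copy()),
        labels=LabelMap(labels, tlab.affine.copy()),
        gm_lesion=gm_mask,
        wm_lesion=wm_mask,
    )


def spacing_from(obj) -> np.ndarray:
    return obj.spacing


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _split_assignments(n: int, fractions, rng) -> list[str]:
    names = ("train", "val", "test")
    fr = np.asarray(fractions, dtype=float)
    fr = fr / fr.sum()
    counts = np.floor(fr * n).astype(int)
    while counts.sum() < n:
        counts[int(np.argmax(fr * n - counts))] += 1
    order = rng.permutation(n)
    out = [""] * n
    pos = 0
    for name, k in zip(names, counts):
        for idx in order[pos : pos + k]:
            out[idx] = name
        pos += k
    return out


def generate_cohort(spec: PhantomSpec, n: int, seed: int,
                    fractions=(0.8, 0.1, 0.1)) -> tuple[tuple[Volume, LabelMap], list[Subject]]:
    """In-memory cohort: one template + ``n`` subjects with a seeded split."""
    if n < 1:
        raise ValueError("n must be >= 1")
    template = make_template(spec)
    rng = np.random.default_rng(seed)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n)
    splits = _split_assignments(n, fractions, rng)
    subjects = []
    for i in range(n):
        s = sample_subject(template, spec, int(subject_seeds[i]), subject_id=f"sub-{i:03d}")
        s.split = splits[i]
        subjects.append(s)
    return template, subjects


def make_cohort(spec: PhantomSpec, n: int, seed: int, out_dir,
                fractions=(0.8, 0.1, 0.1), overwrite: bool = False) -> pd.DataFrame:
    """Write a phantom cohort to disk as NIfTI pairs plus a CSV manifest.

    Manifest columns: subject_id, split, t1, labels, gm_lesion, wm_lesion,
    n_gm_lesion_vox, n_wm_lesion_vox, seed.
    """
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")
    out_dir.mkdir(parents=True, exist_ok=True)

    template, subjects = generate_cohort(spec, n, seed, fractions)
    save_volume(template[0], out_dir / "template_T1.nii.gz")
    save_labels(template[1], out_dir / "template_labels.nii.gz")

    rows = []
    for s in subjects:
        base = out_dir / s.subject_id
        save_volume(s.image, f"{base}_T1.nii.gz")
        save_labels(s.labels, f"{base}_labels.nii.gz")
        aff = s.labels.affine
        save_labels(LabelMap(s.gm_lesion.astype(np.int16), aff,
                             {0: "background", 1: "gm_lesion"}), f"{base}_gm_lesion.nii.gz")
        save_labels(LabelMap(s.wm_lesion.astype(np.int16), aff,
                             {0: "background", 1: "wm_lesion"}), f"{base}_wm_lesion.nii.gz")
        rows.append(
            {
                "subject_id": s.subject_id,
                "split": s.split,
                "t1": f"{s.subject_id}_T1.nii.gz",
                "labels": f"{s.subject_id}_labels.nii.gz",
                "gm_lesion": f"{s.subject_id}_gm_lesion.nii.gz",
                "wm_lesion": f"{s.subject_id}_wm_lesion.nii.gz",
                "n_gm_lesion_vox": int(s.gm_lesion.sum()),
                "n_wm_lesion_vox": int(s.wm_lesion.sum()),
                "seed": seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    return manifest
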
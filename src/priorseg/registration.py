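"""Patient-specific spatial prior by template registration.

A three-stage chain — 6-dof rigid, 12-dof affine, then dense deformable —
is fitted between the subject T1 and a template by multi-resolution
optimization of normalized cross-correlation (rigid/affine) and a
symmetric-forces demons stage after histogram matching (deformable).  The
template's tissue segmentation is then brought onto the subject grid with
a smoothed-label interpolation rule (each class indicator is Gaussian
smoothed with sigma voxels, warped, and the voxelwise argmax over classes
including background is taken).  The warped labels serve both as the prior
input channel for the network and as the registration-to-atlas baseline
segmenter.

The registration engine is SimpleITK, wrapped behind this module's
TransformChain contract; determinism comes from full metric sampling and
fixed iteration budgets.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .grid import LabelMap, Volume

__all__ = ["RegistrationConfig", "TransformChain", "register", "warp_labels",
           "build_prior", "volume_to_sitk", "sitk_to_array"]


# ---------------------------------------------------------------------------
# Volume <-> SimpleITK (array axis 0 maps to sitk x)
# ---------------------------------------------------------------------------

def volume_to_sitk(vol: Volume | LabelMap, dtype=np.float32) -> sitk.Image:
    data = np.asarray(vol.data, dtype=dtype)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
    affine = np.asarray(vol.affine, dtype=float)
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    direction = affine[:3, :3] @ np.diag(1.0 / spacing)
    img.SetSpacing(tuple(spacing))
    img.SetOrigin(tuple(affine[:3, 3]))
    img.SetDirection(tuple(direction.flatten()))
    return img


def sitk_to_array(img: sitk.Image) -> np.ndarray:
    return np.ascontiguousarray(sitk.GetArrayFromImage(img).T)


@dataclass
class RegistrationConfig:
    rigid_iterations: int = 80
    affine_iterations: int = 80
    shrink_factors: tuple[int, ...] = (2, 1)
    smoothing_sigmas: tuple[float, ...] = (1.0, 0.0)
    demons_iterations: tuple[int, ...] = (40, 30)  # coarse-to-fine levels
    demons_shrink_factors: tuple[int, ...] = (2, 1)
    demons_smoothing_sigma: float = 1.5
    label_sigma_vox: float = 0.2
    learning_rate: float = 1.0
    min_step: float = 1e-4


@dataclass
class TransformChain:
    """rigid -> affine -> deformable, each stage optional.

    Semantics follow the resampling convention: the composite maps subject
    (fixed) physical points into template (moving) space, so resampling the
    template through the composite produces a subject-space image.
    """

    rigid: sitk.Transform | None = None
    affine: sitk.Transform | None = None
    deformation: sitk.Image | None = None  # displacement field on the subject grid
    reference: sitk.Image | None = None    # subject-grid geometry

    def composite(self) -> sitk.Transform:
        comp = sitk.CompositeTransform(3)
        linear = self.affine if self.affine is not None else self.rigid
        if linear is not None:
            comp.AddTransform(linear)
        if self.deformation is not None:
            # last added is applied first: displace, then the linear map
            comp.AddTransform(sitk.DisplacementFieldTransform(sitk.Image(self.deformation)))
        return comp

    def inverse_composite(self) -> sitk.Transform:
        comp = sitk.CompositeTransform(3)
        if self.deformation is not None:
            inv_field = sitk.InvertDisplacementField(
                self.deformation, maximumNumberOfIterations=30,
                enforceBoundaryCondition=True,
            )
            comp.AddTransform(sitk.DisplacementFieldTransform(inv_field))
        linear = self.affine if self.affine is not None else self.rigid
        if linear is not None:
            comp.AddTransform(linear.GetInverse())
        return comp

    def apply_to_image(self, moving: Volume, reference: Volume | None = None,
                       interp=sitk.sitkLinear, default_value: float = 0.0) -> Volume:
        """Resample ``moving`` (template space) onto the subject grid."""
        ref = volume_to_sitk(reference) if reference is not None else self.reference
        mov = volume_to_sitk(moving)
        out = sitk.Resample(mov, ref, self.composite(), interp, default_value)
        affine = reference.affine if reference is not None else _affine_of(self.reference)
        return Volume(sitk_to_array(out), affine.copy())

    def save(self, out_dir) -> None:
        """Serialize: linear stage as a 4x4 text matrix, deformation as a
        NIfTI vector field (mm displacements on the subject grid)."""
        from pathlib import Path

        import nibabel as nib

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        linear = self.affine if self.affine is not None else self.rigid
        if linear is not None:
            m = np.eye(4)
            m[:3, :3] = np.asarray(linear.GetMatrix()).reshape(3, 3)
            center = np.asarray(linear.GetCenter())
            trans = np.asarray(linear.GetTranslation())
            # x -> M(x - c) + c + t
            m[:3, 3] = center + trans - m[:3, :3] @ center
            np.savetxt(out / "affine.mat", m, fmt="%.10g")
        if self.deformation is not None:
            field = sitk.GetArrayFromImage(self.deformation)  # (z,y,x,3)
            field = np.ascontiguousarray(field.transpose(2, 1, 0, 3))
            nib.save(nib.Nifti1Image(field.astype(np.float32),
                                     _affine_of(self.reference)),
                     str(out / "deformation.nii.gz"))

    def mean_displacement_vox(self, step: int = 4) -> float:
        """Mean |T(x) - x| over a subject-grid sample, in voxels."""
        ref = self.reference
        comp = self.composite()
        size = ref.GetSize()
        spacing = np.asarray(ref.GetSpacing())
        total, count = 0.0, 0
        for i in range(0, size[0], step):
            for j in range(0, size[1], step):
                for k in range(0, size[2], step):
                    p = ref.TransformIndexToPhysicalPoint((i, j, k))
                    q = comp.TransformPoint(p)
                    d = np.asarray(q) - np.asarray(p)
                    total += float(np.linalg.norm(d / spacing))
                    count += 1
        return total / max(count, 1)


def _affine_of(img: sitk.Image) -> np.ndarray:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    spacing = np.asarray(img.GetSpacing())
    affine = np.eye(4)
    affine[:3, :3] = direction @ np.diag(spacing)
    affine[:3, 3] = img.GetOrigin()
    return affine


# ---------------------------------------------------------------------------
# stage fitting
# ---------------------------------------------------------------------------

def _fit_linear(fixed, moving, transform, cfg: RegistrationConfig, iterations):
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=cfg.learning_rate, minStep=cfg.min_step,
        numberOfIterations=iterations, relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(cfg.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(cfg.smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(transform, inPlace=True)
    reg.Execute(fixed, moving)
    return transform


def register(subject: Volume, template: Volume,
             stages=("rigid", "affine", "deformable"),
             config: RegistrationConfig | None = None) -> TransformChain:
    """Fit the subject->template transform chain.

    ``stages`` is any prefix-closed subset of {rigid, affine, deformable};
    composition order is fixed.  Deterministic given config and inputs.
    """
    cfg = config or RegistrationConfig()
    unknown = set(stages) - {"rigid", "affine", "deformable"}
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    fixed = volume_to_sitk(subject)
    moving = volume_to_sitk(template)
    if sitk_to_array(fixed).std() == 0 or sitk_to_array(moving).std() == 0:
        raise ValueError("constant image: registration similarity undefined")

    chain = TransformChain(reference=fixed)

    if "rigid" in stages:
        init = sitk.CenteredTransformInitializer(
            fixed, moving, sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.GEOMETRY,
        )
        rigid = sitk.Euler3DTransform(init)
        chain.rigid = _fit_linear(fixed, moving, rigid, cfg, cfg.rigid_iterations)

    if "affine" in stages:
        aff = sitk.AffineTransform(3)
        if chain.rigid is not None:
            r = sitk.Euler3DTransform(chain.rigid)
            aff.SetMatrix(r.GetMatrix())
            aff.SetTranslation(r.GetTranslation())
            aff.SetCenter(r.GetCenter())
        chain.affine = _fit_linear(fixed, moving, aff, cfg, cfg.affine_iterations)

    if "deformable" in stages:
        linear = chain.affine if chain.affine is not None else chain.rigid
        if linear is not None:
            moving_lin = sitk.Resample(moving, fixed, linear, sitk.sitkLinear, 0.0)
        else:
            moving_lin = sitk.Resample(moving, fixed, sitk.Transform(3, sitk.sitkIdentity),
                                       sitk.sitkLinear, 0.0)
        matched = sitk.HistogramMatching(
            moving_lin, fixed, numberOfHistogramLevels=128, numberOfMatchPoints=7,
        )
        chain.deformation = _multiscale_demons(fixed, matched, cfg)

    if not np.all(np.isfinite(_chain_sample(chain))):
        raise RuntimeError("registration produced a non-finite transform")
    return chain


def _shrink(img: sitk.Image, factor: int) -> sitk.Image:
    if factor == 1:
        return img
    sm = sitk.SmoothingRecursiveGaussian(img, [factor / 2.0 * s for s in img.GetSpacing()])
    return sitk.Shrink(sm, [factor] * 3)


def _multiscale_demons(fixed: sitk.Image, moving: sitk.Image,
                       cfg: RegistrationConfig) -> sitk.Image:
    """Coarse-to-fine symmetric-forces demons; returns the displacement
    field on the fixed grid (physical mm, so it transfers across levels)."""
    fixed = sitk.Cast(fixed, sitk.sitkFloat32)
    moving = sitk.Cast(moving, sitk.sitkFloat32)
    iterations = cfg.demons_iterations
    if np.isscalar(iterations):
        iterations = (int(iterations),) * len(cfg.demons_shrink_factors)
    field = None
    for shrink, iters in zip(cfg.demons_shrink_factors, iterations):
        f = _shrink(fixed, shrink)
        m = _shrink(moving, shrink)
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(iters))
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(cfg.demons_smoothing_sigma)
        if field is None:
            field = demons.Execute(f, m)
        else:
            init = sitk.Resample(field, f, sitk.Transform(3, sitk.sitkIdentity),
                                 sitk.sitkLinear)
            field = demons.Execute(f, m, sitk.Cast(init, field.GetPixelID()))
    if field.GetSize() != fixed.GetSize():
        field = sitk.Resample(field, fixed, sitk.Transform(3, sitk.sitkIdentity),
                              sitk.sitkLinear)
    return sitk.Cast(field, sitk.sitkVectorFloat64)


def _chain_sample(chain: TransformChain) -> np.ndarray:
    comp = chain.composite()
    p = chain.reference.TransformIndexToPhysicalPoint((0, 0, 0))
    return np.asarray(comp.TransformPoint(p))


# ---------------------------------------------------------------------------
# label propagation
# ---------------------------------------------------------------------------

def warp_labels(template_labels: LabelMap, chain: TransformChain,
                sigma_vox: float = 0.2) -> LabelMap:
    """Bring template labels onto the subject grid with smoothed-label
    interpolation (sigma in template voxels); argmax includes background."""
    if sigma_vox < 0:
        raise ValueError("sigma_vox must be >= 0")
    comp = chain.composite()
    ref = chain.reference
    codes = np.unique(template_labels.data)
    best = None
    out = None
    for code in codes:
        ind = (template_labels.data == code).astype(np.float32)
        if sigma_vox > 0:
            ind = ndimage.gaussian_filter(ind, sigma=sigma_vox)
        ind_img = volume_to_sitk(Volume(ind, template_labels.affine))
        warped = sitk.Resample(ind_img, ref, comp, sitk.sitkLinear,
                               1.0 if code == 0 else 0.0)
        w = sitk_to_array(warped)
        if best is None:
            best = w
            out = np.full(w.shape, code, dtype=np.int16)
        else:
            take = w > best
            out[take] = code
            best[take] = w[take]
    return LabelMap(out, _affine_of(ref), dict(template_labels.scheme))


def build_prior(subject_t1: Volume, template_t1: Volume, template_labels: LabelMap,
                config: RegistrationConfig | None = None,
                stages=("rigid", "affine", "deformable")) -> LabelMap:
    """End-to-end prior: register then warp the template segmentation.

    The output grid equals the (preprocessed) subject grid, so the result
    can be fed directly as the network's second input channel or used as
    the registration-to-atlas baseline segmentation.
    """
    cfg = config or RegistrationConfig()
    chain = register(subject_t1, template_t1, stages=stages, config=cfg)
    return warp_labels(template_labels, chain, sigma_vox=cfg.label_sigma_vox)
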
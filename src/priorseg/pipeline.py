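"""End-to-end orchestration: skull-strip -> crop -> resample -> z-score ->
prior construction -> network inference -> background rule -> native-space
resampling; plus the experiment driver for the loss x prior design matrix.

The prior is built on the preprocessed cube grid (template and subject are
carried through the same crop/resample geometry before registration), so
the warped labels land directly on the network-input grid, encoded as a
single standardized channel of label codes.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import LabelMap, TISSUE_CLASSES, TISSUE_SCHEME, Volume, load_volume, save_labels
from .metrics import evaluate_cohort, z_compare
from .nn.unet import UNet3D, load_checkpoint, predict_labels, skull_strip
from .phantom import Subject
from .prep import CropRecord, crop_foreground, resample_to_cube, to_native, zscore
from .registration import RegistrationConfig, build_prior
from .training import TrainConfig, net_config_for_loss, train

from .prep import standardize_prior_channel as _standardize_prior


@dataclass
class PipelineConfig:
    tissue_checkpoint: str | None = None
    skullstrip_checkpoint: str | None = None
    template_t1: str | None = None
    template_labels: str | None = None
    use_prior: bool = True
    cube: int = 128
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)

    def validate(self) -> None:
        if self.use_prior and (self.template_t1 is None or self.template_labels is None):
            raise ValueError("use_prior requires template_t1 and template_labels")


def preprocess(vol: Volume, labels: LabelMap | None = None, cube: int = 128,
               mask: np.ndarray | None = None):
    """crop -> resample -> z-score; returns (image, labels?, CropRecord)."""
    cvol, clab, record = crop_foreground(vol, labels, mask=mask)
    record.resample_target_shape = (cube,) * 3
    rvol = resample_to_cube(cvol, cube)
    rlab = resample_to_cube(clab, cube) if clab is not None else None
    return zscore(rvol), rlab, record


def encode_input(t1_cube: Volume, prior: LabelMap | None) -> np.ndarray:
    """Stack network input channels: z-scored T1 (+ scaled prior labels)."""
    chans = [np.asarray(t1_cube.data, dtype=np.float32)]
    if prior is not None:
        chans.append(_standardize_prior(prior.data))
    return np.stack(chans)


def preprocess_template(template_t1: Volume, template_labels: LabelMap, cube: int):
    """Template through the same geometry (foreground = labeled brain)."""
    mask = template_labels.data > 0
    t1z, lab, _ = preprocess(template_t1, template_labels, cube=cube, mask=mask)
    return t1z, lab


def prepare_samples(subjects: list[Subject], cube: int, use_prior: bool,
                    template: tuple[Volume, LabelMap] | None = None,
                    reg_config: RegistrationConfig | None = None):
    """Turn phantom subjects into network-ready training samples.

    Each sample carries the stacked input channels, the cube-grid target
    labels, the prior segmentation (for baseline comparison), the crop
    record and the native-grid references.
    """
    if use_prior and template is None:
        raise ValueError("use_prior requires the template pair")
    tmpl_cube = None
    if use_prior:
        tmpl_cube = preprocess_template(template[0], template[1], cube)
    samples = []
    for s in subjects:
        t1z, lab, record = preprocess(s.image, s.labels, cube=cube)
        prior = None
        if use_prior:
            prior = build_prior(t1z, tmpl_cube[0], tmpl_cube[1], config=reg_config)
        lesion_cubes = {}
        for key, mask in (("gm_lesion_cube", s.gm_lesion), ("wm_lesion_cube", s.wm_lesion)):
            if mask is not None and mask.any():
                mlab = LabelMap(mask.astype(np.int16), s.labels.affine,
                                {0: "background", 1: "lesion"})
                _, cm, _ = crop_foreground(s.image, mlab)
                lesion_cubes[key] = resample_to_cube(cm, cube).data > 0
            else:
                lesion_cubes[key] = None
        samples.append({
            "subject_id": s.subject_id,
            "split": s.split,
            "image": encode_input(t1z, prior),
            "labels": lab.data,
            "prior": None if prior is None else prior.data,
            "record": record,
            "native_labels": s.labels,
            "gm_lesion": s.gm_lesion,
            "wm_lesion": s.wm_lesion,
            **lesion_cubes,
        })
    return samples


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def segment(t1, cfg: PipelineConfig, model: UNet3D | None = None,
            out_path=None, qc_path=None):
    """Fully automated segmentation of one T1 volume to native space.

    ``t1`` is a path or a Volume.  Returns (native LabelMap, qc dict);
    writes NIfTI + JSON sidecar when paths are given.
    """
    cfg.validate()
    qc: dict = {"stages": {}}

    def _tick(name, t0):
        qc["stages"][name] = round(time.perf_counter() - t0, 4)

    t0 = time.perf_counter()
    vol = t1 if isinstance(t1, Volume) else load_volume(t1)
    _tick("load", t0)

    if model is None:
        if cfg.tissue_checkpoint is None:
            raise ValueError("no tissue model provided")
        model, _ = load_checkpoint(cfg.tissue_checkpoint)

    mask = None
    if cfg.skullstrip_checkpoint is not None:
        t0 = time.perf_counter()
        ss_model, _ = load_checkpoint(cfg.skullstrip_checkpoint)
        ss_in, _, ss_rec = preprocess(vol, cube=cfg.cube)
        ss_mask_cube = skull_strip(ss_in, ss_model)
        mask = to_native(ss_mask_cube, ss_rec, vol.shape, vol.affine).data > 0
        if not mask.any():
            raise RuntimeError("skull stripping produced an empty brain mask")
        _tick("skull_strip", t0)

    t0 = time.perf_counter()
    t1z, _, record = preprocess(vol, cube=cfg.cube, mask=mask)
    _tick("preprocess", t0)
    qc["crop_bounds"] = [list(b) for b in record.crop_bounds]

    prior = None
    if cfg.use_prior:
        t0 = time.perf_counter()
        tmpl_t1 = load_volume(cfg.template_t1) if isinstance(cfg.template_t1, str) else cfg.template_t1
        tmpl_lab = cfg.template_labels
        if isinstance(tmpl_lab, str):
            from .grid import load_labels
            tmpl_lab = load_labels(tmpl_lab)
        tmpl_cube_t1, tmpl_cube_lab = preprocess_template(tmpl_t1, tmpl_lab, cfg.cube)
        prior = build_prior(t1z, tmpl_cube_t1, tmpl_cube_lab, config=cfg.registration)
        _tick("prior", t0)

    expected = 2 if prior is not None else 1
    if model.cfg.in_channels != expected:
        raise ValueError(f"model expects {model.cfg.in_channels} channels but the "
                         f"pipeline produced {expected}")

    t0 = time.perf_counter()
    probs = model.predict_proba(encode_input(t1z, prior))
    pred_cube = LabelMap(predict_labels(probs, model.cfg.final_activation),
                         t1z.affine.copy())
    _tick("inference", t0)

    t0 = time.perf_counter()
    native = to_native(pred_cube, record, vol.shape, vol.affine)
    _tick("to_native", t0)

    if out_path is not None:
        save_labels(native, out_path)
    if qc_path is not None:
        Path(qc_path).write_text(json.dumps(qc, indent=2))
    return native, qc


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

def evaluate_samples(model: UNet3D, samples, lesions: bool = False) -> dict:
    """Run inference on prepared samples and score on the cube grid."""
    preds, truths, lesion_masks = [], [], []
    for s in samples:
        probs = model.predict_proba(s["image"])
        preds.append(predict_labels(probs, model.cfg.final_activation))
        truths.append(s["labels"])
        if lesions:
            lesion_masks.append((s.get("gm_lesion_cube"), s.get("wm_lesion_cube")))
    return evaluate_cohort(preds, truths, lesion_masks=lesion_masks if lesions else None)


def run_design_matrix(train_samples_by_prior: dict, test_samples_by_prior: dict,
                      losses=("dice", "cce", "wcce"), priors=(True, False),
                      net_kwargs: dict | None = None,
                      train_cfg: TrainConfig | None = None):
    """Train/evaluate every loss x prior configuration.

    ``*_samples_by_prior`` map the prior flag to prepared sample lists
    (inputs differ in channel count).  Returns (table DataFrame in the
    per-tissue mean +/- SD layout, pairwise Z records, fitted results).
    """
    net_kwargs = net_kwargs or {}
    base_cfg = train_cfg or TrainConfig()
    rows, dice_samples, results = [], {}, {}
    for use_prior in priors:
        for loss in losses:
            cfg = TrainConfig(**{**base_cfg.__dict__, "loss": loss, "use_prior": use_prior})
            in_ch = 2 if use_prior else 1
            net_cfg = net_config_for_loss(loss, in_ch, **net_kwargs)
            res = train(train_samples_by_prior[use_prior], net_cfg, cfg)
            report = evaluate_samples(res.model, test_samples_by_prior[use_prior])
            key = (loss, use_prior)
            results[key] = res
            per_subj = report["per_subject"]
            dice_samples[key] = {
                c: per_subj[per_subj["class"] == c]["dice"].to_numpy()
                for c in TISSUE_CLASSES
            }
            row = {"loss": loss, "prior": use_prior,
                   "overall": report["summary"]["overall_dice_mean"]}
            for c in TISSUE_CLASSES:
                t = TISSUE_SCHEME[c]
                row[t] = report["summary"]["per_tissue"][t]["dice_mean"]
                row[f"{t}_sd"] = report["summary"]["per_tissue"][t]["dice_sd"]
            rows.append(row)
    table = pd.DataFrame(rows)

    z_records = []
    for k1, k2 in combinations(dice_samples, 2):
        for c in TISSUE_CLASSES:
            a, b = dice_samples[k1][c], dice_samples[k2][c]
            if len(a) >= 2 and len(b) >= 2:
                zc = z_compare(a, b)
                z_records.append({"config1": k1, "config2": k2,
                                  "tissue": TISSUE_SCHEME[c], "z": zc.z,
                                  "significant": zc.significant})
    return table, pd.DataFrame(z_records), results
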
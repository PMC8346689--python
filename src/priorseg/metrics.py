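"""Segmentation evaluation: Dice, volume similarity, 95th-percentile
Hausdorff distance, intra-lesion accuracy, two-sample Z comparison and
cohort-level reporting.

Conventions (the literature varies, so they are fixed here):

* Dice and volume similarity are defined as 1.0 when both masks are empty.
* HD95 is *directed* (predicted -> true) as printed in its defining
  formula: the 95th percentile of the minimum distances from predicted
  voxels to the true set, in mm, honoring anisotropic spacing; percentile
  by linear interpolation between order statistics.  A symmetric variant is
  provided but is not the default.
* Two-sample Z uses sample means and SDs with the |Z| > 2.5 significance
  rule.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import LabelMap, TISSUE_CLASSES, TISSUE_SCHEME

__all__ = [
    "dice",
    "volume_similarity",
    "hd95",
    "intra_lesion_accuracy",
    "z_compare",
    "ZComparison",
    "evaluate_cohort",
    "harmonize_external_labels",
    "EXTERNAL_SCHEME",
    "EXCLUDED_CODE",
]


def _masks(pred, truth, cls):
    p = np.asarray(pred.data if isinstance(pred, LabelMap) else pred)
    t = np.asarray(truth.data if isinstance(truth, LabelMap) else truth)
    if p.shape != t.shape:
        raise ValueError(f"grids differ: {p.shape} vs {t.shape}")
    return p == cls, t == cls


def dice(pred, truth, cls: int, ignore: np.ndarray | None = None) -> float:
    """Dice overlap 2TP/(2TP+FP+FN) for one class; 1.0 if both masks empty."""
    pm, tm = _masks(pred, truth, cls)
    if ignore is not None:
        keep = ~np.asarray(ignore, dtype=bool)
        pm, tm = pm & keep, tm & keep
    tp = np.count_nonzero(pm & tm)
    fp = np.count_nonzero(pm & ~tm)
    fn = np.count_nonzero(~pm & tm)
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def volume_similarity(pred, truth, cls: int, ignore: np.ndarray | None = None) -> float:
    """VS = 1 - |V_pred - V_true| / (V_pred + V_true); location-blind."""
    pm, tm = _masks(pred, truth, cls)
    if ignore is not None:
        keep = ~np.asarray(ignore, dtype=bool)
        pm, tm = pm & keep, tm & keep
    vx, vy = int(pm.sum()), int(tm.sum())
    if vx + vy == 0:
        return 1.0
    return 1.0 - abs(vx - vy) / (vx + vy)


def hd95(pred, truth, cls: int, spacing=(1.0, 1.0, 1.0), symmetric: bool = False) -> float:
    """Directed 95th-percentile Hausdorff distance (pred -> true) in mm.

    Raises if either mask is empty (the distance is undefined).
    """
    pm, tm = _masks(pred, truth, cls)
    if not pm.any() or not tm.any():
        raise ValueError(f"hd95 undefined: empty mask for class {cls}")
    spacing = np.asarray(spacing, dtype=float)
    # distance from every voxel to the nearest true voxel
    d_to_true = ndimage.distance_transform_edt(~tm, sampling=spacing)
    forward = float(np.percentile(d_to_true[pm], 95, method="linear"))
    if not symmetric:
        return forward
    d_to_pred = ndimage.distance_transform_edt(~pm, sampling=spacing)
    backward = float(np.percentile(d_to_pred[tm], 95, method="linear"))
    return max(forward, backward)


def intra_lesion_accuracy(pred, gm_lesion_mask=None, wm_lesion_mask=None):
    """Fraction of lesion voxels predicted as their underlying tissue.

    WM lesions count label 3; GM lesions count labels 2 or 4.  An empty
    (or absent) mask yields ``None`` — excluded from cohort aggregates.
    """
    p = np.asarray(pred.data if isinstance(pred, LabelMap) else pred)
    acc_gm = acc_wm = None
    if gm_lesion_mask is not None:
        m = np.asarray(gm_lesion_mask, dtype=bool)
        if m.any():
            acc_gm = float(np.count_nonzero(np.isin(p[m], (2, 4))) / m.sum())
    if wm_lesion_mask is not None:
        m = np.asarray(wm_lesion_mask, dtype=bool)
        if m.any():
            acc_wm = float(np.count_nonzero(p[m] == 3) / m.sum())
    return acc_gm, acc_wm


@dataclass
class ZComparison:
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    n1: int
    n2: int
    z: float
    significant: bool
    direction: str  # "model1_higher" | "model2_higher" | "none"


def z_compare(sample1, sample2) -> ZComparison:
    """Two-sample Z statistic Z = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2).

    |Z| > 2.5 flags a significant difference; the sign gives direction.
    Sample SDs use ddof=1.
    """
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("z_compare needs at least 2 observations per sample")
    m1, m2 = float(x1.mean()), float(x2.mean())
    s1, s2 = float(x1.std(ddof=1)), float(x2.std(ddof=1))
    se = math.sqrt(s1 * s1 / x1.size + s2 * s2 / x2.size)
    if se == 0:
        z = 0.0 if m1 == m2 else math.copysign(math.inf, m1 - m2)
    else:
        z = (m1 - m2) / se
    sig = abs(z) > 2.5
    direction = "none"
    if sig:
        direction = "model1_higher" if z > 0 else "model2_higher"
    return ZComparison(m1, m2, s1, s2, int(x1.size), int(x2.size), z, sig, direction)


# ---------------------------------------------------------------------------
# cohort reporting
# ---------------------------------------------------------------------------

def evaluate_cohort(
    preds,
    truths,
    scheme: dict[int, str] | None = None,
    lesion_masks=None,
    spacing=None,
) -> dict:
    """Per-subject per-tissue metrics plus cohort aggregates.

    Returns ``{"per_subject": DataFrame (long format), "summary": dict}``.
    Summary holds mean +/- SD per tissue for Dice/VS/HD95, the overall
    (tissue-averaged) Dice, and mean/median/IQR intra-lesion accuracies.
    ``lesion_masks`` is an optional list of (gm_mask, wm_mask) per subject.
    """
    if len(preds) != len(truths):
        raise ValueError("preds and truths must be matched lists")
    scheme = scheme or {c: TISSUE_SCHEME[c] for c in TISSUE_CLASSES}
    classes = sorted(c for c in scheme if c != 0)
    rows = []
    lesion_rows = []
    for i, (p, t) in enumerate(zip(preds, truths)):
        sp = spacing if spacing is not None else (
            t.spacing if isinstance(t, LabelMap) else (1.0, 1.0, 1.0)
        )
        for c in classes:
            row = {
                "subject": i,
                "class": c,
                "tissue": scheme[c],
                "dice": dice(p, t, c),
                "volume_similarity": volume_similarity(p, t, c),
            }
            try:
                row["hd95_mm"] = hd95(p, t, c, spacing=sp)
            except ValueError:
                row["hd95_mm"] = np.nan
            rows.append(row)
        if lesion_masks is not None:
            gm, wm = lesion_masks[i]
            acc_gm, acc_wm = intra_lesion_accuracy(p, gm, wm)
            lesion_rows.append({"subject": i, "acc_gm": acc_gm, "acc_wm": acc_wm})

    per_subject = pd.DataFrame(rows)
    summary: dict = {"per_tissue": {}, "n_subjects": len(preds)}
    for c in classes:
        sub = per_subject[per_subject["class"] == c]
        summary["per_tissue"][scheme[c]] = {
            "dice_mean": float(sub["dice"].mean()),
            "dice_sd": float(sub["dice"].std(ddof=0)),
            "vs_mean": float(sub["volume_similarity"].mean()),
            "vs_sd": float(sub["volume_similarity"].std(ddof=0)),
            "hd95_mean_mm": float(sub["hd95_mm"].mean()),
            "hd95_sd_mm": float(sub["hd95_mm"].std(ddof=0)),
        }
    overall = per_subject.groupby("subject")["dice"].mean()
    summary["overall_dice_mean"] = float(overall.mean())
    summary["overall_dice_sd"] = float(overall.std(ddof=0))

    if lesion_rows:
        df = pd.DataFrame(lesion_rows)
        for key in ("acc_gm", "acc_wm"):
            vals = df[key].dropna().astype(float)
            if len(vals):
                q1, q3 = np.percentile(vals, [25, 75])
                summary[key] = {
                    "mean": float(vals.mean()),
                    "median": float(vals.median()),
                    "iqr": (float(q1), float(q3)),
                    "n": int(len(vals)),
                }
        summary["per_subject_lesion"] = df
    return {"per_subject": per_subject, "summary": summary}


# ---------------------------------------------------------------------------
# external-scheme harmonization
# ---------------------------------------------------------------------------

#: external manual-annotation scheme (MRBrainS18-style, 10 classes)
EXTERNAL_SCHEME: dict[int, str] = {
    0: "background",
    1: "csf",
    2: "basal_ganglia",
    3: "white_matter",
    4: "wm_hyperintensity",
    5: "cortical_gm",
    6: "ventricles",
    7: "cerebellum",
    8: "brainstem",
    9: "infarction",
    10: "other",
}

#: sentinel for voxels excluded from every metric computation
EXCLUDED_CODE = 255

_HARMONIZE = {
    0: 0,
    1: 1,   # CSF
    2: 4,   # basal ganglia -> deep gray matter
    3: 3,   # white matter
    4: 3,   # WM hyperintensity -> white matter
    5: 2,   # cortical gray matter
    6: 1,   # ventricles -> CSF
    7: 6,   # cerebellum
    8: 5,   # brainstem
    9: EXCLUDED_CODE,   # infarction: tissue type unclassifiable
    10: EXCLUDED_CODE,  # other
}


def harmonize_external_labels(ext: LabelMap) -> tuple[LabelMap, np.ndarray]:
    """Map the 10-class external manual scheme onto the 6-tissue scheme.

    Ventricles and CSF are condensed into one CSF class and white-matter
    hyperintensities are relabeled as white matter; infarction/other voxels
    cannot be assigned a tissue type and are returned as an exclusion mask
    to be passed to the metric functions' ``ignore`` argument.
    """
    data = np.asarray(ext.data)
    unknown = set(np.unique(data)) - set(_HARMONIZE)
    if unknown:
        raise ValueError(f"unknown external label codes: {sorted(unknown)}")
    out = np.zeros_like(data, dtype=np.int16)
    for src, dst in _HARMONIZE.items():
        out[data == src] = dst
    excluded = out == EXCLUDED_CODE
    out[excluded] = 0
    scheme = dict(TISSUE_SCHEME)
    return LabelMap(out, ext.affine.copy(), scheme), excluded
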
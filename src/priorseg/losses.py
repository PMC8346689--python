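"""Training objectives: multi-label soft Dice, categorical cross-entropy,
and median-frequency-weighted categorical cross-entropy.

Soft Dice operates on 6 sigmoid tissue channels (no explicit background:
the objective maximizes label-wise set similarity).  The cross-entropies
operate on 7 softmax channels with background explicit.  Median-frequency
class weights are w_i = n_b / n_i where n_b and n_i are the *median*
per-subject voxel counts of the background and i-th class across the
training set, so rare classes are upweighted and the background weight is
1 by construction.

Numerical policy: soft-Dice smoothing eps = 1e-5 in numerator and
denominator; cross-entropy probabilities clamped at 1e-7 before the log.
All losses accept either plain ndarrays or autograd Tensors; with Tensor
probabilities the returned scalar supports ``backward()``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import LabelMap
from .nn import autograd as ag
from .nn.autograd import Tensor

__all__ = ["ClassWeights", "soft_dice_loss", "cce_loss", "wcce_loss",
           "median_frequency_weights", "one_hot"]

DICE_EPS = 1e-5
LOG_CLAMP = 1e-7


def one_hot(labels: np.ndarray, n_channels: int, include_background: bool) -> np.ndarray:
    """One-hot encode an integer label array.

    With ``include_background`` the channels are labels 0..n-1 (softmax
    convention); without, channels are tissue labels 1..n (sigmoid
    convention).
    """
    labels = np.asarray(labels)
    out = np.zeros((n_channels,) + labels.shape, dtype=np.float32)
    offset = 0 if include_background else 1
    for c in range(n_channels):
        out[c] = labels == (c + offset)
    return out


@dataclass
class ClassWeights:
    """Per-class weights for weighted cross-entropy, background included."""

    weights: dict[int, float]

    def __post_init__(self):
        for c, w in self.weights.items():
            if not (w > 0):
                raise ValueError(f"class {c} weight must be positive, got {w}")

    def to_json(self) -> str:
        import json

        return json.dumps({str(c): w for c, w in sorted(self.weights.items())})

    @classmethod
    def from_json(cls, text: str) -> "ClassWeights":
        import json

        return cls({int(c): float(w) for c, w in json.loads(text).items()})

    def as_array(self, n_channels: int) -> np.ndarray:
        missing = [c for c in range(n_channels) if c not in self.weights]
        if missing:
            raise KeyError(f"missing weight for classes {missing}")
        return np.array([self.weights[c] for c in range(n_channels)], dtype=np.float64)


def _check_shapes(probs, target):
    p_shape = probs.shape if not isinstance(probs, Tensor) else probs.data.shape
    if tuple(p_shape) != tuple(np.asarray(target).shape):
        raise ValueError(f"shape mismatch: probs {tuple(p_shape)} vs target "
                         f"{tuple(np.asarray(target).shape)}")


def soft_dice_loss(probs, target_onehot) -> Tensor:
    """1 - mean over classes of (2*sum(p*t)+eps) / (sum(p)+sum(t)+eps)."""
    _check_shapes(probs, target_onehot)
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=np.float64))
    t = np.asarray(target_onehot, dtype=p.data.dtype)
    spatial = tuple(range(1, t.ndim))
    inter = ag.sum_(ag.mul(p, t), axis=spatial)          # (C,)
    psum = ag.sum_(p, axis=spatial)
    tsum = t.sum(axis=spatial)
    per_class = ag.div(2.0 * inter + DICE_EPS, psum + (tsum + DICE_EPS))
    return 1.0 - ag.mean_(per_class)


def cce_loss(probs, target_onehot) -> Tensor:
    """Mean over voxels of -sum_c t_c log p_c (7 channels, softmax mode)."""
    _check_shapes(probs, target_onehot)
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=np.float64))
    t = np.asarray(target_onehot, dtype=p.data.dtype)
    n_vox = int(np.prod(t.shape[1:]))
    lp = ag.log(ag.clamp_min(p, LOG_CLAMP))
    return ag.mul(ag.sum_(ag.mul(lp, t)), -1.0 / n_vox)


def wcce_loss(probs, target_onehot, weights: ClassWeights) -> Tensor:
    """Mean over voxels of -sum_c w_c t_c log p_c."""
    _check_shapes(probs, target_onehot)
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=np.float64))
    t = np.asarray(target_onehot, dtype=p.data.dtype)
    present = np.flatnonzero(t.reshape(t.shape[0], -1).sum(axis=1) > 0)
    missing = [int(c) for c in present if c not in weights.weights]
    if missing:
        raise KeyError(f"no weight provided for present classes {missing}")
    w = np.zeros(t.shape[0], dtype=t.dtype)
    for c in range(t.shape[0]):
        w[c] = weights.weights.get(c, 0.0)
    wt = t * w.reshape((-1,) + (1,) * (t.ndim - 1))
    n_vox = int(np.prod(t.shape[1:]))
    lp = ag.log(ag.clamp_min(p, LOG_CLAMP))
    return ag.mul(ag.sum_(ag.mul(lp, wt)), -1.0 / n_vox)


def median_frequency_weights(label_maps, n_classes: int = 7) -> ClassWeights:
    """w_i = median(n_b) / median(n_i) over per-subject voxel counts.

    ``label_maps``: LabelMaps or integer arrays (the training set).  Every
    class 0..n_classes-1 must have a nonzero median count.
    """
    maps = [np.asarray(m.data if isinstance(m, LabelMap) else m) for m in label_maps]
    if not maps:
        raise ValueError("need at least one label map")
    counts = np.zeros((len(maps), n_classes), dtype=np.int64)
    for i, m in enumerate(maps):
        for c in range(n_classes):
            counts[i, c] = int(np.count_nonzero(m == c))
    medians = np.median(counts, axis=0)
    zero = [c for c in range(n_classes) if medians[c] == 0]
    if zero:
        raise ValueError(f"median voxel count is zero for classes {zero}")
    weights = {c: float(medians[0] / medians[c]) for c in range(n_classes)}
    return ClassWeights(weights)
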
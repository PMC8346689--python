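"""3-D encoder-decoder segmentation network.

Architecture: 4 downsampling blocks (stride-2 convolutions into residual
context modules) followed by 4 upsampling blocks (nearest-neighbor upscale
+ convolution, skip concatenation, localization module), 3x3x3 kernels
throughout, instance normalization and leaky ReLU after every 3x3x3
convolution.  The outputs of the final three upsampling blocks pass
through 1x1x1 convolutions, are upsampled to the input shape, summed, and
passed through a single final activation (deep supervision via summed side
outputs).  Segmentation-head 1x1x1 convolutions are left linear so the
summed logits feed one activation.

Two tissue modes — 6 sigmoid channels (no explicit background; background
is assigned by the >0.5 decision rule) or 7 softmax channels (explicit
background) — plus a 1-channel sigmoid mode for skull stripping.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ..grid import LabelMap, Volume
from . import autograd as ag
from .autograd import Parameter, Tensor

__all__ = ["NetConfig", "UNet3D", "build_network", "predict_labels",
           "skull_strip", "save_checkpoint", "load_checkpoint"]


@dataclass
class NetConfig:
    in_channels: int = 2
    out_channels: int = 6
    final_activation: str = "sigmoid"  # {"sigmoid", "softmax"}
    base_filters: int = 8
    depth: int = 4
    input_shape: int = 128
    negative_slope: float = 0.01
    dropout: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.final_activation not in ("sigmoid", "softmax"):
            raise ValueError(f"unknown final_activation {self.final_activation!r}")
        tissue_ok = (self.out_channels == 6 and self.final_activation == "sigmoid") or (
            self.out_channels == 7 and self.final_activation == "softmax"
        )
        binary_ok = self.out_channels == 1 and self.final_activation == "sigmoid"
        if not (tissue_ok or binary_ok):
            raise ValueError(
                "invalid head: 6 channels pair with sigmoid, 7 with softmax, "
                "1 (skull-strip) with sigmoid"
            )
        if self.input_shape % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_shape {self.input_shape} not divisible by 2^depth={2**self.depth}"
            )


class _Conv:
    """Conv3d (+ optional instance norm + leaky ReLU)."""

    def __init__(self, name, cin, cout, k, rng, stride=1, norm_act=True, slope=0.01):
        fan_in = cin * k ** 3
        std = np.sqrt(2.0 / fan_in)
        self.w = Parameter(rng.normal(0.0, std, (cout, cin, k, k, k)).astype(np.float32),
                           name=f"{name}.w")
        self.b = Parameter(np.zeros(cout, dtype=np.float32), name=f"{name}.b")
        self.stride = stride
        self.pad = k // 2
        self.norm_act = norm_act
        self.slope = slope
        if norm_act:
            self.gamma = Parameter(np.ones(cout, dtype=np.float32), name=f"{name}.gamma")
            self.beta = Parameter(np.zeros(cout, dtype=np.float32), name=f"{name}.beta")

    def __call__(self, x: Tensor) -> Tensor:
        y = ag.conv3d(x, self.w, self.b, stride=self.stride, padding=self.pad)
        if self.norm_act:
            y = ag.instance_norm(y, self.gamma, self.beta)
            y = ag.leaky_relu(y, self.slope)
        return y

    def parameters(self):
        ps = [self.w, self.b]
        if self.norm_act:
            ps += [self.gamma, self.beta]
        return ps


class _Context:
    """Residual context module: two 3x3x3 convs with dropout between."""

    def __init__(self, name, ch, rng, slope, p_drop):
        self.c1 = _Conv(f"{name}.c1", ch, ch, 3, rng, slope=slope)
        self.c2 = _Conv(f"{name}.c2", ch, ch, 3, rng, slope=slope)
        self.p_drop = p_drop

    def __call__(self, x, training, rng):
        y = self.c1(x)
        y = ag.dropout(y, self.p_drop, rng, training)
        y = self.c2(y)
        return ag.add(x, y)

    def parameters(self):
        return self.c1.parameters() + self.c2.parameters()


class UNet3D:
    """The network; forward maps (in_channels, S, S, S) -> class probabilities."""

    def __init__(self, cfg: NetConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        F = [cfg.base_filters * (2 ** l) for l in range(cfg.depth + 1)]
        s = cfg.negative_slope

        self.in_conv = _Conv("in_conv", cfg.in_channels, F[0], 3, rng, slope=s)
        self.context = [_Context(f"ctx{l}", F[l], rng, s, cfg.dropout)
                        for l in range(cfg.depth + 1)]
        self.down = [_Conv(f"down{l}", F[l - 1], F[l], 3, rng, stride=2, slope=s)
                     for l in range(1, cfg.depth + 1)]
        self.up = [_Conv(f"up{l}", F[l], F[l - 1], 3, rng, slope=s)
                   for l in range(cfg.depth, 0, -1)]
        self.loc3 = [_Conv(f"loc{l}.a", 2 * F[l - 1], F[l - 1], 3, rng, slope=s)
                     for l in range(cfg.depth, 0, -1)]
        self.loc1 = [_Conv(f"loc{l}.b", F[l - 1], F[l - 1], 1, rng, slope=s)
                     for l in range(cfg.depth, 0, -1)]
        # segmentation heads on the final three decoder levels (linear 1x1x1)
        self.heads = {
            2: _Conv("head2", F[2], cfg.out_channels, 1, rng, norm_act=False),
            1: _Conv("head1", F[1], cfg.out_channels, 1, rng, norm_act=False),
            0: _Conv("head0", F[0], cfg.out_channels, 1, rng, norm_act=False),
        }

    # ------------------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        ps = self.in_conv.parameters()
        for m in self.context:
            ps += m.parameters()
        for m in self.down + self.up + self.loc3 + self.loc1:
            ps += m.parameters()
        for m in self.heads.values():
            ps += m.parameters()
        return ps

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name} in state dict")
            if p.data.shape != state[p.name].shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.data = np.array(state[p.name], dtype=np.float32)

    # ------------------------------------------------------------------
    def forward(self, x, training: bool = False, rng=None) -> Tensor:
        """x: ndarray or Tensor (in_channels, S, S, S) -> probability Tensor."""
        cfg = self.cfg
        if rng is None:
            rng = np.random.default_rng(0)
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if t.shape[0] != cfg.in_channels:
            raise ValueError(f"expected {cfg.in_channels} input channels, got {t.shape[0]}")
        if any(s % (2 ** cfg.depth) for s in t.shape[1:]):
            raise ValueError(f"spatial shape {t.shape[1:]} not divisible by 2^{cfg.depth}")

        skips = []
        h = self.context[0](self.in_conv(t), training, rng)
        skips.append(h)
        for l in range(1, cfg.depth + 1):
            h = self.down[l - 1](h)
            h = self.context[l](h, training, rng)
            if l < cfg.depth:
                skips.append(h)

        side = {}
        for i, l in enumerate(range(cfg.depth, 0, -1)):
            h = self.up[i](ag.upsample_nearest(h, 2))
            h = ag.concat([h, skips[l - 1]])
            h = self.loc3[i](h)
            h = self.loc1[i](h)
            level = l - 1
            if level in self.heads:
                side[level] = self.heads[level](h)

        logits = None
        for level, t_side in side.items():
            up = t_side if level == 0 else ag.upsample_nearest(t_side, 2 ** level)
            logits = up if logits is None else ag.add(logits, up)

        if cfg.final_activation == "softmax":
            return ag.softmax_channels(logits)
        return ag.sigmoid(logits)

    def predict_proba(self, x) -> np.ndarray:
        """Deterministic inference; returns the (C, S, S, S) probability array."""
        return self.forward(x, training=False).data


def build_network(cfg: NetConfig) -> UNet3D:
    return UNet3D(cfg)


# ---------------------------------------------------------------------------
# decision rule
# ---------------------------------------------------------------------------

def predict_labels(probs: np.ndarray, mode: str) -> np.ndarray:
    """Class decision from per-class probabilities.

    softmax mode (7 channels): voxelwise argmax; channel 0 is background.
    sigmoid mode (6 channels): argmax over the tissue channels, but a voxel
    whose maximum probability does not exceed 0.5 is assigned background
    (label 0).  Exact ties resolve to the lowest channel index.
    """
    probs = np.asarray(probs)
    if mode == "softmax":
        return np.argmax(probs, axis=0).astype(np.int16)
    if mode == "sigmoid":
        best = np.argmax(probs, axis=0)
        labels = (best + 1).astype(np.int16)  # channel c -> tissue label c+1
        labels[np.max(probs, axis=0) <= 0.5] = 0
        return labels
    raise ValueError(f"unknown mode {mode!r}")


def skull_strip(vol: Volume, model: UNet3D, threshold: float = 0.5) -> LabelMap:
    """Binary brain mask from a 1-channel sigmoid-mode network."""
    if model.cfg.out_channels != 1 or model.cfg.final_activation != "sigmoid":
        raise ValueError("skull_strip requires a 1-channel sigmoid-mode model")
    data = np.asarray(vol.data, dtype=np.float32)[None]
    probs = model.predict_proba(data)
    mask = (probs[0] > threshold).astype(np.int16)
    return LabelMap(mask, vol.affine.copy(), {0: "background", 1: "brain"})


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: UNet3D, path, metadata: dict | None = None) -> None:
    """Single-file checkpoint: weights + embedded NetConfig (+ metadata)."""
    payload = {f"param::{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.array(json.dumps(asdict(model.cfg)))
    payload["metadata_json"] = np.array(json.dumps(metadata or {}))
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[UNet3D, dict]:
    with np.load(path, allow_pickle=False) as npz:
        cfg = NetConfig(**json.loads(str(npz["config_json"])))
        metadata = json.loads(str(npz["metadata_json"]))
        state = {k[len("param::"):]: npz[k] for k in npz.files if k.startswith("param::")}
    model = UNet3D(cfg)
    model.load_state_dict(state)
    return model, metadata
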
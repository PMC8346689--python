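"""Optimization schedule and transfer-learning protocol.

Training uses Adam from a seeded random initialization with an inner 90/10
subject-level split for plateau detection: after 10 epochs without
improvement in validation loss the learning rate is halved, and training
stops after 50 epochs without improvement ("improvement" = strictly below
the best loss so far minus a 1e-5 tolerance).  The checkpoint with the
best validation loss is retained.  Batch size is 1 (one whole volume per
step), which is also why instance normalization is used in the network.

Transfer learning re-runs the same schedule from a pretrained
checkpoint's weights, inheriting its loss / prior configuration; the
leave-one-out protocol trains one model per subject on n-2 subjects,
validates on 1, and predicts the held-out subject with the model that
never saw it.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import (AffineAugmentParams, apply_affine_voxel, sample_affine,
                   standardize_prior_channel)
from .losses import (
    ClassWeights,
    cce_loss,
    median_frequency_weights,
    one_hot,
    soft_dice_loss,
    wcce_loss,
)
from .nn.unet import NetConfig, UNet3D, predict_labels

__all__ = ["TrainConfig", "ScheduleMonitor", "Adam", "train",
           "transfer_finetune", "loocv_transfer", "TrainResult"]


@dataclass
class TrainConfig:
    initial_lr: float = 0.0005
    lr_decay_factor: float = 0.5
    lr_patience_epochs: int = 10
    early_stop_epochs: int = 50
    batch_size: int = 1
    inner_split: tuple[float, float] = (0.9, 0.1)
    max_epochs: int = 1000
    loss: str = "dice"  # {"dice", "cce", "wcce"}
    use_prior: bool = True
    augment: bool = False
    augment_params: AffineAugmentParams | None = None
    min_improve: float = 1e-5
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.lr_decay_factor < 1):
            raise ValueError("lr_decay_factor must be in (0, 1)")
        if not (self.lr_patience_epochs < self.early_stop_epochs):
            raise ValueError("lr patience must be smaller than the early-stop window")
        if self.loss not in ("dice", "cce", "wcce"):
            raise ValueError(f"unknown loss {self.loss!r}")


class ScheduleMonitor:
    """Plateau LR decay + early stopping driven by a validation-loss trace.

    ``update`` is called once per epoch with the epoch's validation loss
    and reports the current learning rate and whether a decay or stop
    event fired.  The decay counter resets after each decay; the stop
    counter only resets on improvement.
    """

    def __init__(self, initial_lr: float, decay_factor: float = 0.5,
                 patience: int = 10, early_stop: int = 50, min_improve: float = 1e-5):
        if not (0 < decay_factor < 1):
            raise ValueError("decay_factor must be in (0, 1)")
        if patience >= early_stop:
            raise ValueError("patience must be < early_stop")
        self.lr = float(initial_lr)
        self.decay_factor = decay_factor
        self.patience = patience
        self.early_stop = early_stop
        self.min_improve = min_improve
        self.best = np.inf
        self.best_epoch = -1
        self.epoch = -1
        self._since_improve = 0
        self._since_decay = 0

    def update(self, val_loss: float) -> dict:
        self.epoch += 1
        improved = val_loss < self.best - self.min_improve
        if improved:
            self.best = float(val_loss)
            self.best_epoch = self.epoch
            self._since_improve = 0
            self._since_decay = 0
        else:
            self._since_improve += 1
            self._since_decay += 1
        decayed = False
        if self._since_decay >= self.patience:
            self.lr *= self.decay_factor
            self._since_decay = 0
            decayed = True
        stop = self._since_improve >= self.early_stop
        return {"epoch": self.epoch, "lr": self.lr, "improved": improved,
                "decayed": decayed, "stop": stop}


class Adam:
    """Adam on a list of Parameters (Kingma & Ba defaults)."""

    def __init__(self, params, lr=0.0005, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / bc1) / (
                np.sqrt(self.v[i] / bc2) + self.eps
            )


@dataclass
class TrainResult:
    model: UNet3D
    best_state: dict
    best_val_loss: float
    log: pd.DataFrame
    net_config: NetConfig
    train_config: TrainConfig
    class_weights: ClassWeights | None = None

    @property
    def metadata(self) -> dict:
        return {"loss": self.train_config.loss,
                "use_prior": self.train_config.use_prior,
                "best_val_loss": float(self.best_val_loss)}


def _augment_sample(sample: dict, params: AffineAugmentParams, rng) -> tuple[np.ndarray, np.ndarray]:
    """One random affine applied jointly to all input channels and labels.

    The T1 channel is interpolated trilinearly; the prior channel (integer
    label codes scaled to [0,1]) and the target labels go through the
    label-preserving smoothed-one-hot rule.
    """
    mat, trans = sample_affine(params, rng)
    image = np.asarray(sample["image"])
    labels = np.asarray(sample["labels"])
    chans = [apply_affine_voxel(image[0], mat, trans, order=1)]
    if image.shape[0] > 1 and sample.get("prior") is not None:
        prior_aug = apply_affine_voxel(np.asarray(sample["prior"]), mat, trans,
                                       order=1, is_labels=True)
        chans.append(standardize_prior_channel(prior_aug))
    elif image.shape[0] > 1:
        chans.extend(apply_affine_voxel(image[c], mat, trans, order=1)
                     for c in range(1, image.shape[0]))
    lab_aug = apply_affine_voxel(labels, mat, trans, order=1, is_labels=True)
    return np.stack(chans).astype(np.float32), lab_aug


def _encode_target(labels: np.ndarray, loss: str, out_channels: int = 6) -> np.ndarray:
    if out_channels == 1:  # binary (skull-strip) mode: brain vs background
        return (np.asarray(labels) > 0).astype(np.float32)[None]
    if loss == "dice":
        return one_hot(labels, 6, include_background=False)
    return one_hot(labels, 7, include_background=True)


def _loss_fn(loss: str, weights: ClassWeights | None):
    if loss == "dice":
        return soft_dice_loss
    if loss == "cce":
        return cce_loss
    if loss == "wcce":
        if weights is None:
            raise ValueError("wcce requires class weights")
        return lambda p, t: wcce_loss(p, t, weights)
    raise ValueError(loss)


def net_config_for_loss(loss: str, in_channels: int, **kwargs) -> NetConfig:
    """Head configuration implied by the loss: dice -> 6 sigmoid channels,
    cce/wcce -> 7 softmax channels."""
    if loss == "dice":
        return NetConfig(in_channels=in_channels, out_channels=6,
                         final_activation="sigmoid", **kwargs)
    return NetConfig(in_channels=in_channels, out_channels=7,
                     final_activation="softmax", **kwargs)


def train(samples, net_cfg: NetConfig, cfg: TrainConfig,
          val_samples=None, init_state: dict | None = None) -> TrainResult:
    """Train a network on a list of samples.

    Each sample is a dict with ``image`` (in_channels, S, S, S) float32 and
    ``labels`` (S, S, S) int.  If ``val_samples`` is None an inner
    subject-level split (``cfg.inner_split``) is drawn once, seeded.
    ``init_state`` warm-starts the weights (transfer learning).
    """
    cfg.validate()
    net_cfg.validate()
    samples = list(samples)
    if val_samples is None and len(samples) < 2:
        raise ValueError("need at least 2 training subjects")
    rng = np.random.default_rng(cfg.seed)

    if val_samples is None:
        order = rng.permutation(len(samples))
        n_val = max(1, int(round(cfg.inner_split[1] * len(samples))))
        val_idx = set(order[:n_val].tolist())
        train_set = [samples[i] for i in range(len(samples)) if i not in val_idx]
        val_set = [samples[i] for i in sorted(val_idx)]
    else:
        train_set = samples
        val_set = list(val_samples)
    if not train_set:
        raise ValueError("empty training set after split")

    weights = None
    if cfg.loss == "wcce":
        weights = median_frequency_weights([s["labels"] for s in train_set], n_classes=7)
    loss_fn = _loss_fn(cfg.loss, weights)

    model = UNet3D(net_cfg)
    if init_state is not None:
        model.load_state_dict(init_state)
    opt = Adam(model.parameters(), lr=cfg.initial_lr)
    monitor = ScheduleMonitor(cfg.initial_lr, cfg.lr_decay_factor,
                              cfg.lr_patience_epochs, cfg.early_stop_epochs,
                              cfg.min_improve)

    targets = {id(s): _encode_target(s["labels"], cfg.loss, net_cfg.out_channels)
               for s in train_set + val_set}
    aug_params = cfg.augment_params
    if cfg.augment and aug_params is None:
        # translation amplitude scaled to ~4% of the field of view
        side = int(train_set[0]["image"].shape[-1])
        aug_params = AffineAugmentParams(translation_vox=max(1.0, 0.04 * side))
    best_state = copy.deepcopy(model.state_dict())
    best_val = np.inf
    rows = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_set))
        train_losses = []
        for i in order:
            s = train_set[i]
            if cfg.augment:
                x, lab_aug = _augment_sample(s, aug_params, rng)
                target = _encode_target(lab_aug, cfg.loss, net_cfg.out_channels)
            else:
                x = np.asarray(s["image"], dtype=np.float32)
                target = targets[id(s)]
            probs = model.forward(x, training=True, rng=rng)
            loss = loss_fn(probs, target)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.lr = monitor.lr
            opt.step()
            train_losses.append(lval)

        val_losses = []
        for s in val_set:
            probs = model.forward(np.asarray(s["image"], dtype=np.float32), training=False)
            val_losses.append(float(loss_fn(probs, targets[id(s)]).data))
        val_loss = float(np.mean(val_losses))
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")

        event = monitor.update(val_loss)
        if event["improved"]:
            best_state = copy.deepcopy(model.state_dict())
            best_val = val_loss
        rows.append({"epoch": epoch, "train_loss": float(np.mean(train_losses)),
                     "val_loss": val_loss, "lr": event["lr"],
                     "decayed": event["decayed"], "stopped": event["stop"]})
        if event["stop"]:
            break

    if not rows:  # max_epochs == 0: keep the initial weights
        best_val = np.nan
    model.load_state_dict(best_state)
    log = pd.DataFrame(rows)
    return TrainResult(model, best_state, best_val, log, net_cfg, cfg, weights)


def transfer_finetune(base: TrainResult | tuple[UNet3D, dict], samples,
                      cfg: TrainConfig, val_samples=None) -> TrainResult:
    """Fine-tune from a pretrained checkpoint with the same schedule.

    Loss and prior settings are inherited from the base model's
    configuration; the network configuration must match.
    """
    if isinstance(base, TrainResult):
        base_model, meta = base.model, base.metadata
    else:
        base_model, meta = base
    cfg = copy.deepcopy(cfg)
    cfg.loss = meta.get("loss", cfg.loss)
    cfg.use_prior = meta.get("use_prior", cfg.use_prior)
    net_cfg = base_model.cfg

    mismatches = []
    sample0 = samples[0] if samples else None
    if sample0 is not None and sample0["image"].shape[0] != net_cfg.in_channels:
        mismatches.append(
            f"in_channels: model {net_cfg.in_channels} vs data {sample0['image'].shape[0]}"
        )
    expected_out = 6 if cfg.loss == "dice" else 7
    if net_cfg.out_channels != expected_out:
        mismatches.append(f"out_channels: model {net_cfg.out_channels} vs loss "
                          f"{cfg.loss} needing {expected_out}")
    if mismatches:
        raise ValueError("incompatible base checkpoint: " + "; ".join(mismatches))

    result = train(samples, copy.deepcopy(net_cfg), cfg, val_samples=val_samples,
                   init_state=base_model.state_dict())
    if cfg.max_epochs == 0:
        # 0-epoch fine-tune: weights identical to the base model
        result.best_state = copy.deepcopy(base_model.state_dict())
        result.model.load_state_dict(result.best_state)
    return result


def loocv_transfer(base, samples, cfg: TrainConfig) -> dict:
    """Leave-one-out transfer: for each subject, train on n-2, validate on
    1, and predict the held-out subject with the model that never saw it.

    Validation cases rotate round-robin (fold i holds out subject i and
    validates on subject i+1 mod n).  Returns fold assignments, per-subject
    predicted label arrays, and the per-fold TrainResults.
    """
    samples = list(samples)
    n = len(samples)
    if n < 3:
        raise ValueError(f"leave-one-out transfer needs >= 3 subjects, got {n}")
    folds = []
    predictions = {}
    results = []
    for i in range(n):
        val_j = (i + 1) % n
        train_ids = [j for j in range(n) if j not in (i, val_j)]
        fold_cfg = copy.deepcopy(cfg)
        fold_cfg.seed = cfg.seed + i
        res = transfer_finetune(base, [samples[j] for j in train_ids], fold_cfg,
                                val_samples=[samples[val_j]])
        probs = res.model.predict_proba(np.asarray(samples[i]["image"], dtype=np.float32))
        mode = res.net_config.final_activation
        predictions[i] = predict_labels(probs, mode)
        folds.append({"fold": i, "test": i, "val": val_j, "train": train_ids})
        results.append(res)
    return {"folds": folds, "predictions": predictions, "results": results}
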
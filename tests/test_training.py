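"""Schedule semantics, training loop, transfer and leave-one-out protocol."""
import numpy as np
import pytest

from priorseg.training import (
    Adam,
    ScheduleMonitor,
    TrainConfig,
    loocv_transfer,
    net_config_for_loss,
    train,
    transfer_finetune,
)


def _toy_samples(n, rng, size=16, channels=1):
    samples = []
    for _ in range(n):
        labels = rng.integers(0, 7, (size, size, size))
        image = (labels[None] / 6.0 + 0.1 * rng.standard_normal((channels, size, size, size))
                 ).astype(np.float32)
        samples.append({"image": image, "labels": labels})
    return samples


def _tiny_cfg(channels=1, loss="dice", **kw):
    return net_config_for_loss(loss, channels, base_filters=2, input_shape=16,
                               dropout=0.0, **kw)


class TestScheduleMonitor:
    def test_flat_trace_decays_at_epoch_11(self):
        m = ScheduleMonitor(0.0005, patience=10, early_stop=50)
        events = [m.update(1.0) for _ in range(11)]
        assert not any(e["decayed"] for e in events[:10])
        assert events[10]["decayed"] and events[10]["lr"] == pytest.approx(0.00025)

    def test_flat_trace_stops_after_50(self):
        m = ScheduleMonitor(1e-3, patience=10, early_stop=50)
        events = [m.update(2.0) for _ in range(51)]
        assert not any(e["stop"] for e in events[:50])
        assert events[50]["stop"]

    def test_improvement_resets_counters(self):
        m = ScheduleMonitor(1e-3, patience=10, early_stop=50)
        for i in range(9):
            m.update(1.0)
        e = m.update(0.5)  # improvement on the 10th epoch
        assert e["improved"] and not e["decayed"]
        events = [m.update(0.5) for _ in range(10)]
        assert events[-1]["decayed"] and not any(e["decayed"] for e in events[:-1])

    def test_lr_sequence_non_increasing(self, rng):
        m = ScheduleMonitor(1e-3, patience=3, early_stop=20)
        lrs = [m.update(float(v))["lr"] for v in rng.random(30)]
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ScheduleMonitor(1e-3, decay_factor=1.5)
        with pytest.raises(ValueError):
            ScheduleMonitor(1e-3, patience=50, early_stop=50)


class TestAdam:
    def test_minimizes_quadratic(self):
        from priorseg.nn.autograd import Parameter

        p = Parameter(np.array([5.0, -3.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            opt.zero_grad()
            p.grad = 2 * p.data
            opt.step()
        assert np.abs(p.data).max() < 1e-2


class TestTrain:
    def test_needs_two_subjects(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            train(_toy_samples(1, rng), _tiny_cfg(), TrainConfig(max_epochs=1))

    def test_smoke_val_loss_decreases(self, rng):
        samples = _toy_samples(4, rng)
        cfg = TrainConfig(max_epochs=10, seed=0, initial_lr=0.005, loss="dice")
        res = train(samples, _tiny_cfg(), cfg)
        assert res.log["val_loss"].iloc[-1] < res.log["val_loss"].iloc[0]
        # retained checkpoint is the minimum over epochs
        assert res.best_val_loss == pytest.approx(res.log["val_loss"].min())

    def test_reproducible_log(self, rng):
        samples = _toy_samples(3, np.random.default_rng(5))
        cfg = TrainConfig(max_epochs=3, seed=9, loss="cce")
        a = train(samples, _tiny_cfg(loss="cce"), cfg)
        b = train(samples, _tiny_cfg(loss="cce"), cfg)
        assert np.allclose(a.log["val_loss"], b.log["val_loss"])

    def test_wcce_derives_weights_from_training_maps(self, rng):
        samples = _toy_samples(3, rng)
        cfg = TrainConfig(max_epochs=1, seed=0, loss="wcce")
        res = train(samples, _tiny_cfg(loss="wcce"), cfg)
        assert res.class_weights is not None
        assert res.class_weights.weights[0] == 1.0


class TestTransfer:
    def test_zero_epoch_finetune_keeps_weights(self, rng):
        samples = _toy_samples(3, rng)
        base = train(samples, _tiny_cfg(), TrainConfig(max_epochs=2, seed=0))
        out = transfer_finetune(base, samples, TrainConfig(max_epochs=0, seed=1))
        for k, v in base.model.state_dict().items():
            assert np.array_equal(out.model.state_dict()[k], v)

    def test_metadata_inherited(self, rng):
        samples = _toy_samples(3, rng)
        base = train(samples, _tiny_cfg(), TrainConfig(max_epochs=1, seed=0,
                                                       loss="dice", use_prior=False))
        out = transfer_finetune(base, samples,
                                TrainConfig(max_epochs=0, loss="cce", use_prior=True))
        assert out.train_config.loss == "dice"
        assert out.train_config.use_prior is False

    def test_incompatible_channels_rejected(self, rng):
        base = train(_toy_samples(3, rng), _tiny_cfg(),
                     TrainConfig(max_epochs=0, seed=0))
        two_channel = _toy_samples(2, rng, channels=2)
        with pytest.raises(ValueError, match="in_channels"):
            transfer_finetune(base, two_channel, TrainConfig(max_epochs=0))


class TestLOOCV:
    def test_seven_fold_bookkeeping(self, rng):
        samples = _toy_samples(7, rng)
        base = train(samples[:3], _tiny_cfg(), TrainConfig(max_epochs=0, seed=0))
        out = loocv_transfer(base, samples, TrainConfig(max_epochs=0, seed=0))
        folds = out["folds"]
        assert len(folds) == 7
        assert sorted(f["test"] for f in folds) == list(range(7))
        for f in folds:
            held_out = f["test"]
            assert held_out not in f["train"]
            assert held_out != f["val"]
            assert len(f["train"]) == 5
            assert sorted(f["train"] + [f["val"], f["test"]]) == list(range(7))
        assert sorted(out["predictions"]) == list(range(7))

    def test_three_subject_degenerate(self, rng):
        samples = _toy_samples(3, rng)
        base = train(samples, _tiny_cfg(), TrainConfig(max_epochs=0, seed=0))
        out = loocv_transfer(base, samples, TrainConfig(max_epochs=0, seed=0))
        assert all(len(f["train"]) == 1 for f in out["folds"])

    def test_too_few_subjects(self, rng):
        samples = _toy_samples(2, rng)
        base = train(samples, _tiny_cfg(), TrainConfig(max_epochs=0, seed=0))
        with pytest.raises(ValueError, match=">= 3"):
            loocv_transfer(base, samples, TrainConfig(max_epochs=0))
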
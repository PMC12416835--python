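import numpy as np
import pytest

from distseg.model_core import (
    DegenerateScheduleError,
    OptionalDependencyError,
    TrainConfig,
    TrainHistory,
    l2_loss,
    load_checkpoint,
    lr_at,
    reference_backbone,
    sam_adapter,
    save_checkpoint,
    train,
)


class TestL2Loss:
    def test_equal_maps_zero(self, rng):
        x = rng.random((16, 16))
        assert l2_loss(x, x) == 0.0

    def test_closed_forms(self):
        z, o = np.zeros((8, 8)), np.ones((8, 8))
        assert l2_loss(z, o) == 1.0
        assert l2_loss(np.full((8, 8), 0.5), z) == 0.25

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l2_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestLrSchedule:
    CFG = TrainConfig()

    def test_warmup_end_hits_initial_rate(self):
        assert lr_at(249, 10_000, self.CFG) == pytest.approx(1e-4)

    def test_first_iteration_ramp(self):
        assert lr_at(0, 10_000, self.CFG) == pytest.approx(1e-4 / 250)

    def test_decay_midpoint_is_half(self):
        total = 250 + 2_000
        mid = 250 + 1_000
        assert lr_at(mid, total, self.CFG) == pytest.approx(0.5e-4)

    def test_continuous_nonnegative_peaks_at_warmup(self):
        total = 1_000
        lrs = [lr_at(i, total, self.CFG) for i in range(total)]
        assert min(lrs) > 0
        assert int(np.argmax(lrs)) == self.CFG.warmup_iters - 1
        jumps = np.abs(np.diff(lrs))
        assert jumps.max() < 1e-4 / 200  # no discontinuity at the joint
        assert lrs[-1] == pytest.approx(1e-4 / (total - 250))

    def test_degenerate_horizon_rejected(self):
        with pytest.raises(DegenerateScheduleError):
            lr_at(0, 250, self.CFG)


class _StubBackbone:
    """Scripted backbone: constant prediction driven by the update count."""

    def __init__(self, value_fn):
        self._value_fn = value_fn
        self.steps = 0
        self._params = {"w": np.zeros(1, dtype=np.float32)}

    @property
    def value(self):
        return self._value_fn(self.steps)

    def predict(self, patch):
        return np.full((256, 256), self.value)

    def loss_and_grads(self, x, y):
        self.steps += 1
        return 0.1, {"w": np.zeros(1, dtype=np.float32)}

    def parameters(self):
        return self._params

    def state(self):
        return {"w": self._params["w"].copy(), "steps": np.array([self.steps])}

    def load_state(self, state):
        self.steps = int(state["steps"][0])


def _tiny_dataset(rng, n=2, size=384):
    return [
        (rng.random((size, size)) * 100, np.clip(rng.random((size, size)), 0, 1))
        for _ in range(n)
    ]


class TestEarlyStopping:
    def test_constant_loss_stops_at_patience_window_end(self, rng):
        # with min_epochs=2 and patience=7, a flat validation loss must
        # stop exactly after epoch 1 + 7 = 8
        stub = _StubBackbone(lambda s: 0.5)
        cfg = TrainConfig(
            max_epochs=20, min_epochs=2, patience_epochs=7, warmup_iters=1, seed=0
        )
        _, hist = train(stub, _tiny_dataset(rng), cfg)
        assert hist.stopped_epoch == 8
        assert hist.best_epoch == 1

    def test_min_epochs_respected_when_flat(self, rng):
        stub = _StubBackbone(lambda s: 0.5)
        cfg = TrainConfig(
            max_epochs=30, min_epochs=12, patience_epochs=3, warmup_iters=1, seed=0
        )
        _, hist = train(stub, _tiny_dataset(rng), cfg)
        assert hist.stopped_epoch == 12

    def test_improving_loss_never_stops_early(self, rng):
        # validation loss falls every epoch by far more than min_delta
        stub = _StubBackbone(lambda s: max(0.9 - 0.05 * s, 0.55))
        cfg = TrainConfig(
            max_epochs=6, min_epochs=2, patience_epochs=3, warmup_iters=1, seed=0
        )
        _, hist = train(stub, _tiny_dataset(rng), cfg)
        assert hist.stopped_epoch == 6
        assert hist.best_epoch == 6
        assert all(a > b for a, b in zip(hist.val_loss, hist.val_loss[1:]))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(_StubBackbone(lambda s: 0.5), [], TrainConfig())


class TestReferenceBackbone:
    def test_output_shape_and_sigmoid_range(self, rng):
        bb = reference_backbone(seed=1)
        out = bb.predict(rng.normal(size=(256, 256)))
        assert out.shape == (256, 256)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_seeded_construction_deterministic(self, rng):
        a, b = reference_backbone(3), reference_backbone(3)
        x = rng.normal(size=(256, 256))
        np.testing.assert_array_equal(a.predict(x), b.predict(x))

    def test_parameter_budget(self):
        assert reference_backbone(0).n_parameters() < 1_000_000

    def test_gradients_match_finite_differences(self, rng):
        bb = reference_backbone(0)
        x = rng.normal(size=(2, 16, 16))
        y = rng.random((2, 16, 16))
        _, grads = bb.loss_and_grads(x, y)
        for name in ("e2.W", "d1.W", "head.W"):
            p = bb.params[name]
            idx = tuple(int(rng.integers(0, s)) for s in p.shape)
            eps, old = 1e-3, p[idx]
            p[idx] = old + eps
            up, _ = bb.loss_and_grads(x, y)
            p[idx] = old - eps
            dn, _ = bb.loss_and_grads(x, y)
            p[idx] = old
            fd = (up - dn) / (2 * eps)
            assert grads[name][idx] == pytest.approx(fd, rel=0.05, abs=1e-7)

    def test_training_deterministic_from_seed(self, rng):
        ds = _tiny_dataset(rng, n=3)
        cfg = TrainConfig(
            max_epochs=2, min_epochs=1, patience_epochs=2, warmup_iters=1,
            lr_init=1e-3, seed=7,
        )
        _, h1 = train(reference_backbone(7), list(ds), cfg)
        _, h2 = train(reference_backbone(7), list(ds), cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_checkpoint_round_trip(self, tmp_path, rng):
        bb = reference_backbone(2)
        save_checkpoint(tmp_path / "ck.npz", bb.state(), TrainConfig(), TrainHistory())
        back = load_checkpoint(tmp_path / "ck.npz")
        x = rng.normal(size=(256, 256))
        np.testing.assert_array_equal(back.predict(x), bb.predict(x))


class TestSamAdapter:
    def test_missing_optional_dependency_is_a_clear_error(self, tmp_path):
        with pytest.raises(OptionalDependencyError, match="optional"):
            sam_adapter(tmp_path / "sam_vit_b.pth")
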
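import numpy as np
import pytest

from rfdseg.errors import ValidationError
from rfdseg.nn.autograd import Tensor
from rfdseg.nn.losses import LossWeights, total_loss
from rfdseg.nn.model import NetworkConfig, build_network, load_checkpoint, save_checkpoint
from rfdseg.nn.train import TrainConfig, _graph_total_loss, one_hot, predict, train


def tiny_config(**kw):
    defaults = dict(
        num_classes=3,
        base_channels=4,
        depth=2,
        patch_size=(8, 8, 8),
        attention_feature_maps=8,
    )
    defaults.update(kw)
    return NetworkConfig(**defaults)


class TestNetworkConfig:
    def test_channel_sequence_doubles_and_clamps(self):
        cfg = NetworkConfig(base_channels=16, max_channels=128, depth=4,
                            patch_size=(64, 64, 64))
        assert cfg.channels == [16, 32, 64, 128]
        cfg5 = NetworkConfig(base_channels=16, max_channels=128, depth=5,
                             patch_size=(64, 64, 64))
        assert cfg5.channels[-1] == 128  # clamped

    def test_patch_divisibility_enforced(self):
        with pytest.raises(ValidationError):
            NetworkConfig(depth=4, patch_size=(20, 20, 20))


class TestForward:
    def test_output_shape_and_row_stochastic(self):
        net = build_network(tiny_config(), seed=0)
        x = Tensor(np.random.default_rng(0).normal(size=(1, 1, 8, 8, 8)))
        probs, ds = net.forward(x, training=False)
        assert probs.shape == (1, 3, 8, 8, 8)
        assert np.allclose(probs.data.sum(axis=1), 1.0)
        assert np.isfinite(probs.data).all()

    def test_deep_supervision_heads_at_full_resolution(self):
        net = build_network(tiny_config(depth=3), seed=0)
        x = Tensor(np.zeros((1, 1, 8, 8, 8)))
        _, ds = net.forward(x, training=False)
        assert len(ds) == 1  # depth-3: one intermediate decoder stage
        assert ds[0].shape == (1, 3, 8, 8, 8)
        assert np.allclose(ds[0].data.sum(axis=1), 1.0)

    def test_ablation_flags_preserve_output_shape(self):
        x = Tensor(np.random.default_rng(1).normal(size=(1, 1, 8, 8, 8)))
        for flags in [(False, False, False), (True, False, False),
                      (False, True, False), (False, False, True)]:
            da, arb, ds = flags
            net = build_network(
                tiny_config(use_dual_attention=da, use_attention_refinement=arb,
                            use_deep_supervision=ds),
                seed=0,
            )
            probs, _ = net.forward(x, training=False)
            assert probs.shape == (1, 3, 8, 8, 8)

    def test_untrained_model_deterministic(self):
        net1 = build_network(tiny_config(), seed=5)
        net2 = build_network(tiny_config(), seed=5)
        x = np.zeros((8, 8, 8))
        assert np.array_equal(net1.predict_probs(x), net2.predict_probs(x))


class TestGradients:
    def test_loss_gradients_match_finite_differences(self):
        net = build_network(tiny_config(depth=3), seed=1)
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(1, 1, 8, 8, 8)))
        gold = one_hot(rng.integers(0, 3, size=(8, 8, 8)), 3)[None]
        lw = LossWeights()
        cw = np.array([1.0, 2.0, 0.5])

        def value():
            p, ds = net.forward(x, training=False)
            return _graph_total_loss(p, ds, gold, lw, cw)

        loss = value()
        loss.backward()
        params = net.parameters()
        rng2 = np.random.default_rng(9)
        checked = 0
        for pi in rng2.choice(len(params), size=6, replace=False):
            prm = params[pi]
            idx = tuple(int(rng2.integers(0, s)) for s in prm.data.shape)
            analytic = prm.grad[idx]
            eps = 1e-6
            orig = prm.data[idx]
            prm.data[idx] = orig + eps
            lp = float(value().data)
            prm.data[idx] = orig - eps
            lm = float(value().data)
            prm.data[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert analytic == pytest.approx(fd, abs=1e-6, rel=1e-4)
            checked += 1
        assert checked == 6

    def test_graph_loss_equals_plain_formulas(self):
        net = build_network(tiny_config(depth=3), seed=2)
        rng = np.random.default_rng(1)
        x = Tensor(rng.normal(size=(1, 1, 8, 8, 8)))
        gold = one_hot(rng.integers(0, 3, size=(8, 8, 8)), 3)[None]
        probs, ds = net.forward(x, training=False)
        cw = (1.0, 1.5, 0.5)
        graph = _graph_total_loss(probs, ds, gold, LossWeights(), np.array(cw))
        plain = total_loss(
            probs.data[0], [d.data[0] for d in ds], gold[0],
            LossWeights(class_weights=cw),
        )
        assert float(graph.data) == pytest.approx(plain, abs=1e-12)


class TestTraining:
    def test_same_seed_identical_loss_history(self, small_phantom):
        vol, mask, _ = small_phantom
        tc = TrainConfig(iterations=3, lr=0.01, grad_clip=1.0, seed=4)
        h1 = train(build_network(tiny_config(num_classes=4, patch_size=(16, 16, 16)),
                                 seed=7), [vol], [mask], None, tc)
        h2 = train(build_network(tiny_config(num_classes=4, patch_size=(16, 16, 16)),
                                 seed=7), [vol], [mask], None, tc)
        assert h1.loss == h2.loss

    def test_lr_schedule_steps_down(self, small_phantom):
        vol, mask, _ = small_phantom
        tc = TrainConfig(iterations=6, lr=1e-3, lr_drop_points=(2, 4), seed=0)
        net = build_network(tiny_config(num_classes=4, patch_size=(16, 16, 16)), seed=0)
        h = train(net, [vol], [mask], None, tc)
        assert h.lr == pytest.approx([1e-3, 1e-3, 1e-4, 1e-4, 1e-5, 1e-5])

    def test_gradient_clipping_bounds_update_norm(self, small_phantom):
        vol, mask, _ = small_phantom
        tc = TrainConfig(iterations=2, grad_clip=0.005, seed=1)
        net = build_network(tiny_config(num_classes=4, patch_size=(16, 16, 16)), seed=1)
        h = train(net, [vol], [mask], None, tc)
        assert all(n >= 0 for n in h.grad_norm)

    def test_empty_dataset_rejected(self):
        net = build_network(tiny_config(), seed=0)
        with pytest.raises(ValidationError):
            train(net, [], [], None, TrainConfig(iterations=1))


class TestPredict:
    def test_probabilities_sum_to_one_with_overlap(self):
        net = build_network(tiny_config(), seed=3)
        vol = np.random.default_rng(2).integers(0, 255, (8, 12, 12)).astype(float)
        probs, mask = predict(net, vol)
        assert probs.shape == (3, 8, 12, 12)
        assert np.allclose(probs.sum(axis=0), 1.0)
        assert mask.shape == vol.shape

    def test_small_volume_padded_and_cropped(self):
        net = build_network(tiny_config(), seed=3)
        vol = np.zeros((8, 8, 5))
        probs, mask = predict(net, vol)
        assert mask.shape == (8, 8, 5)

    def test_argmax_ties_break_to_lower_class(self):
        probs = np.array([[0.5], [0.5]])
        assert probs.argmax(axis=0)[0] == 0  # documented numpy behavior we rely on


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, small_phantom):
        vol, mask, _ = small_phantom
        net = build_network(tiny_config(num_classes=4, patch_size=(16, 16, 16)), seed=6)
        train(net, [vol], [mask], None,
              TrainConfig(iterations=2, lr=0.01, grad_clip=1.0, seed=0))
        path = tmp_path / "m.npz"
        save_checkpoint(net, path)
        net2 = load_checkpoint(path)
        assert np.array_equal(net.predict_probs(vol / 255.0),
                              net2.predict_probs(vol / 255.0))
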
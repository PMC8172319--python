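"""Network architecture, joint objective, and hand-written backprop checks."""

import numpy as np
import pytest

from vbmnet.nn import (ConfigurationError, LossWeights, ModelConfig,
                       build_model, objective_gradients, objective_loss,
                       task_losses)


def _batch(rng, n=3, shape=(8, 8, 8)):
    x = rng.normal(0, 0.5, size=(n, *shape, 2)).astype(np.float32)
    targets = {"age": rng.uniform(6, 20, n), "gender": rng.integers(0, 2, n).astype(float),
               "diagnosis": rng.integers(0, 2, n).astype(float)}
    return x, targets


class TestArchitecture:
    def test_spatial_trace_halves_per_block(self):
        net = build_model(ModelConfig(filters_per_block=(4, 8), dense_units=32), (32, 32, 32))
        assert net.spatial_trace == [(32, 32, 32), (16, 16, 16), (8, 8, 8)]

    def test_classification_outputs_in_unit_interval(self, tiny_net):
        rng = np.random.default_rng(0)
        x, _ = _batch(rng)
        out = tiny_net.forward(x)
        for task in ("gender", "diagnosis"):
            assert np.all(out[task] > 0) and np.all(out[task] < 1)
        assert out["age"].shape == (3,)

    def test_parameter_count_matches_hand_count(self):
        # 1 block of 2 filters on 2 input channels, dense 4, input 8^3:
        #   block BN:   2 * 2                        =   4
        #   conv:       2*27*2 weights + 2 biases    = 110
        #   (pool 8->4) flatten: 4^3 * 2 = 128
        #   shared dense: 128*4 + 4                  = 516
        #   3 heads: dense 4*1+1 = 5, BN 2 -> 7 each =  21
        cfg = ModelConfig(filters_per_block=(2,), dense_units=4, dropout_rate=0.0)
        net = build_model(cfg, (8, 8, 8))
        assert net.n_parameters() == 4 + 110 + 516 + 21

    def test_too_deep_for_input_raises_with_block_index(self):
        cfg = ModelConfig(filters_per_block=(2, 2, 2), dense_units=4)
        with pytest.raises(ConfigurationError, match="block 2"):
            build_model(cfg, (8, 8, 8))

    def test_forward_deterministic_without_dropout(self, tiny_net):
        rng = np.random.default_rng(1)
        x, _ = _batch(rng)
        a = tiny_net.forward(x)
        b = tiny_net.forward(x)
        for task in a:
            assert np.array_equal(a[task], b[task])

    def test_state_round_trip(self, tiny_net):
        rng = np.random.default_rng(2)
        x, _ = _batch(rng)
        before = tiny_net.forward(x)
        state = tiny_net.get_state()
        for p in tiny_net.parameters():
            p.value += 0.1
        tiny_net.set_state(state)
        after = tiny_net.forward(x)
        for task in before:
            assert np.array_equal(before[task], after[task])


class TestObjectiveLoss:
    def test_hand_case(self):
        targets = {"age": [10.0], "gender": [1.0], "diagnosis": [0.0]}
        preds = {"age": [12.0], "gender": [0.5], "diagnosis": [0.5]}
        loss = objective_loss(targets, preds)
        assert loss == pytest.approx(4.0 + 2 * np.log(2), abs=1e-9)

    def test_perfect_predictions(self):
        eps = 1e-7
        targets = {"age": [10.0, 15.0], "gender": [1.0, 0.0], "diagnosis": [0.0, 1.0]}
        preds = {"age": [10.0, 15.0], "gender": [1 - eps, eps], "diagnosis": [eps, 1 - eps]}
        per_task = task_losses(targets, preds)
        assert per_task["age"] == 0.0
        assert objective_loss(targets, preds) < 1e-6

    def test_weight_zeroing_leaves_pure_mse(self):
        rng = np.random.default_rng(3)
        targets = {"age": rng.uniform(6, 20, 8), "gender": rng.integers(0, 2, 8).astype(float),
                   "diagnosis": rng.integers(0, 2, 8).astype(float)}
        preds = {"age": rng.uniform(6, 20, 8), "gender": rng.uniform(0.1, 0.9, 8),
                 "diagnosis": rng.uniform(0.1, 0.9, 8)}
        loss = objective_loss(targets, preds, LossWeights(1.0, 0.0, 0.0))
        assert loss == pytest.approx(np.mean((targets["age"] - preds["age"]) ** 2))

    def test_permutation_invariance_and_weight_additivity(self):
        rng = np.random.default_rng(4)
        n = 10
        targets = {"age": rng.uniform(6, 20, n), "gender": rng.integers(0, 2, n).astype(float),
                   "diagnosis": rng.integers(0, 2, n).astype(float)}
        preds = {"age": rng.uniform(6, 20, n), "gender": rng.uniform(0.01, 0.99, n),
                 "diagnosis": rng.uniform(0.01, 0.99, n)}
        perm = rng.permutation(n)
        shuffled = ({k: v[perm] for k, v in targets.items()},
                    {k: v[perm] for k, v in preds.items()})
        assert objective_loss(*shuffled) == pytest.approx(objective_loss(targets, preds))
        w = LossWeights(0.3, 1.7, 2.0)
        parts = [objective_loss(targets, preds, LossWeights(*e))
                 for e in ((1, 0, 0), (0, 1, 0), (0, 0, 1))]
        total = objective_loss(targets, preds, w)
        assert total == pytest.approx(0.3 * parts[0] + 1.7 * parts[1] + 2.0 * parts[2])

    def test_rejects_nan_and_empty(self):
        with pytest.raises(ValueError):
            objective_loss({"age": [np.nan], "gender": [1], "diagnosis": [0]},
                           {"age": [1.0], "gender": [0.5], "diagnosis": [0.5]})
        with pytest.raises(ValueError):
            objective_loss({"age": [], "gender": [], "diagnosis": []},
                           {"age": [], "gender": [], "diagnosis": []})

    def test_analytic_gradient_matches_finite_differences(self):
        """Loss-level gradient check at 1e-4 relative tolerance (float64)."""
        rng = np.random.default_rng(5)
        n = 6
        targets = {"age": rng.uniform(6, 20, n), "gender": rng.integers(0, 2, n).astype(float),
                   "diagnosis": rng.integers(0, 2, n).astype(float)}
        preds = {"age": rng.uniform(6, 20, n), "gender": rng.uniform(0.05, 0.95, n),
                 "diagnosis": rng.uniform(0.05, 0.95, n)}
        w = LossWeights(1.0, 2.0, 0.5)
        grads = objective_gradients(targets, preds, w)
        eps = 1e-6
        for task in ("age", "gender", "diagnosis"):
            for i in range(n):
                up = {k: v.copy() for k, v in preds.items()}
                dn = {k: v.copy() for k, v in preds.items()}
                up[task][i] += eps
                dn[task][i] -= eps
                num = (objective_loss(targets, up, w) - objective_loss(targets, dn, w)) / (2 * eps)
                assert abs(num - grads[task][i]) <= 1e-4 * max(1.0, abs(num))


class TestBackprop:
    def test_weight_gradients_match_finite_differences(self):
        """End-to-end gradient check of the hand-written backward pass.

        Biases feeding straight into batch-norm have (near-)zero true
        gradient, which finite differences in float32 cannot resolve, so the
        check covers multi-element parameters (conv/dense kernels, batch-norm
        scale and shift).
        """
        rng = np.random.default_rng(0)
        cfg = ModelConfig(filters_per_block=(2,), dense_units=4, dropout_rate=0.0)
        net = build_model(cfg, (6, 6, 6), seed=1)
        x = rng.normal(0, 1, size=(3, 6, 6, 6, 2)).astype(np.float32)
        targets = {"age": np.array([10.0, 12.0, 8.0]), "gender": np.array([1.0, 0.0, 1.0]),
                   "diagnosis": np.array([0.0, 1.0, 0.0])}

        def loss_now():
            out = net.forward(x, training=True, dropout_rng=np.random.default_rng(5))
            return objective_loss(targets, out), out

        _, out = loss_now()
        net.zero_grads()
        net.backward({k: v.astype(np.float32)
                      for k, v in objective_gradients(targets, out).items()})
        prng = np.random.default_rng(2)
        checked = 0
        for p in net.parameters():
            if p.value.size < 2:
                continue
            idx = tuple(prng.integers(0, s) for s in p.value.shape)
            # eps small enough that the batch-norm curvature (batch of 3)
            # stays in the linear regime, large enough for float32 losses
            eps = 1e-3
            orig = float(p.value[idx])
            p.value[idx] = orig + eps
            l1, _ = loss_now()
            p.value[idx] = orig - eps
            l2, _ = loss_now()
            p.value[idx] = orig
            num = (l1 - l2) / (2 * eps)
            ana = float(p.grad[idx])
            assert abs(num - ana) <= 2e-2 * max(1.0, abs(num), abs(ana)), p.name
            checked += 1
        assert checked >= 6

    def test_input_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        cfg = ModelConfig(filters_per_block=(2,), dense_units=4, dropout_rate=0.0)
        net = build_model(cfg, (6, 6, 6), seed=1)
        x = rng.normal(0, 1, size=(2, 6, 6, 6, 2)).astype(np.float32)
        g = net.input_gradient(x, "age")
        idx = (1, 3, 2, 4, 0)
        eps = 1e-2
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        num = (net.forward(xp)["age"][1] - net.forward(xm)["age"][1]) / (2 * eps)
        assert g[idx] == pytest.approx(num, rel=1e-3, abs=1e-5)

    def test_unknown_task_rejected(self, tiny_net):
        rng = np.random.default_rng(2)
        x, _ = _batch(rng)
        with pytest.raises(KeyError):
            tiny_net.input_gradient(x, "iq")
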
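import numpy as np
import pytest

from ftdx.network import (
    ParallelNet,
    ParallelNetConfig,
    compute_class_weights,
    concat_config,
    parallel_config,
    single_type_config,
    softmax,
    weighted_cross_entropy,
    weighted_cross_entropy_grad,
)


class TestClassWeights:
    def test_equal_counts_give_unit_weights(self):
        w = compute_class_weights({"bvFTD": 10, "nfvPPA": 10, "svPPA": 10})
        np.testing.assert_allclose(w, [1.0, 1.0, 1.0])

    def test_imbalanced_counts_proportional_to_inverse_frequency(self):
        """173/63/41: unnormalized N/(3 n_c) = {0.534, 1.466, 2.252},
        rescaled to mean 1."""
        w = compute_class_weights({"bvFTD": 173, "nfvPPA": 63, "svPPA": 41})
        raw = np.array([277 / (3 * 173), 277 / (3 * 63), 277 / (3 * 41)])
        np.testing.assert_allclose(raw, [0.534, 1.466, 2.252], atol=5e-4)
        np.testing.assert_allclose(w, raw * 3 / raw.sum(), rtol=1e-12)
        assert w.mean() == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = compute_class_weights({"bvFTD": 173, "nfvPPA": 63, "svPPA": 41})
        b = compute_class_weights({"bvFTD": 346, "nfvPPA": 126, "svPPA": 82})
        np.testing.assert_allclose(a, b)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights({"bvFTD": 0, "nfvPPA": 1, "svPPA": 1})


class TestWeightedCrossEntropy:
    def test_uniform_logits_give_ln3(self):
        logits = np.zeros((4, 3))
        labels = np.array([0, 1, 2, 0])
        loss = weighted_cross_entropy(logits, labels, np.ones(3))
        assert loss == pytest.approx(np.log(3.0), rel=1e-9)

    def test_loss_vanishes_at_large_margin(self):
        logits = np.full((2, 3), -50.0)
        logits[0, 1] = 50.0
        logits[1, 2] = 50.0
        loss = weighted_cross_entropy(logits, np.array([1, 2]), np.ones(3))
        assert loss < 1e-8

    def test_single_sample_weight_cancels(self):
        logits = np.array([[0.3, -0.2, 1.1]])
        labels = np.array([2])
        a = weighted_cross_entropy(logits, labels, np.array([1.0, 1.0, 1.0]))
        b = weighted_cross_entropy(logits, labels, np.array([1.0, 1.0, 2.0]))
        assert a == pytest.approx(b)

    def test_label_and_weight_permutation_symmetry(self, rng):
        """Permuting class labels, weights and logit columns together
        leaves the weighted loss unchanged (exact symmetry)."""
        logits = rng.standard_normal((6, 3))
        labels = rng.integers(0, 3, 6)
        weights = np.array([0.5, 1.0, 1.5])
        perm = np.array([2, 0, 1])
        inv = np.argsort(perm)
        a = weighted_cross_entropy(logits, labels, weights)
        b = weighted_cross_entropy(
            logits[:, inv], perm[labels], weights[inv]
        )
        assert a == pytest.approx(b, rel=1e-12)

    def test_non_finite_logits_rejected(self):
        with pytest.raises(FloatingPointError):
            weighted_cross_entropy(
                np.array([[np.inf, 0, 0]]), np.array([0]), np.ones(3)
            )

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.standard_normal((5, 3))
        labels = rng.integers(0, 3, 5)
        weights = np.array([0.5, 1.0, 1.5])
        grad = weighted_cross_entropy_grad(logits, labels, weights)
        eps = 1e-6
        for i in range(5):
            for j in range(3):
                lp, lm = logits.copy(), logits.copy()
                lp[i, j] += eps
                lm[i, j] -= eps
                num = (
                    weighted_cross_entropy(lp, labels, weights)
                    - weighted_cross_entropy(lm, labels, weights)
                ) / (2 * eps)
                assert num == pytest.approx(grad[i, j], abs=1e-4)


class TestParallelNet:
    def test_probabilities_normalized(self, rng):
        net = ParallelNet(parallel_config(seed=0))
        X = rng.standard_normal((4, 735))
        p = net.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_seeded_initialization_identical(self):
        a = ParallelNet(parallel_config(seed=3)).get_flat_params()
        b = ParallelNet(parallel_config(seed=3)).get_flat_params()
        np.testing.assert_array_equal(a, b)
        c = ParallelNet(parallel_config(seed=4)).get_flat_params()
        assert not np.array_equal(a, c)

    def test_volume_arm_connected(self, rng):
        net = ParallelNet(parallel_config(seed=1))
        X = rng.standard_normal((3, 735))
        X2 = X.copy()
        X2[:, 360:] = 0.0
        assert not np.allclose(net.predict_logits(X), net.predict_logits(X2))

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ParallelNetConfig(arm_input_sizes=(360, 375), arm_hidden=((8,),))
        net = ParallelNet(parallel_config(seed=0))
        with pytest.raises(ValueError, match="735"):
            net.predict_logits(np.zeros((2, 100)))

    def test_architecture_shapes(self):
        assert concat_config().n_inputs == 735
        assert single_type_config(360).n_inputs == 360
        # 360->128->32 + 375->128->32, fused 64 -> 32 -> 3
        net = ParallelNet(parallel_config(seed=0))
        assert net.arms[0][0].W.shape == (360, 128)
        assert net.arms[1][0].W.shape == (375, 128)
        assert net.fusion[0].W.shape == (64, 32)
        assert net.out.W.shape == (32, 3)

    def test_parameter_gradients_match_finite_differences(self, rng):
        """Backprop agrees with central differences on a tiny network."""
        cfg = ParallelNetConfig(
            arm_input_sizes=(4, 3),
            arm_hidden=((5,), (4,)),
            fusion_hidden=(3,),
            dropout=0.0,
            seed=2,
        )
        net = ParallelNet(cfg)
        X = rng.standard_normal((6, 7))
        labels = rng.integers(0, 3, 6)
        weights = np.array([0.7, 1.0, 1.3])

        logits, cache = net.forward(X)
        grads, _ = net.backward(
            cache, weighted_cross_entropy_grad(logits, labels, weights)
        )
        flat_grad = np.concatenate(
            [np.concatenate([g.W.ravel(), g.b]) for g in net._grad_layers(grads)]
        )
        theta = net.get_flat_params()
        eps = 1e-6
        idx = rng.choice(theta.size, 40, replace=False)
        for k in idx:
            for sign, store in ((1, "p"), (-1, "m")):
                pass
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            net.set_flat_params(tp)
            lp = weighted_cross_entropy(net.predict_logits(X), labels, weights)
            net.set_flat_params(tm)
            lm = weighted_cross_entropy(net.predict_logits(X), labels, weights)
            assert (lp - lm) / (2 * eps) == pytest.approx(
                flat_grad[k], abs=1e-4
            )
        net.set_flat_params(theta)

    def test_input_gradients_match_finite_differences(self, rng):
        cfg = ParallelNetConfig(
            arm_input_sizes=(4, 3), arm_hidden=((5,), (4,)),
            fusion_hidden=(3,), dropout=0.0, seed=9, activation="tanh",
        )
        net = ParallelNet(cfg)
        x = rng.standard_normal((1, 7))
        g = net.input_gradients(x, target_class=1)[0]
        eps = 1e-6
        for j in range(7):
            xp, xm = x.copy(), x.copy()
            xp[0, j] += eps
            xm[0, j] -= eps
            num = (
                net.predict_logits(xp)[0, 1] - net.predict_logits(xm)[0, 1]
            ) / (2 * eps)
            assert num == pytest.approx(g[j], abs=1e-5)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = ParallelNet(parallel_config(seed=5))
        net.save_checkpoint(tmp_path / "ckpt.json")
        loaded = ParallelNet.load_checkpoint(tmp_path / "ckpt.json")
        X = rng.standard_normal((2, 735))
        np.testing.assert_array_equal(
            net.predict_logits(X), loaded.predict_logits(X)
        )

    def test_logit_shift_invariance_of_softmax(self, rng):
        logits = rng.standard_normal((3, 3))
        np.testing.assert_allclose(
            softmax(logits), softmax(logits + 7.5), atol=1e-12
        )
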
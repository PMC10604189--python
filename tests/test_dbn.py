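import itertools

import numpy as np
import pytest

from mitopipe import dbn


def enumerate_energy(v, h, omega, b, c):
    """Fully unrolled summation oracle for the RBM energy."""
    total = 0.0
    for i in range(len(v)):
        for j in range(len(h)):
            total -= omega[i, j] * v[i] * h[j]
    for i in range(len(v)):
        total -= b[i] * v[i]
    for j in range(len(h)):
        total -= c[j] * h[j]
    return total


def exact_conditional_hidden(v, params):
    """p(h_j = 1 | v) by brute-force enumeration of the joint."""
    m = params.n_hidden
    weights = []
    states = list(itertools.product([0, 1], repeat=m))
    for h in states:
        e = enumerate_energy(v, h, params.omega, params.b_vis, params.c_hid)
        weights.append(np.exp(-e))
    weights = np.array(weights)
    weights /= weights.sum()
    return np.array([sum(w for w, h in zip(weights, states) if h[j] == 1)
                     for j in range(m)])


class TestEnergy:
    def test_zero_state_zero_energy(self, rng):
        params = dbn.RBMParams(rng.normal(size=(3, 2)), rng.normal(size=3),
                               rng.normal(size=2))
        assert dbn.energy(np.zeros(3), np.zeros(2), params) == 0.0

    def test_zero_weights_decouple(self, rng):
        b, c = rng.normal(size=3), rng.normal(size=2)
        params = dbn.RBMParams(np.zeros((3, 2)), b, c)
        v, h = np.array([1, 0, 1]), np.array([0, 1])
        assert dbn.energy(v, h, params) == pytest.approx(-(b @ v) - (c @ h))

    def test_all_16_states_match_loop_oracle(self, rng):
        params = dbn.RBMParams(rng.normal(size=(2, 2)), rng.normal(size=2),
                               rng.normal(size=2))
        for v in itertools.product([0, 1], repeat=2):
            for h in itertools.product([0, 1], repeat=2):
                expected = enumerate_energy(v, h, params.omega,
                                            params.b_vis, params.c_hid)
                got = dbn.energy(np.array(v), np.array(h), params)
                assert got == pytest.approx(expected)

    def test_length_mismatch_rejected(self, rng):
        params = dbn.RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        with pytest.raises(ValueError):
            dbn.energy(np.zeros(2), np.zeros(2), params)


class TestConditionals:
    def test_zero_params_give_half(self):
        params = dbn.RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        assert np.allclose(dbn.p_hidden_given_visible(np.ones(3), params), 0.5)
        assert np.allclose(dbn.p_visible_given_hidden(np.ones(2), params), 0.5)

    def test_large_bias_saturates(self):
        params = dbn.RBMParams(np.zeros((2, 2)), np.zeros(2),
                               np.full(2, 20.0))
        probs = dbn.p_hidden_given_visible(np.zeros(2), params)
        assert np.all(probs > 0.999)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_hidden_conditional_matches_exact_joint(self, seed):
        gen = np.random.default_rng(seed)
        params = dbn.RBMParams(gen.normal(size=(3, 2)), gen.normal(size=3),
                               gen.normal(size=2))
        for v in itertools.product([0, 1], repeat=3):
            got = dbn.p_hidden_given_visible(np.array(v, dtype=float), params)
            assert np.allclose(got, exact_conditional_hidden(v, params),
                               atol=1e-12)

    def test_visible_conditional_is_symmetric_counterpart(self, rng):
        params = dbn.RBMParams(rng.normal(size=(3, 2)), rng.normal(size=3),
                               rng.normal(size=2))
        flipped = dbn.RBMParams(params.omega.T, params.c_hid, params.b_vis)
        h = np.array([1.0, 0.0])
        assert np.allclose(dbn.p_visible_given_hidden(h, params),
                           dbn.p_hidden_given_visible(h, flipped))


class TestPartitionFunction:
    def test_zero_params_count_states(self):
        assert dbn.partition_function(
            dbn.RBMParams(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        ) == pytest.approx(16.0)
        assert dbn.partition_function(
            dbn.RBMParams(np.zeros((1, 1)), np.zeros(1), np.zeros(1))
        ) == pytest.approx(4.0)

    def test_joint_normalizes(self, rng):
        params = dbn.RBMParams(rng.normal(size=(3, 3)), rng.normal(size=3),
                               rng.normal(size=3))
        z = dbn.partition_function(params)
        total = 0.0
        for v in itertools.product([0, 1], repeat=3):
            for h in itertools.product([0, 1], repeat=3):
                e = dbn.energy(np.array(v, float), np.array(h, float), params)
                total += np.exp(-e) / z
        assert total == pytest.approx(1.0)

    def test_refuses_large_models(self):
        params = dbn.RBMParams(np.zeros((15, 10)), np.zeros(15), np.zeros(10))
        with pytest.raises(ValueError):
            dbn.partition_function(params)


class TestCD1:
    def test_zero_learning_rate_keeps_params(self, rng):
        params = dbn.init_rbm(4, 3, rng)
        before = params.copy()
        cfg = dbn.RBMTrainConfig(epsilon=0.0)
        dbn.cd1_update(rng.integers(0, 2, size=(5, 4)), params, cfg, rng)
        assert np.array_equal(params.omega, before.omega)
        assert np.array_equal(params.b_vis, before.b_vis)

    def test_perfect_reconstruction_gives_zero_update(self, rng):
        params = dbn.init_rbm(4, 3, rng)
        before = params.copy()
        batch = rng.integers(0, 2, size=(6, 4)).astype(float)
        cfg = dbn.RBMTrainConfig(epsilon=0.5)
        # force h0 = p(h|v) and v1 = v0: data and reconstruction coincide
        dbn.cd1_update(batch, params, cfg, rng,
                       sample_hidden=lambda p: p,
                       reconstruct_visible=lambda h: batch)
        assert np.allclose(params.omega, before.omega)
        assert np.allclose(params.b_vis, before.b_vis)
        assert np.allclose(params.c_hid, before.c_hid)

    def test_empty_batch_rejected(self, rng):
        params = dbn.init_rbm(3, 2, rng)
        with pytest.raises(ValueError):
            dbn.cd1_update(np.zeros((0, 3)), params,
                           dbn.RBMTrainConfig(), rng)

    def test_cd1_training_raises_exact_log_likelihood(self):
        data = np.array([[1, 1, 0], [0, 0, 1]] * 10, dtype=float)
        gen = np.random.default_rng(0)
        params = dbn.init_rbm(3, 2, gen)
        ll_before = dbn.exact_log_likelihood(data, params)
        cfg = dbn.RBMTrainConfig(epsilon=0.2)
        for _ in range(300):
            dbn.cd1_update(data, params, cfg, gen)
        ll_after = dbn.exact_log_likelihood(data, params)
        assert ll_after > ll_before


class TestDBN:
    def test_single_layer_equals_train_rbm(self, separable_features):
        x, _ = separable_features
        cfg = dbn.DBNConfig(layer_sizes=(8,),
                            rbm_train=dbn.RBMTrainConfig(epochs=3, seed=4))
        stack = dbn.pretrain_dbn(x, cfg)
        solo, _ = dbn.train_rbm(x, 8, dbn.RBMTrainConfig(epochs=3, seed=4))
        assert np.array_equal(stack[0].omega, solo.omega)

    def test_layer_wiring(self, separable_features):
        x, _ = separable_features
        cfg = dbn.DBNConfig(layer_sizes=(8, 4),
                            rbm_train=dbn.RBMTrainConfig(epochs=2))
        stack = dbn.pretrain_dbn(x, cfg)
        assert stack[0].omega.shape == (16, 8)
        assert stack[1].omega.shape == (8, 4)

    def test_reconstruction_error_decreases(self, separable_features):
        x, _ = separable_features
        _, trace = dbn.train_rbm(x, 8, dbn.RBMTrainConfig(epochs=30, seed=0))
        assert trace[-1] < trace[0]

    def test_unscaled_input_rejected(self):
        with pytest.raises(ValueError):
            dbn.pretrain_dbn(np.array([[0.5, 1.7]]), dbn.DBNConfig())

    def test_finetune_separates_and_is_deterministic(self, separable_features):
        x, y = separable_features
        cfg = dbn.DBNConfig(layer_sizes=(32, 16), seed=0)
        clf = dbn.fit_dbn(x, y, cfg)
        acc = (clf.predict(x) == y).mean()
        assert acc >= 0.95
        clf2 = dbn.fit_dbn(x, y, cfg)
        assert np.array_equal(clf.predict(x), clf2.predict(x))

    def test_probabilities_normalized(self, separable_features):
        x, y = separable_features
        clf = dbn.fit_dbn(x, y, dbn.DBNConfig(layer_sizes=(16,), seed=1))
        probs = clf.predict_proba(x)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert np.all(probs >= 0)

    def test_single_class_labels_rejected(self, separable_features):
        x, _ = separable_features
        stack = dbn.pretrain_dbn(
            x, dbn.DBNConfig(rbm_train=dbn.RBMTrainConfig(epochs=1)))
        with pytest.raises(ValueError):
            dbn.finetune_and_predict(stack, x, np.zeros(len(x), dtype=int),
                                     dbn.DBNConfig())

    def test_finetune_not_worse_than_frozen_head(self, separable_features):
        x, y = separable_features
        cfg = dbn.DBNConfig(layer_sizes=(32, 16), seed=2)
        stack = dbn.pretrain_dbn(x, cfg)
        frozen = dbn.finetune_and_predict(stack, x, y, cfg,
                                          freeze_pretrained=True)
        full = dbn.finetune_and_predict(stack, x, y, cfg)
        acc_frozen = (frozen.predict(x) == y).mean()
        acc_full = (full.predict(x) == y).mean()
        assert acc_full >= acc_frozen


def test_min_max_scale_contract(rng):
    x = rng.normal(size=(10, 4)) * 5
    scaled, lo, span = dbn.min_max_scale(x)
    assert scaled.min() >= 0 and scaled.max() <= 1
    again, _, _ = dbn.min_max_scale(x, lo, span)
    assert np.array_equal(scaled, again)
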
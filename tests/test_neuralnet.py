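import numpy as np
import pytest

import odorlex as ox
from odorlex.neuralnet import NetworkError, _gradients, sigmoid


def random_net(sizes, seed=0, sigma=0.5):
    return ox.init_network(ox.NetworkSpec(list(sizes)), seed, sigma)


class TestInit:
    def test_same_seed_bit_identical(self):
        a = random_net([4, 3, 2], seed=42, sigma=0.1)
        b = random_net([4, 3, 2], seed=42, sigma=0.1)
        for Wa, Wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(Wa, Wb)

    def test_weight_sd_matches_sigma(self):
        net = random_net([100, 100], seed=0, sigma=0.1)
        assert 0.09 < net.weights[0].std() < 0.11

    def test_sigma_zero_gives_zero_weights(self):
        net = random_net([4, 3], seed=0, sigma=0.0)
        assert not net.weights[0].any()

    def test_biases_start_at_zero(self):
        net = random_net([4, 3, 2], seed=1)
        assert all(not b.any() for b in net.biases)


class TestForward:
    def test_zero_parameters_give_half_everywhere(self):
        net = random_net([3, 2, 2], sigma=0.0)
        acts = ox.forward(net, np.array([0.3, -1.0, 2.0]))
        for a in acts[1:]:
            np.testing.assert_allclose(a, 0.5)

    def test_one_one_identity_weight(self):
        net = random_net([1, 1], sigma=0.0)
        net.weights[0][0, 0] = 1.0
        assert ox.forward(net, np.array([0.0]))[-1][0] == pytest.approx(0.5)

    def test_matches_matrix_free_loop_oracle(self, rng):
        net = random_net([4, 3, 2], seed=3)
        x = rng.normal(size=4)
        a = list(x)
        for W, b in zip(net.weights, net.biases):
            a = [1.0 / (1.0 + np.exp(-(sum(W[i, j] * a[j] for j in range(len(a))) + b[i])))
                 for i in range(W.shape[0])]
        np.testing.assert_allclose(ox.forward(net, x)[-1], a, atol=1e-12)

    def test_batch_forward_matches_single(self, rng):
        net = random_net([5, 4, 3], seed=2)
        X = rng.normal(size=(6, 5))
        batch = ox.forward_batch(net, X)
        for i in range(6):
            np.testing.assert_allclose(batch[i], ox.forward(net, X[i])[-1], atol=1e-12)

    def test_size_mismatch_rejected(self):
        with pytest.raises(NetworkError):
            ox.forward(random_net([3, 2]), np.zeros(4))


class TestLoss:
    def test_perfect_outputs_zero_loss(self):
        net = random_net([2, 1], sigma=0.0)  # outputs 0.5 everywhere
        assert ox.loss(net, np.zeros((3, 2)), np.full((3, 1), 0.5)) == pytest.approx(0.0)

    def test_half_vs_one_quarter(self):
        net = random_net([2, 1], sigma=0.0)
        assert ox.loss(net, np.zeros((1, 2)), np.ones((1, 1))) == pytest.approx(0.25)

    def test_zero_weights_zero_penalty(self):
        net = random_net([2, 2], sigma=0.0)
        with_reg = ox.loss(net, np.zeros((1, 2)), np.full((1, 2), 0.5), lam=10.0)
        assert with_reg == pytest.approx(0.0)

    def test_penalty_excludes_biases(self):
        net = random_net([2, 1], sigma=0.0)
        net.biases[0][:] = 100.0
        base = ox.loss(net, np.zeros((1, 2)), np.ones((1, 1)), lam=0.0)
        reg = ox.loss(net, np.zeros((1, 2)), np.ones((1, 1)), lam=1.0)
        assert reg == pytest.approx(base)  # big biases add nothing


class TestGradients:
    @pytest.mark.parametrize("lam", [0.0, 3e-7, 1e-2])
    def test_backprop_matches_central_differences(self, lam, rng):
        net = random_net([4, 3, 2], seed=5)
        x, y = rng.normal(size=4), rng.random(2)
        gw, gb = _gradients(net, x, y, lam)
        eps = 1e-6
        for l in range(len(net.weights)):
            for idx in np.ndindex(net.weights[l].shape):
                orig = net.weights[l][idx]
                net.weights[l][idx] = orig + eps
                up = ox.loss(net, x[None], y[None], lam)
                net.weights[l][idx] = orig - eps
                dn = ox.loss(net, x[None], y[None], lam)
                net.weights[l][idx] = orig
                assert gw[l][idx] == pytest.approx((up - dn) / (2 * eps), abs=1e-7)
            for i in range(len(net.biases[l])):
                orig = net.biases[l][i]
                net.biases[l][i] = orig + eps
                up = ox.loss(net, x[None], y[None], lam)
                net.biases[l][i] = orig - eps
                dn = ox.loss(net, x[None], y[None], lam)
                net.biases[l][i] = orig
                assert gb[l][i] == pytest.approx((up - dn) / (2 * eps), abs=1e-7)


class TestSGDStep:
    def test_plain_gradient_step_hand_computed(self):
        # 1-1 net, x=0 so only the bias gradient is active:
        # out = sigmoid(b); E = (out - y)^2; check b' = b - eta * dE/db
        net = random_net([1, 1], sigma=0.0)
        y = np.array([1.0])
        out = 0.5
        grad_b = 2 * (out - 1.0) * out * (1 - out)
        net2, _ = ox.sgd_step(net.copy(), None, (np.array([0.0]), y), eta=0.1, alpha=0.0)
        assert net2.biases[0][0] == pytest.approx(-0.1 * grad_b)

    def test_eta_zero_keeps_parameters_scales_velocity(self, rng):
        net = random_net([3, 2], seed=1)
        w_before = net.weights[0].copy()
        vel = ([np.ones((2, 3))], [np.ones(2)])
        net2, (vw, _) = ox.sgd_step(net, vel, (rng.normal(size=3), rng.random(2)),
                                    eta=0.0, alpha=0.5)
        np.testing.assert_allclose(net2.weights[0], w_before + 0.5)  # momentum only
        np.testing.assert_allclose(vw[0], 0.5)

    def test_momentum_accumulates_previous_update(self, rng):
        net = random_net([2, 2], seed=2)
        sample = (rng.normal(size=2), rng.random(2))
        netA = net.copy()
        netA, vel = ox.sgd_step(netA, None, sample, eta=0.1, alpha=0.9)
        first_update = vel[0][0].copy()
        netA, vel = ox.sgd_step(netA, vel, sample, eta=0.0, alpha=0.9)
        np.testing.assert_allclose(vel[0][0], 0.9 * first_update)


class TestTrain:
    def test_eta_zero_alpha_zero_leaves_network_unchanged(self, rng):
        net = random_net([3, 2], seed=4)
        X, Y = rng.normal(size=(4, 3)), rng.random((4, 2))
        cfg = ox.TrainingConfig(eta0=0.0, alpha0=0.0, epochs=1, seed=0)
        trained, _ = ox.train(net, X, Y, cfg)
        np.testing.assert_array_equal(trained.weights[0], net.weights[0])

    def test_toy_problem_loss_decreases(self, rng):
        net = random_net([2, 3, 1], seed=7, sigma=0.1)
        X = np.array([[0.0, 1.0], [1.0, 0.0]])
        Y = np.array([[0.0], [1.0]])
        cfg = ox.TrainingConfig(eta0=2.0, alpha0=0.5, decay=0.999, epochs=500, seed=1)
        _, trace = ox.train(net, X, Y, cfg)
        assert trace[-1] < trace[0]

    def test_fixed_seed_identical_trace(self, rng):
        net = random_net([3, 2], seed=0)
        X, Y = rng.normal(size=(5, 3)), rng.random((5, 2))
        cfg = ox.TrainingConfig(eta0=0.5, alpha0=0.3, epochs=5, seed=9)
        _, t1 = ox.train(net, X, Y, cfg)
        _, t2 = ox.train(net, X, Y, cfg)
        assert t1 == t2

    def test_weight_norm_non_increasing_in_lambda(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        Y = np.array([[0.0], [1.0], [1.0]])
        norms = []
        for lam in (0.0, 1e-3, 1e-1):
            net = random_net([2, 3, 1], seed=3, sigma=0.1)
            cfg = ox.TrainingConfig(eta0=1.0, alpha0=0.3, decay=0.999, lam=lam,
                                    epochs=300, seed=2)
            trained, _ = ox.train(net, X, Y, cfg)
            norms.append(sum(float((W ** 2).sum()) for W in trained.weights))
        assert norms[0] >= norms[1] >= norms[2]


class TestAutoencoder:
    def test_structure_five_layers_bottleneck_30(self):
        spec = ox.autoencoder_spec()
        assert spec.layer_sizes == [212, 85, 30, 85, 212]
        assert spec.n_layers == 5

    def test_encoder_outputs_bottleneck_dimension(self, rng):
        X = rng.random((10, 8))
        cfg = ox.TrainingConfig(eta0=0.5, epochs=2, seed=0)
        enc, full, _ = ox.train_autoencoder(X, ox.NetworkSpec([8, 4, 2, 4, 8]), cfg)
        assert ox.encode(enc, X).shape == (10, 2)

    def test_asymmetric_spec_rejected(self, rng):
        with pytest.raises(NetworkError):
            ox.train_autoencoder(rng.random((4, 8)), ox.NetworkSpec([8, 4, 8, 8]),
                                 ox.TrainingConfig(eta0=0.1, epochs=1))

    def test_beats_constant_predictor_on_low_rank_data(self, rng):
        # rank-2 inputs must reconstruct better than predicting the mean
        basis = rng.random((2, 8))
        X = np.clip(rng.random((40, 2)) @ basis, 0, 1)
        cfg = ox.TrainingConfig(eta0=2.0, alpha0=0.5, decay=0.999, epochs=400, seed=1)
        _, full, trace = ox.train_autoencoder(X, ox.NetworkSpec([8, 4, 2, 4, 8]), cfg)
        const_mse = float(((X - X.mean(axis=0)) ** 2).mean())
        assert trace[-1] < const_mse

    def test_repeated_vector_is_memorized(self):
        X = np.tile(np.array([0.2, 0.8, 0.4, 0.6]), (20, 1))
        cfg = ox.TrainingConfig(eta0=2.0, alpha0=0.5, decay=0.999, epochs=300, seed=0)
        _, full, _ = ox.train_autoencoder(X, ox.NetworkSpec([4, 3, 1, 3, 4]), cfg)
        recon = ox.forward_batch(full, X[:1])
        np.testing.assert_allclose(recon[0], X[0], atol=0.05)


class TestAssembly:
    def test_six_layer_structure(self):
        enc = random_net([212, 85, 30])
        mapper = random_net([30, 50, 20, 20])
        assembled = ox.assemble_predictor(enc, mapper)
        assert assembled.spec.layer_sizes == [212, 85, 30, 50, 20, 20]
        assert assembled.spec.n_layers == 6

    def test_composition_is_exact(self, rng):
        enc = random_net([6, 4, 3], seed=1)
        mapper = random_net([3, 5, 2], seed=2)
        assembled = ox.assemble_predictor(enc, mapper)
        x = rng.normal(size=6)
        composed = ox.forward(mapper, ox.forward(enc, x)[-1])[-1]
        np.testing.assert_array_equal(ox.forward(assembled, x)[-1], composed)

    def test_size_mismatch_rejected(self):
        with pytest.raises(NetworkError):
            ox.assemble_predictor(random_net([4, 3]), random_net([2, 1]))

    def test_fine_tuning_moves_every_layer(self, rng):
        enc = random_net([6, 4, 3], seed=1)
        mapper = random_net([3, 5, 2], seed=2)
        assembled = ox.assemble_predictor(enc, mapper)
        X, Y = rng.random((8, 6)), (rng.random((8, 2)) < 0.5).astype(float)
        cfg = ox.TrainingConfig(eta0=1.0, alpha0=0.1, epochs=50, seed=3)
        tuned, _ = ox.train(assembled, X, Y, cfg)
        for W0, W1 in zip(assembled.weights, tuned.weights):
            assert not np.array_equal(W0, W1)


class TestThreshold:
    def test_perfectly_separated_scores(self):
        # steep 1-1 net: scores ~1 for positive inputs, ~0 for negative
        netp = random_net([1, 1], sigma=0.0)
        netp.weights[0][0, 0] = 10.0
        X = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        Y = np.array([[1.0], [1.0], [0.0], [0.0]])
        pred = ox.fit_threshold(netp, X, Y)
        out = pred.predict(X)
        np.testing.assert_array_equal(out, Y)

    def test_single_value_grid(self, rng):
        net = random_net([2, 1], seed=0)
        pred = ox.fit_threshold(net, rng.random((4, 2)),
                                (rng.random((4, 1)) < 0.5).astype(float),
                                grid=np.array([0.37]))
        assert pred.theta == 0.37

    def test_matches_exhaustive_search(self, rng):
        net = random_net([3, 4], seed=6, sigma=1.0)
        X = rng.normal(size=(20, 3))
        Y = (rng.random((20, 4)) < 0.3).astype(float)
        grid = np.round(np.arange(0.01, 1.0, 0.01), 2)
        pred = ox.fit_threshold(net, X, Y, grid)
        scores = ox.forward_batch(net, X).ravel()
        truth = Y.ravel().astype(bool)
        best, best_obj = None, -1
        for theta in grid:
            p = scores > theta
            tp = (p & truth).sum() / truth.sum()
            tn = (~p & ~truth).sum() / (~truth).sum()
            obj = (tp + tn) / 2
            if obj > best_obj:
                best, best_obj = theta, obj
        assert pred.theta == pytest.approx(best)

    def test_threshold_outside_unit_interval_rejected(self):
        with pytest.raises(NetworkError):
            ox.ThresholdedPredictor(random_net([1, 1]), 1.0)


class TestSerialization:
    def test_json_round_trip(self, tmp_path, rng):
        from odorlex.neuralnet import load_network, save_network

        net = random_net([4, 3, 2], seed=8)
        path = tmp_path / "net.json"
        save_network(net, path, config={"note": "test"})
        back = load_network(path)
        assert back.spec.layer_sizes == net.spec.layer_sizes
        for Wa, Wb in zip(net.weights, back.weights):
            np.testing.assert_array_equal(Wa, Wb)
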
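"""Model construction, training determinism, oracles, and metrics."""

import numpy as np
import pytest

import biovep as bv
from biovep import network as nn


class TestBuild:
    def test_lr_parameter_count(self):
        net = bv.build_model(bv.ModelConfig(family="LR"), (56, 40))
        assert net.n_parameters() == 56 * 40 + 1

    def test_cnn_valid_padding_output_length(self):
        cfg = bv.ModelConfig(family="CNN", kernel=5, filters=16, n_conv_layers=1,
                             head="flatten")
        net = bv.build_model(cfg, (56, 49))
        conv = net.layers[0]
        out = conv.forward(np.zeros((2, 56, 49)))
        assert out.shape == (2, 52, 16)  # 56 - 5 + 1

    def test_gcn_requires_matching_graph(self):
        cfg = bv.ModelConfig(family="GCN")
        with pytest.raises(ValueError):
            bv.build_model(cfg, (10, 40), graph=None)
        g = bv.ContactGraph(np.zeros((8, 8)), 7.0)
        with pytest.raises(ValueError):
            bv.build_model(cfg, (10, 40), graph=g)

    def test_gcn_edgeless_graph_is_per_residue_local(self, rng):
        """With an identity propagation matrix, node outputs depend only on
        that node's own input features."""
        g = bv.ContactGraph(np.zeros((6, 6)), 7.0)
        cfg = bv.ModelConfig(family="GCN", graph_channels=(8,), seed=1)
        net = bv.build_model(cfg, (6, 5), graph=g)
        gconv = net.layers[0]
        x = rng.normal(size=(3, 6, 5))
        base = gconv.forward(x)
        perturbed = x.copy()
        perturbed[:, 2, :] += 10.0
        out = gconv.forward(perturbed)
        changed = np.any(np.abs(out - base) > 1e-12, axis=(0, 2))
        np.testing.assert_array_equal(changed, [False, False, True, False, False, False])

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            bv.ModelConfig(family="transformer")


class TestGradients:
    """Finite-difference check of every layer's backward pass."""

    @pytest.mark.parametrize("family", ["LR", "NN", "CNN", "GCN"])
    def test_network_gradient_matches_finite_differences(self, family, rng):
        g = bv.ContactGraph((np.ones((7, 7)) - np.eye(7) > 0.5).astype(float), 7.0)
        cfg = bv.ModelConfig(family=family, hidden=(6,), filters=4, kernel=3,
                             n_conv_layers=1, graph_channels=(4,), dense_units=5,
                             dropout=0.0, seed=2)
        net = bv.build_model(cfg, (7, 5), graph=g if family == "GCN" else None)
        X = rng.normal(size=(4, 7, 5))
        y = rng.normal(size=4)

        def loss():
            return float(np.mean((net.forward(X) - y) ** 2))

        base = loss()
        net.backward(2.0 * (net.forward(X) - y) / len(y))
        eps = 1e-6
        for p, grad in zip(net.params, net.grads):
            flat = p.ravel()
            for k in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                old = flat[k]
                flat[k] = old + eps
                up = loss()
                flat[k] = old - eps
                down = loss()
                flat[k] = old
                fd = (up - down) / (2 * eps)
                assert grad.ravel()[k] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestTraining:
    def test_lr_matches_closed_form_least_squares(self, rng):
        """Gradient-trained LR converges to the ridgeless normal-equation
        solution on a small well-conditioned problem."""
        X = rng.normal(size=(60, 3, 4))
        w = rng.normal(size=12)
        y = X.reshape(60, -1) @ w + 0.7
        net = bv.build_model(bv.ModelConfig(family="LR", seed=0), (3, 4))
        # staged learning-rate annealing drives Adam to the exact optimum
        for lr in (0.05, 1e-3, 1e-5, 1e-7):
            nn.fit_network(net, X, y, X, y, learning_rate=lr, batch_size=60,
                           epochs=2000, patience=2000, seed=0)
        A = np.hstack([X.reshape(60, -1), np.ones((60, 1))])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(net.predict(X), A @ coef, atol=1e-6)

    def test_lr_recovers_noiseless_linear_fitness(self, rng):
        X = rng.normal(size=(120, 4, 5))
        w = rng.normal(size=20)
        y = X.reshape(120, -1) @ w
        cfg = bv.ModelConfig(family="LR", learning_rate=0.02, batch_size=32,
                             epochs=800, patience=800, seed=3)
        model = bv.train_model(cfg, X[:100], y[:100], X[100:], y[100:])
        r = np.corrcoef(y[:100], model.predict(X[:100]))[0, 1]
        assert r >= 0.999

    def test_training_deterministic_under_seed(self, rng):
        X = rng.normal(size=(80, 6, 5))
        y = rng.normal(size=80)
        cfg = bv.ModelConfig(family="NN", hidden=(8,), epochs=15, patience=15, seed=7)
        a = bv.train_model(cfg, X[:60], y[:60], X[60:], y[60:])
        b = bv.train_model(cfg, X[:60], y[:60], X[60:], y[60:])
        assert a.history.val_loss == b.history.val_loss
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_constant_scores_converge_with_undefined_correlation(self, rng):
        X = rng.normal(size=(40, 3, 4))
        y = np.full(40, 2.5)
        cfg = bv.ModelConfig(family="LR", epochs=20, patience=20, seed=0)
        model = bv.train_model(cfg, X[:30], y[:30], X[30:], y[30:])
        report = bv.evaluate_model(model, X[30:], y[30:])
        assert report.pearson is None and report.spearman is None
        assert np.isfinite(report.mae)

    def test_prediction_rejects_mismatched_width(self, rng):
        X = rng.normal(size=(40, 3, 4))
        y = rng.normal(size=40)
        cfg = bv.ModelConfig(family="LR", epochs=5, patience=5)
        model = bv.train_model(cfg, X[:30], y[:30], X[30:], y[30:])
        with pytest.raises(ValueError, match="shape"):
            model.predict(rng.normal(size=(5, 3, 5)))

    def test_prediction_invariant_to_test_order(self, rng):
        X = rng.normal(size=(50, 3, 4))
        y = rng.normal(size=50)
        cfg = bv.ModelConfig(family="NN", hidden=(6,), epochs=10, patience=10, seed=1)
        model = bv.train_model(cfg, X[:40], y[:40], X[40:], y[40:])
        perm = rng.permutation(10)
        np.testing.assert_allclose(
            model.predict(X[40:])[perm], model.predict(X[40:][perm]), atol=1e-12
        )


class TestEvaluation:
    def test_perfect_predictions(self):
        r = bv.evaluate_predictions(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4]))
        assert r.pearson == pytest.approx(1.0)
        assert r.spearman == pytest.approx(1.0)
        assert r.mae == 0.0

    def test_anticorrelated_predictions(self):
        y = np.array([1.0, 2, 3, 4])
        r = bv.evaluate_predictions(y, -(y - y.mean()))
        assert r.pearson == pytest.approx(-1.0)

    def test_hand_computed_mae(self):
        r = bv.evaluate_predictions(
            np.array([1.0, 2, 3, 4]), np.array([1.5, 1.5, 3.5, 3.5])
        )
        assert r.mae == pytest.approx(0.5)

    def test_mae_stratified_by_mutation_count(self):
        r = bv.evaluate_predictions(
            np.array([1.0, 2.0, 3.0, 4.0]),
            np.array([1.5, 2.5, 3.0, 4.0]),
            mutation_counts=[1, 1, 2, 2],
        )
        assert r.mae_by_mutation_count == {1: pytest.approx(0.5), 2: pytest.approx(0.0)}

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            bv.evaluate_predictions(np.array([]), np.array([]))


class TestExperimentHarness:
    def test_single_repeat_single_row_per_condition(self, world, dms, resources):
        df = bv.run_experiment(
            dms, resources, "random",
            with_biophysics_flags=(True,), families=("LR",),
            configs={"LR": bv.ModelConfig(family="LR", epochs=10, patience=10)},
            n_repeats=1,
        )
        assert len(df) == 1
        assert set(df.columns) >= {"scheme", "family", "biophysics", "seed",
                                   "pearson", "spearman", "mae"}

    def test_grid_search_selects_by_validation(self, dms, resources):
        # a deliberately crippled candidate (0 epochs of useful training)
        # must lose to a real one
        good = bv.ModelConfig(family="LR", learning_rate=5e-3, epochs=200, patience=200)
        bad = bv.ModelConfig(family="LR", epochs=1, patience=1, learning_rate=1e-9)
        df = bv.run_experiment(
            dms, resources, "random",
            with_biophysics_flags=(True,), families=("LR",),
            config_grid={"LR": [bad, good]}, n_repeats=1,
        )
        assert df["pearson"].iloc[0] > 0.3
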
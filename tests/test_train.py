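"""Training loop, detection rules and ensemble decision logic."""

import numpy as np
import pytest

from conftest import random_graph
from gmmconv.train import (DetectionResult, TrainConfig, accuracy,
                           build_architecture, detect, ensemble_detect_any,
                           ensemble_detect_max, evaluate_hit, mean_mse, train)
from gmmconv.transforms import RotationBank, rotation_bank


def tiny_training_set(rng, n_graphs=4, n_nodes=8):
    return [random_graph(rng, n_nodes, with_targets=True) for _ in range(n_graphs)]


class TestTrain:
    def test_zero_epochs_returns_initial_parameters(self, rng):
        graphs = tiny_training_set(rng)
        net = build_architecture("verification", seed=0)
        before = [a.copy() for a in net.param_arrays()]
        best, history = train(net, graphs[:3], graphs[3:],
                              TrainConfig(epochs=0, seed=0))
        assert history == []
        for a, b in zip(best.param_arrays(), before):
            assert np.array_equal(a, b)

    def test_history_records_eval_interval_epochs_exactly(self, rng):
        graphs = tiny_training_set(rng)
        net = build_architecture("verification", n_gaussians=1, seed=0)
        _, history = train(net, graphs[:3], graphs[3:],
                           TrainConfig(learning_rate=1e-3, epochs=120,
                                       eval_interval=50, seed=0))
        assert [h["epoch"] for h in history] == [50, 100]

    def test_training_reduces_mse_and_selects_best_val(self, rng):
        graphs = tiny_training_set(rng, n_graphs=6, n_nodes=10)
        net = build_architecture("verification", n_gaussians=2, seed=1)
        initial = mean_mse(net, graphs[:4])
        best, history = train(net, graphs[:4], graphs[4:],
                              TrainConfig(learning_rate=1e-2, epochs=60,
                                          eval_interval=20, seed=1))
        selected = [h for h in history if h["selected"]]
        assert len(selected) == 1
        assert selected[0]["val_mse"] == min(h["val_mse"] for h in history)
        assert mean_mse(best, graphs[:4]) <= initial

    def test_deterministic_given_seed(self, rng):
        graphs = tiny_training_set(rng)
        cfg = TrainConfig(learning_rate=1e-2, epochs=10, eval_interval=5, seed=3)
        b1, h1 = train(build_architecture("verification", n_gaussians=1, seed=2),
                       graphs[:3], graphs[3:], cfg)
        b2, h2 = train(build_architecture("verification", n_gaussians=1, seed=2),
                       graphs[:3], graphs[3:], cfg)
        assert h1 == h2
        for a, b in zip(b1.param_arrays(), b2.param_arrays()):
            assert np.array_equal(a, b)

    def test_missing_targets_rejected(self, rng):
        g = random_graph(rng, 5)
        net = build_architecture("verification", seed=0)
        with pytest.raises(ValueError):
            train(net, [g], [], TrainConfig(epochs=1))


class TestGradientCorrectness:
    def test_analytic_matches_central_differences(self, rng):
        """MSE gradients w.r.t. g, mu, variances and b on a 10-node graph."""
        g = random_graph(rng, 10, with_targets=True)
        net = build_architecture("verification", n_gaussians=2, seed=7)

        def loss():
            out = net.forward(g)[:, 0]
            return float(np.mean((out - g.targets) ** 2))

        out, state = net.forward_cached(g)
        grad_out = 2.0 * (out - g.targets[:, None]) / out.size
        grads = net.backward(grad_out, state)
        step = 1e-5
        worst = 0.0
        for li, layer in enumerate(net.layers):
            for ai, arr in enumerate(layer.param_arrays()):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + step
                    lp = loss()
                    arr[idx] = orig - step
                    lm = loss()
                    arr[idx] = orig
                    fd = (lp - lm) / (2 * step)
                    analytic = grads[li][ai][idx]
                    denom = max(abs(fd), abs(analytic), 1e-8)
                    worst = max(worst, abs(fd - analytic) / denom)
        assert worst < 1e-4


class TestDetect:
    def test_unique_maximum(self):
        out = np.zeros(10)
        out[7] = 3.0
        res = detect(out, np.arange(20).reshape(10, 2))
        assert res.node == 7
        assert res.score == 3.0
        assert np.array_equal(res.centroid, [14, 15])

    def test_all_equal_ties_to_node_zero(self):
        res = detect(np.ones(5), np.zeros((5, 2)))
        assert res.node == 0

    def test_matches_linear_scan(self, rng):
        out = rng.normal(size=40)
        res = detect(out, np.zeros((40, 2)))
        best = 0
        for i in range(40):
            if out[i] > out[best]:
                best = i
        assert res.node == best

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            detect(np.array([]), np.zeros((0, 2)))

    def test_invariant_to_constant_shift(self, rng):
        out = rng.normal(size=15)
        a = detect(out, np.zeros((15, 2)))
        b = detect(out + 123.4, np.zeros((15, 2)))
        assert a.node == b.node


class TestEvaluateHit:
    BBOX = (10, 20, 30, 50)  # rmin, cmin, rmax, cmax

    def test_center_hits(self):
        res = DetectionResult(0, np.array([20.0, 35.0]), 1.0)
        assert evaluate_hit(res, self.BBOX, enlargement=16.0)
        assert res.hit is True

    def test_near_boundary_within_enlargement(self):
        # sqrt(A)-1 = 15 pixels outside the tight box, A=256 -> hit
        res = DetectionResult(0, np.array([10.0 - 15.0, 35.0]), 1.0)
        assert evaluate_hit(res, self.BBOX, enlargement=16.0)
        # boundary of the enlarged box counts as inside
        res = DetectionResult(0, np.array([10.0 - 16.0, 35.0]), 1.0)
        assert evaluate_hit(res, self.BBOX, enlargement=16.0)

    def test_far_outside_misses(self):
        res = DetectionResult(0, np.array([90.0, 35.0]), 1.0)
        assert not evaluate_hit(res, self.BBOX, enlargement=16.0)


class TestEnsembleRules:
    @pytest.fixture
    def setup(self, rng):
        net = build_architecture("verification", seed=4)
        bank = rotation_bank(net, count=5)
        g = random_graph(rng, 12)
        return net, bank, g

    def test_singleton_bank_equals_single_detect(self, setup, rng):
        net, _, g = setup
        bank1 = rotation_bank(net, count=1)
        res = ensemble_detect_max(bank1, g)
        ref = detect(net.forward(g)[:, 0], g.centroids)
        assert (res.node, res.score) == (ref.node, ref.score)
        assert res.angle == 0.0

    def test_constant_outputs_tie_to_zero_angle_node_zero(self, rng):
        net = build_architecture("verification", seed=4)
        for layer in net.layers:
            layer.g[...] = 0.0
        net.layers[-1].b[:] = 1.0  # every network outputs constant 1
        bank = rotation_bank(net, count=5)
        g = random_graph(rng, 6)
        res = ensemble_detect_max(bank, g)
        assert res.angle == 0.0
        assert res.node == 0

    def test_winning_angle_tracks_graph_rotation(self, setup):
        from test_transforms import rotated_graph
        net, bank, g = setup
        base = detect(net.forward(g)[:, 0], g.centroids)
        theta_star = float(bank.angles[3])
        g_rot = rotated_graph(g, theta_star)
        res = ensemble_detect_max(bank, g_rot)
        # exact equivariance: the theta* network reproduces the base response
        assert res.score >= base.score - 1e-9
        if res.angle == theta_star:
            assert res.node == base.node

    def test_any_rule_dominates_max_rule(self, setup, rng):
        net, bank, _ = setup
        bbox = (0, 0, 30, 30)
        for _ in range(10):
            g = random_graph(rng, 10)
            g.centroids = rng.random((10, 2)) * 60
            rmax = ensemble_detect_max(bank, g)
            hit_max = evaluate_hit(rmax, bbox, enlargement=5.0)
            hit_any = ensemble_detect_any(bank, g, bbox, enlargement=5.0)
            assert hit_any >= hit_max

    def test_any_true_when_base_correct(self, setup, rng):
        net, bank, g = setup
        res = detect(net.forward(g)[:, 0], g.centroids)
        generous = (res.centroid[0], res.centroid[1], res.centroid[0],
                    res.centroid[1])
        assert ensemble_detect_any(bank, g, generous, enlargement=0.5)


class TestAccuracy:
    def test_fraction_and_recount(self, rng):
        assert accuracy([True] * 4) == 1.0
        assert accuracy([True, True, True, False]) == 0.75
        flags = list(rng.random(50) < 0.5)
        assert accuracy(flags) == sum(flags) / 50

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy([])


class TestArchitectures:
    def test_verification_shape(self):
        net = build_architecture("verification")
        assert [l.n_in for l in net.layers] == [1, 10]
        assert [l.n_out for l in net.layers] == [10, 1]
        assert [l.activation for l in net.layers] == ["relu", "identity"]
        assert net.param_count == 420

    def test_main_shape(self):
        net = build_architecture("main")
        assert [l.n_out for l in net.layers] == [20, 10, 5, 1]
        assert net.layers[-1].activation == "identity"
        assert all(l.activation == "relu" for l in net.layers[:-1])
        assert net.param_count == 5775

    def test_main_plus_adds_input_layer(self):
        net = build_architecture("main_plus")
        assert len(net.layers) == 5
        assert [l.n_out for l in net.layers] == [20, 20, 10, 5, 1]

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            build_architecture("resnet")
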
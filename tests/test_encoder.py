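"""Core/readout forward semantics, sampling rules, and gradient checks."""

import numpy as np
import pytest
from scipy.stats import pearsonr

import v1enc as v
from v1enc.encoder import CoreConfig, GaussianReadout, ModelParams, build_core, sample_position
from v1enc._nn import BatchNorm2d, Conv2d, DepthwiseConv2d


@pytest.fixture(scope="module")
def small_model():
    rng = np.random.default_rng(3)
    coords = rng.uniform(-1, 1, (5, 3))
    return ModelParams.init(CoreConfig(channels=(4, 5, 6, 6, 6)), {"s": coords}, seed=2)


class TestCore:
    def test_output_shape_and_channels(self):
        rng = np.random.default_rng(0)
        core = build_core(CoreConfig(), rng)
        x = rng.normal(size=(2, 6, 144, 256)).astype(np.float32)
        out = core.forward(x, training=False)
        assert out.shape == (2, 256, 36, 64)
        x2 = rng.normal(size=(2, 6, 36, 64)).astype(np.float32)
        assert core.forward(x2, training=False).shape == (2, 256, 9, 16)

    def test_zero_weights_identity_bn_gives_zero(self):
        core = build_core(CoreConfig(channels=(4, 4, 4, 4, 4)), np.random.default_rng(0))
        for layer in core.layers:
            if isinstance(layer, (Conv2d, DepthwiseConv2d)):
                layer.W.value[...] = 0.0
                layer.b.value[...] = 0.0
        x = np.random.default_rng(1).normal(size=(1, 6, 36, 64)).astype(np.float32)
        out = core.forward(x, training=False)  # running stats are identity at init
        assert np.allclose(out, 0.0)

    def test_wrong_input_shape_rejected(self):
        core = build_core(CoreConfig(), np.random.default_rng(0))
        with pytest.raises(ValueError):
            v.core_forward(np.zeros((1, 3, 36, 64), dtype=np.float32), core)


class TestReadoutPosition:
    def test_zero_network_maps_to_origin(self):
        r = GaussianReadout(np.zeros((3, 3)), 8, np.random.default_rng(0))
        r.fc1.W.value[...] = 0; r.fc1.b.value[...] = 0
        r.fc2.W.value[...] = 0; r.fc2.b.value[...] = 0
        assert np.allclose(r.positions_mu(), 0.0)

    def test_outputs_strictly_inside_unit_square(self):
        rng = np.random.default_rng(1)
        r = GaussianReadout(rng.uniform(-1, 1, (40, 3)), 8, rng)
        mu = r.positions_mu()
        assert np.all(np.abs(mu) < 1.0)

    def test_hand_computed_forward(self):
        r = GaussianReadout(np.array([[0.5, -0.5, 1.0]]), 4, np.random.default_rng(0))
        r.fc1.W.value[...] = 0.0
        r.fc1.W.value[0, 0] = 1.0   # hidden0 = elu(0.5) = 0.5
        r.fc1.W.value[2, 1] = -2.0  # hidden1 = elu(-2)
        r.fc1.b.value[...] = 0.0
        r.fc2.W.value[...] = 0.0
        r.fc2.W.value[0, 0] = 2.0
        r.fc2.W.value[1, 1] = 1.0
        r.fc2.b.value[...] = 0.0
        mu = v.readout_position(np.array([[0.5, -0.5, 1.0]]), r)
        want_x = np.tanh(2.0 * 0.5)
        want_y = np.tanh(np.expm1(-2.0))
        assert mu[0, 0] == pytest.approx(want_x, rel=1e-6)
        assert mu[0, 1] == pytest.approx(want_y, rel=1e-6)


class TestSamplePosition:
    def test_eval_returns_mu(self):
        mu = np.array([[0.3, -0.7]])
        out = sample_position(mu, np.eye(2), training=False)
        assert np.array_equal(out, mu)

    def test_zero_spread_returns_mu_in_training(self):
        mu = np.array([[0.3, -0.7]])
        out = sample_position(mu, np.zeros((2, 2)), training=True, rng=np.random.default_rng(0))
        assert np.allclose(out, mu)

    def test_monte_carlo_mean(self):
        mu = np.array([0.1, -0.2])
        sigma = np.array([[0.05, 0.01], [0.0, 0.04]])
        rng = np.random.default_rng(7)
        samples = np.stack(
            [sample_position(mu, sigma, training=True, rng=rng)[0] for _ in range(20000)]
        )
        se = samples.std(axis=0) / np.sqrt(len(samples))
        assert np.all(np.abs(samples.mean(axis=0) - mu) < 3 * se + 1e-4)

    def test_samples_are_clamped(self):
        mu = np.array([[0.99, -0.99]])
        rng = np.random.default_rng(1)
        s = np.stack([sample_position(mu, 0.5 * np.eye(2), training=True, rng=rng)[0] for _ in range(200)])
        assert s.max() <= 1.0 and s.min() >= -1.0


class TestReadoutForward:
    def test_constant_feature_map_is_position_independent(self):
        features = np.full((4, 9, 16), 2.5, dtype=np.float32)
        w = np.array([0.25, 0.25, 0.25, 0.25])
        a = v.readout_forward(features, np.array([0.0, 0.0]), w, 0.0)
        b = v.readout_forward(features, np.array([-0.73, 0.41]), w, 0.0)
        assert a == pytest.approx(b, rel=1e-6)
        assert a == pytest.approx(2.5 + 1.0, rel=1e-6)

    def test_always_positive(self):
        rng = np.random.default_rng(2)
        features = rng.normal(size=(4, 9, 16)).astype(np.float32)
        for _ in range(20):
            pos = rng.uniform(-1, 1, 2)
            out = v.readout_forward(features, pos, rng.normal(size=4), float(rng.normal()))
            assert out > 0

    def test_midpoint_interpolates_the_average(self):
        features = np.zeros((1, 3, 3), dtype=np.float32)
        features[0] = [[0, 0, 0], [4, 8, 0], [0, 0, 0]]
        # midway between nodes (1,0) and (1,1): y=0 row is the middle row
        pos = np.array([-0.5, 0.0])  # gx = 0.5, gy = 1.0
        out = v.readout_forward(features, pos, np.array([1.0]), 0.0)
        assert out == pytest.approx((4 + 8) / 2 + 1.0, rel=1e-6)


class TestModelForward:
    def test_positive_and_deterministic_in_eval(self, small_model):
        x = np.random.default_rng(5).normal(size=(3, 6, 16, 24)).astype(np.float32)
        a = v.model_forward(x, small_model, "s")
        b = v.model_forward(x, small_model, "s")
        assert np.all(a > 0)
        assert np.array_equal(a, b)

    def test_unknown_subject_rejected(self, small_model):
        with pytest.raises(KeyError, match="subject"):
            v.model_forward(np.zeros((1, 6, 16, 24), dtype=np.float32), small_model, "nope")

    def test_untrained_model_has_near_zero_correlation(self, recovery_dataset):
        dataset, _, _ = recovery_dataset
        model = ModelParams.init(
            CoreConfig(), {dataset.subject_id: v.normalize_coordinates(dataset.coords)}, seed=99
        )
        idx = dataset.indices("final_test")
        preds = v.predict(model, v.prepare_inputs(dataset)[idx], dataset.subject_id)
        resp = v.standardize_responses(dataset.responses[idx], dataset.response_std)
        table = v.table_from_trials(resp, dataset.repeat_ids[idx], preds)
        r, mean = v.correlation_to_average(table)
        assert abs(mean) < 0.1

    def test_checkpoint_round_trip(self, small_model, tmp_path):
        x = np.random.default_rng(6).normal(size=(2, 6, 16, 24)).astype(np.float32)
        want = small_model.forward(x, "s")
        small_model.save(tmp_path / "ckpt.npz")
        loaded = ModelParams.load_checkpoint(tmp_path / "ckpt.npz")
        got = loaded.forward(x, "s")
        assert np.allclose(got, want, atol=1e-6)


class TestGradients:
    def test_backprop_matches_finite_differences(self, small_model):
        m = small_model
        rng0 = np.random.default_rng(4)
        x = rng0.normal(size=(2, 6, 8, 12)).astype(np.float32)
        r = rng0.uniform(0.5, 2.0, size=(2, 5))

        def run(grad=False):
            out = m.forward(x, "s", training=True, rng=np.random.default_rng(11))
            o = out.astype(np.float64)
            if grad:
                for p in m.params():
                    p.zero_grad()
                m.backward(((1.0 - r / o) / o.size).astype(np.float32), "s")
            return float((o - r * np.log(o)).mean())

        run(grad=True)
        grads = [p.grad.copy() for p in m.params()]
        rng = np.random.default_rng(0)
        checked = 0
        for p, g in zip(m.params(), grads):
            flat = p.value.ravel()
            for _ in range(3):
                i = rng.integers(flat.size)
                ana = g.ravel()[i]
                old = flat[i]
                flat[i] = old + 1e-3
                lp = run()
                flat[i] = old - 1e-3
                lm = run()
                flat[i] = old
                num = (lp - lm) / 2e-3
                if max(abs(num), abs(ana)) < 5e-5:
                    continue  # below float32 finite-difference noise
                checked += 1
                assert abs(num - ana) / max(abs(num), abs(ana)) < 0.2, (p.value.shape, num, ana)
        assert checked > 20


class TestParameterRecovery:
    def test_learned_centers_track_ground_truth(self, recovery_run):
        """After training on noiseless synthetic data the readout's mu should
        recover the generative receptive-field centers on both axes."""
        dataset, truth, model, _ = recovery_run
        mu = model.readouts[dataset.subject_id].positions_mu()
        for axis in (0, 1):
            r = pearsonr(mu[:, axis], truth.rf_center[:, axis]).statistic
            assert r >= 0.8
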
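"""Classifier training, inference and persistence contracts.

Unit tests use deliberately small networks and window sets; the full
training protocol is exercised in the acceptance suite.
"""

import numpy as np
import pytest

from dlmss import trajsim as ts
from dlmss.exceptions import (
    CompatibilityError,
    DegenerateDataError,
    TooShortError,
    ValidationError,
)
from dlmss.features import FeatureConfig, make_windows
from dlmss.nn import BiLSTM, cross_entropy
from dlmss.segmenter import ModelConfig, evaluate_splits, load_model, save_model, train


def two_state_model(d_fast=10.0, d_slow=1e-4):
    """Trivially separable: fast diffusion vs essentially frozen, no switching."""
    return ts.SwitchingModel(
        states=(
            ts.MotionState(label=0, kind="brownian", D=d_fast),
            ts.MotionState(label=1, kind="brownian", D=d_slow),
        ),
        Pi=np.eye(2),
        min_len=26,
    )


def window_pool(model, n_windows, seed):
    rng = np.random.default_rng(seed)
    pool = []
    while len(pool) < n_windows:
        for t in ts.simulate_dataset(model, ts.FbmParams(), 200, rng):
            pool.extend(make_windows(t))
    return pool[:n_windows]


SMALL = dict(hidden_units=24, max_epochs=12, learning_rate=1e-2, batch_size=64)


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        net = BiLSTM(3, 5, 3, rng, dtype=np.float64)
        X = rng.standard_normal((2, 6, 3))
        y = rng.integers(0, 3, (2, 6))
        _, grads = net.loss_and_grads(X, y)
        eps = 1e-6
        for name, P in net.params.items():
            for _ in range(5):
                idx = tuple(rng.integers(0, s) for s in P.shape)
                orig = P[idx]
                P[idx] = orig + eps
                lp = cross_entropy(net.forward(X), y)
                P[idx] = orig - eps
                lm = cross_entropy(net.forward(X), y)
                P[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, abs=1e-5), name


class TestTrain:
    def test_separable_two_state_data_is_learned(self):
        pool = window_pool(two_state_model(), 1000, seed=1)
        cfg = ModelConfig(n_classes=2, seed=3, **SMALL)
        model, (tr, va, te) = train(pool[:600], pool[600:800], pool[800:], cfg)
        # a bare step-length threshold already separates these states
        steps = np.concatenate([w.features[:, 0] for w in pool[800:]])
        labels = np.concatenate([w.labels for w in pool[800:]])
        thr_acc = max(
            np.mean((steps > t) == (labels == 0)) for t in (0.05, 0.1, 0.2)
        )
        assert thr_acc > 0.99
        assert te > 0.99

    def test_shuffled_labels_fall_to_chance(self):
        pool = window_pool(ts.three_state_model(), 700, seed=2)
        rng = np.random.default_rng(0)
        for w in pool:
            w.labels = rng.integers(0, 3, size=len(w.labels))
        cfg = ModelConfig(n_classes=3, seed=3, **SMALL)
        _, (_, _, te) = train(pool[:400], pool[400:550], pool[550:], cfg)
        assert te == pytest.approx(1 / 3, abs=0.02)

    def test_single_class_training_rejected(self):
        pool = window_pool(two_state_model(), 120, seed=3)
        only0 = [w for w in pool if np.all(w.labels == 0)][:60]
        cfg = ModelConfig(n_classes=2, **SMALL)
        with pytest.raises(DegenerateDataError):
            train(only0[:40], only0[40:], None, cfg)

    def test_inconsistent_feature_dims_rejected(self):
        pool = window_pool(two_state_model(), 60, seed=4)
        pool[3].features = pool[3].features[:, :4]
        with pytest.raises(ValidationError):
            train(pool[:40], pool[40:], None, ModelConfig(n_classes=2, **SMALL))

    def test_split_pool_too_small(self):
        pool = window_pool(two_state_model(), 50, seed=5)
        with pytest.raises(DegenerateDataError):
            evaluate_splits(pool, ModelConfig(n_classes=2, **SMALL), n_splits=1,
                            sizes=(40, 10, 10))


@pytest.fixture(scope="module")
def tiny_model():
    pool = window_pool(two_state_model(), 700, seed=6)
    cfg = ModelConfig(n_classes=2, seed=1, **SMALL)
    model, accs = train(pool[:500], pool[500:600], pool[600:], cfg)
    return model


class TestPredict:
    def test_output_shapes_and_probability_rows(self, tiny_model, rng):
        track = ts.simulate_track(two_state_model(), ts.FbmParams(), rng, n_frames=137)
        labels, probs = tiny_model.predict(track.positions)
        assert labels.shape == (136,)
        assert probs.shape == (136, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)
        points = tiny_model.predict_points(track.positions)
        assert points.shape == (137,)
        assert points[-1] == labels[-1]

    def test_deterministic_and_translation_invariant(self, tiny_model, rng):
        track = ts.simulate_track(two_state_model(), ts.FbmParams(), rng, n_frames=80)
        l1, p1 = tiny_model.predict(track.positions)
        l2, p2 = tiny_model.predict(track.positions)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(p1, p2)
        l3, _ = tiny_model.predict(track.positions + np.array([123.4, -56.7]))
        np.testing.assert_array_equal(l1, l3)

    def test_too_short_rejected(self, tiny_model):
        with pytest.raises(TooShortError):
            tiny_model.predict(np.zeros((1, 2)))

    def test_separable_track_recall(self, tiny_model, rng):
        """Single-state tracks are labeled almost entirely correctly."""
        for lab, D in ((0, 10.0), (1, 1e-4)):
            model = two_state_model()
            track = ts.simulate_track(model, ts.FbmParams(), rng, n_frames=200, init=lab)
            labels, _ = tiny_model.predict(track.positions)
            assert np.mean(labels == lab) >= 0.90


class TestPersistence:
    def test_roundtrip_bitwise(self, tiny_model, rng, tmp_path):
        path = tmp_path / "model.npz"
        save_model(tiny_model, path)
        reloaded = load_model(path)
        track = ts.simulate_track(two_state_model(), ts.FbmParams(), rng, n_frames=60)
        l1, p1 = tiny_model.predict(track.positions)
        l2, p2 = reloaded.predict(track.positions)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(p1, p2)
        assert reloaded.feature_config == tiny_model.feature_config

    def test_corrupt_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.npz"
        bad.write_bytes(b"not a model")
        with pytest.raises(CompatibilityError):
            load_model(bad)

    def test_tampered_metadata_rejected(self, tiny_model, tmp_path):
        import json

        path = tmp_path / "model.npz"
        save_model(tiny_model, path)
        data = dict(np.load(path, allow_pickle=False))
        meta = json.loads(bytes(data["meta_json"]).decode())
        meta["n_classes"] = 5  # now inconsistent with the stored weights
        data["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **data)
        with pytest.raises(CompatibilityError):
            load_model(path)
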
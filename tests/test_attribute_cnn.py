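"""Windowing, estimator architecture, training contracts, serialization."""
import numpy as np
import pytest

import zspose as z
from zspose.attribute_cnn import (
    CHANNELS_PER_SENSOR,
    EstimatorSpec,
    TrainConfig,
    _BatchNorm2D,
    _Conv2D,
    _Dense,
    build_estimator,
    estimate_attributes,
    estimator_spec,
    load_estimator,
    save_estimator,
    sliding_windows,
    train_estimator,
)
from zspose.attribute_space import AttributeSchema, JointSpec


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "T,expected",
        [(1800, 59), (60, 1), (89, 1), (90, 2), (120, 3)],
    )
    def test_window_counts(self, T, expected):
        wins = sliding_windows(np.zeros((T, 4)))
        assert wins.shape == (expected, 60, 4)

    def test_windows_are_half_open_shifted_ranges(self):
        x = np.arange(150)[:, None].astype(float)
        wins = sliding_windows(x)
        assert wins[0, 0, 0] == 0 and wins[0, -1, 0] == 59
        assert wins[1, 0, 0] == 30 and wins[2, 0, 0] == 60

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            sliding_windows(np.zeros((59, 4)))


class TestEstimatorSpecs:
    def test_default_schema_yields_14_specs(self, schema):
        specs = [estimator_spec(j) for j in schema]
        assert len(specs) == 14

    def test_hand_joints_get_wide_kernels(self, schema):
        for j in schema:
            spec = estimator_spec(j)
            if j.name.startswith("Ha"):
                assert spec.kernel == (3, 10)
            else:
                assert spec.kernel == (3, 3)
            assert spec.conv_channels == (25, 20, 15, 10)
            assert spec.fc_nodes == 100

    def test_head_and_loss_follow_joint_kind(self, schema):
        he = estimator_spec(schema.joint("He"))
        knee = estimator_spec(schema.joint("K(L)"))
        assert he.head == "softmax" and he.loss == "cross_entropy"
        assert knee.head == "sigmoid" and knee.loss == "mae"

    def test_too_few_channels_rejected(self):
        j = JointSpec("Ha(L)", "classification", ("a", "b", "c"), ("s",))
        with pytest.raises(ValueError, match="too few"):
            build_estimator(EstimatorSpec(j, kernel=(3, 10)), n_channels=10)


class TestUntrainedHeads:
    def test_classification_head_is_simplex(self):
        j = JointSpec("He", "classification", tuple("abcde"), ("s",))
        m = build_estimator(estimator_spec(j), n_channels=10, seed=1)
        rng = np.random.default_rng(0)
        p = m.predict(rng.normal(size=(7, 60, 10)))
        assert p.shape == (7, 5)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_regression_head_in_unit_interval(self):
        j = JointSpec("K(L)", "regression", (), ("s",))
        m = build_estimator(EstimatorSpec(j), n_channels=10, seed=1)
        rng = np.random.default_rng(0)
        p = m.predict(rng.normal(size=(5, 60, 10)) * 10)
        assert p.shape == (5,)
        assert np.all((p >= 0) & (p <= 1))


class TestLayerGradients:
    """Analytic backward passes vs float64 central differences."""

    @staticmethod
    def _check(layer, x, rng, tol=1e-6):
        x = x.astype(np.float64)
        out = layer.forward(x, train=True)
        dout = rng.normal(size=out.shape)
        dx = layer.backward(dout)
        eps = 1e-6
        v = rng.normal(size=x.shape)
        fd = (
            np.sum(layer.forward(x + eps * v, train=True) * dout)
            - np.sum(layer.forward(x - eps * v, train=True) * dout)
        ) / (2 * eps)
        assert abs(fd - np.sum(dx * v)) / (abs(fd) + 1e-9) < tol
        layer.forward(x, train=True)
        layer.backward(dout)
        for k, p in layer.params.items():
            g = layer.grads[k]
            vv = rng.normal(size=p.shape)
            p += eps * vv
            lp = np.sum(layer.forward(x, train=True) * dout)
            p -= 2 * eps * vv
            lm = np.sum(layer.forward(x, train=True) * dout)
            p += eps * vv
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - np.sum(g * vv)) / (abs(fd) + 1e-9) < tol

    def test_conv2d(self):
        rng = np.random.default_rng(0)
        c = _Conv2D(3, 4, 3, 3, rng)
        c.W = c.W.astype(np.float64)
        c.b = c.b.astype(np.float64)
        self._check(c, rng.normal(size=(2, 3, 8, 7)), rng)

    def test_batchnorm2d(self):
        rng = np.random.default_rng(1)
        b = _BatchNorm2D(3)
        for k in ("gamma", "beta", "run_mean", "run_var"):
            setattr(b, k, getattr(b, k).astype(np.float64))
        self._check(b, rng.normal(size=(4, 3, 5, 6)), rng, tol=1e-5)

    def test_dense(self):
        rng = np.random.default_rng(2)
        d = _Dense(7, 3, rng)
        d.W = d.W.astype(np.float64)
        d.b = d.b.astype(np.float64)
        self._check(d, rng.normal(size=(5, 7)), rng)


def _classification_fixture(rng, n_per_cat=60, n_cats=3):
    """Windows whose channel-0 mean level encodes the category."""
    X, y = [], []
    for k in range(n_cats):
        w = rng.normal(0, 0.3, size=(n_per_cat, 60, 10))
        w[:, :, 0] += k
        X.append(w)
        y += [k] * n_per_cat
    return np.concatenate(X).astype(np.float32), np.array(y)


class TestTraining:
    def test_separable_classification_recovered(self):
        rng = np.random.default_rng(4)
        X, y = _classification_fixture(rng)
        Xt, yt = _classification_fixture(np.random.default_rng(5))
        j = JointSpec("toy", "classification", ("a", "b", "c"), ("s",))
        m = build_estimator(estimator_spec(j), n_channels=10, seed=0)
        m, history = train_estimator(m, X, y, TrainConfig(epochs=15, batch_size=32, lr=0.02, seed=0))
        acc = (m.predict(Xt).argmax(axis=1) == yt).mean()
        assert acc > 0.9
        assert history[-1] < history[0]  # loss came down

    def test_regression_of_channel_mean(self):
        rng = np.random.default_rng(6)

        def make(rng, n=200):
            t = rng.random(n)
            X = rng.normal(0, 0.2, size=(n, 60, 10))
            X[:, :, 0] += t[:, None]
            return X.astype(np.float32), t

        X, t = make(rng)
        Xt, tt = make(np.random.default_rng(7))
        j = JointSpec("toy", "regression", (), ("s",))
        m = build_estimator(EstimatorSpec(j), n_channels=10, seed=0)
        m, history = train_estimator(m, X, t, TrainConfig(epochs=20, batch_size=32, lr=0.02, seed=0))
        mae = np.abs(m.predict(Xt) - tt).mean()
        assert mae < 0.1
        assert history[-1] < history[0]

    def test_training_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        X, y = _classification_fixture(rng, n_per_cat=10)
        preds = []
        for _ in range(2):
            j = JointSpec("toy", "classification", ("a", "b", "c"), ("s",))
            m = build_estimator(estimator_spec(j), n_channels=10, seed=3)
            train_estimator(m, X, y, TrainConfig(epochs=2, batch_size=16, seed=3))
            preds.append(m.predict(X[:5]))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_zero_epochs_keeps_valid_heads(self):
        rng = np.random.default_rng(9)
        X, y = _classification_fixture(rng, n_per_cat=5)
        j = JointSpec("toy", "classification", ("a", "b", "c"), ("s",))
        m = build_estimator(estimator_spec(j), n_channels=10, seed=0)
        train_estimator(m, X, y, TrainConfig(epochs=0))
        p = m.predict(X[:4])
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_degenerate_training_sets_rejected(self):
        j = JointSpec("toy", "classification", ("a", "b"), ("s",))
        m = build_estimator(estimator_spec(j), n_channels=10, seed=0)
        with pytest.raises(ValueError, match="empty"):
            m.fit(np.empty((0, 60, 10)), np.empty(0))
        with pytest.raises(ValueError, match="single category"):
            m.fit(np.zeros((4, 60, 10)), np.zeros(4))


@pytest.fixture(scope="module")
def toy_setup(defs):
    """Two-joint schema + estimators trained on a tiny synthetic corpus."""
    schema = AttributeSchema(
        (
            JointSpec("He", "classification", ("up", "down", "left", "right", "front"),
                      ("head",)),
            JointSpec("K(L)", "regression", (), ("upperleg_l", "lowerleg_l")),
        )
    )
    var = z.VariationSpec()
    classes = ["Standing", "Squatting", "Waist twisting (L)"]
    recs = []
    for i, c in enumerate(classes):
        for r in range(2):
            recs.append(
                z.generate_imu_recording(c, defs, var, duration_s=4, seed=10 * i + r,
                                         schema=schema)
            )
    from zspose.attribute_cnn import train_all_estimators

    models = train_all_estimators(
        recs, defs, schema, TrainConfig(epochs=5, batch_size=16, lr=0.02, seed=0)
    )
    return schema, models


class TestEstimateAttributes:
    def test_output_shape_and_invariants(self, toy_setup, defs):
        schema, models = toy_setup
        rec = z.generate_imu_recording("Squatting", defs, z.VariationSpec(),
                                       duration_s=30, seed=77, schema=schema)
        A = estimate_attributes(models, rec, schema)
        assert A.shape == (59, schema.D)  # 59 windows in 30 s
        for v in A:
            z.validate_attribute_vector(v, schema)

    def test_majority_argmax_matches_definition(self, toy_setup, defs):
        schema, models = toy_setup
        rec = z.generate_imu_recording("Waist twisting (L)", defs, z.VariationSpec(),
                                       duration_s=6, seed=78, schema=schema)
        A = estimate_attributes(models, rec, schema)
        he = schema.joint("He")
        pred_cats = [he.categories[i] for i in A[:, schema.slices["He"]].argmax(axis=1)]
        # left-facing head should dominate the estimates
        assert np.mean([c == "left" for c in pred_cats]) > 0.5

    def test_missing_estimator_rejected(self, toy_setup, defs):
        schema, models = toy_setup
        rec = z.generate_imu_recording("Standing", defs, z.VariationSpec(),
                                       duration_s=2, seed=79, schema=schema)
        with pytest.raises(KeyError, match="He"):
            estimate_attributes({"K(L)": models["K(L)"]}, rec, schema)


class TestSerialization:
    def test_save_load_round_trip(self, toy_setup, tmp_path):
        schema, models = toy_setup
        m = models["He"]
        save_estimator(m, tmp_path / "he")
        back = load_estimator(tmp_path / "he")
        rng = np.random.default_rng(0)
        X = rng.normal(size=(3, 60, 10)).astype(np.float32)
        np.testing.assert_allclose(back.predict(X), m.predict(X), atol=1e-6)
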
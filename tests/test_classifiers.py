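import numpy as np
import pytest

from residuemap.calibration import DEFAULT_ORDER, DEFAULT_THRESHOLD
from residuemap.classifiers import (
    CNN_DEFAULTS,
    RF_DT1_DEFAULTS,
    RF_OID_DEFAULTS,
    SVM_DEFAULTS,
    predict_map,
    train_classifier,
)
from residuemap.multiscale import DT1_FEATURES, OID_FEATURES, FeatureStack
from residuemap.nn import (
    AttentionBlock,
    NetworkConfig,
    cam_forward,
    init_params,
    network_forward,
)


def _separable(rng, n=200, n_feat=5):
    centers = np.array([[4.0] * n_feat, [-4.0] * n_feat])
    y = rng.integers(1, 3, size=n)
    X = centers[y - 1] + rng.normal(0, 0.3, size=(n, n_feat))
    return X, y


def _table(stack, df):
    return stack.sample_table(df["row"].to_numpy(), df["col"].to_numpy())


class TestTrainClassifier:
    @pytest.mark.parametrize("method", ["nb", "rf", "svm", "cnn", "cnn_ca"])
    def test_linearly_separable_perfect_accuracy(self, method, rng):
        X, y = _separable(rng)
        cfg = None
        if method in ("cnn", "cnn_ca"):
            cfg = NetworkConfig.fast(5, 2, epochs=10, seed=0)
        hp = {"n_estimators": 50, "max_depth": 10} if method == "rf" else cfg
        model = train_classifier(method, X[:140], y[:140], config=hp, seed=0)
        assert (model.predict(X[140:]) == y[140:]).mean() == 1.0

    def test_nan_features_rejected(self, rng):
        X, y = _separable(rng)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train_classifier("rf", X, y)

    def test_unknown_method_rejected(self, rng):
        X, y = _separable(rng)
        with pytest.raises(ValueError, match="unknown method"):
            train_classifier("knn", X, y)

    def test_rf_seeded_determinism(self, rng):
        X, y = _separable(rng, n=300)
        pred = [
            train_classifier(
                "rf", X[:200], y[:200],
                config={"n_estimators": 30, "max_depth": 8}, seed=4,
            ).predict(X[200:])
            for _ in range(2)
        ]
        assert np.array_equal(pred[0], pred[1])

    def test_cnn_seeded_determinism(self, rng):
        X, y = _separable(rng, n=120)
        pred = [
            train_classifier(
                "cnn_ca", X[:80], y[:80],
                config=NetworkConfig.fast(5, 2, epochs=5, seed=9), seed=9,
            ).predict(X[80:])
            for _ in range(2)
        ]
        assert np.array_equal(pred[0], pred[1])

    def test_svm_outperforms_nb_on_textured_scene(
        self, overlap_stack, overlap_samples
    ):
        from residuemap.metrics import evaluate

        sub = overlap_stack.subset(OID_FEATURES)
        tr, va = overlap_samples.train, overlap_samples.validation
        kappas = {}
        for method in ("svm", "nb"):
            model = train_classifier(
                method, _table(sub, tr), tr["label"].to_numpy(), seed=11
            )
            rep = evaluate(va["label"].to_numpy(), model.predict(_table(sub, va)))
            kappas[method] = rep.kappa
        assert kappas["svm"] > kappas["nb"]


class TestConfigurationDefaults:
    def test_random_forest_defaults(self):
        assert RF_OID_DEFAULTS == {
            "n_estimators": 1411, "max_depth": 281, "max_features": "sqrt",
        }
        assert RF_DT1_DEFAULTS == {
            "n_estimators": 1091, "max_depth": 381, "max_features": "auto",
        }

    def test_svm_defaults(self):
        assert SVM_DEFAULTS == {"C": 510.0, "kernel": "rbf", "gamma": "scale"}

    def test_network_defaults(self):
        cfg = NetworkConfig(n_f=9, n_class=4)
        assert cfg.epochs == 150
        assert cfg.batch_size == 20
        assert cfg.learning_rate == 0.01
        assert cfg.dropout == 0.4
        assert cfg.conv_filters == 512
        assert cfg.dense_widths == (2048, 1024)
        assert CNN_DEFAULTS == {
            "epochs": 150, "batch_size": 20, "learning_rate": 0.01, "dropout": 0.4,
        }

    def test_calibration_defaults(self):
        assert DEFAULT_ORDER == (2, 3, 1)
        assert DEFAULT_THRESHOLD == 60

    def test_feature_set_definitions(self):
        assert DT1_FEATURES == ("B_blue", "B_green", "B_red", "B_nir")
        assert OID_FEATURES == DT1_FEATURES + (
            "B_ms4", "B_ms8", "B_ms16", "B_ms32", "B_ms64",
        )


class TestChannelAttention:
    def test_identity_limit_when_gate_saturates(self, rng):
        F = rng.normal(size=(3, 9, 8))
        block = AttentionBlock(
            W1=np.zeros((8, 2)), b1=np.zeros(2),
            W2=np.zeros((2, 8)), b2=np.full(8, np.inf),
        )
        Fc = cam_forward(F, block)
        assert np.array_equal(Fc, F)  # M == 1 exactly

    def test_single_channel_identity_mlp_hand_computation(self):
        from scipy.special import expit

        v = 0.7
        F = np.full((1, 5, 1), v)
        block = AttentionBlock(
            W1=np.ones((1, 1)), b1=np.zeros(1),
            W2=np.ones((1, 1)), b2=np.zeros(1),
        )
        Fc, M = cam_forward(F, block, return_weights=True)
        assert np.isclose(M[0, 0], expit(2 * v))
        assert np.allclose(Fc, expit(2 * v) * F)

    def test_zero_input_gives_zero_output(self, rng):
        block = AttentionBlock.init(8, 2, rng)
        Fc = cam_forward(np.zeros((2, 4, 8)), block)
        assert (Fc == 0).all()

    def test_weights_strictly_inside_unit_interval(self, rng):
        block = AttentionBlock.init(16, 8, rng)
        _, M = cam_forward(rng.normal(size=(4, 9, 16)), block, return_weights=True)
        assert (M > 0).all() and (M < 1).all()

    def test_shape_mismatch_rejected(self, rng):
        block = AttentionBlock.init(8, 2, rng)
        with pytest.raises(ValueError, match="channel count"):
            cam_forward(rng.normal(size=(2, 4, 16)), block)


class TestNetworkForward:
    def test_published_layer_shapes(self):
        cfg = NetworkConfig(n_f=9, n_class=4, seed=0)
        x = np.random.default_rng(0).normal(size=(3, 9))
        probs, cache = network_forward(x, cfg)
        assert cache["F"].shape == (3, 9, 512)
        assert cache["flat"].shape == (3, 9 * 512)      # flattened width 4,608
        assert cache["logits"].shape == (3, 4)
        assert probs.shape == (3, 4)

    def test_softmax_rows_sum_to_one(self, rng):
        cfg = NetworkConfig.fast(7, 3, seed=1)
        probs, _ = network_forward(rng.normal(size=(20, 7)), cfg)
        assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-6

    def test_attention_off_equals_forced_identity_gate(self, rng):
        cfg_off = NetworkConfig.fast(6, 3, attention=False, seed=2)
        params = init_params(cfg_off)
        cfg_on = NetworkConfig.fast(6, 3, attention=True, seed=2)
        params_on = dict(params)
        params_on.update(
            att_W1=np.zeros((cfg_on.conv_filters, 8)), att_b1=np.zeros(8),
            att_W2=np.zeros((8, cfg_on.conv_filters)),
            att_b2=np.full(cfg_on.conv_filters, np.inf),
        )
        x = rng.normal(size=(5, 6))
        _, cache_off = network_forward(x, cfg_off, params)
        _, cache_on = network_forward(x, cfg_on, params_on)
        assert np.array_equal(cache_off["logits"], cache_on["logits"])

    def test_wrong_input_length_rejected(self, rng):
        cfg = NetworkConfig.fast(6, 3)
        with pytest.raises(ValueError, match="length 6"):
            network_forward(rng.normal(size=(2, 5)), cfg)


class TestPredictMap:
    def _stack_and_model(self, rng, r=12, c=10):
        layers = {
            "a": rng.normal(size=(r, c)),
            "b": rng.normal(size=(r, c)),
        }
        stack = FeatureStack(layers)
        labels = (layers["a"] > 0).astype(int) + 1
        X = stack.pixel_table()
        model = train_classifier(
            "rf", X, labels.ravel(),
            feature_names=("a", "b"),
            config={"n_estimators": 30, "max_depth": None}, seed=0,
        )
        return stack, model, labels

    def test_output_shape_and_memorization(self, rng):
        stack, model, labels = self._stack_and_model(rng)
        cmap, timing = predict_map(model, stack)
        assert cmap.labels.shape == stack.shape
        # forest trained to purity reproduces its training labels
        assert (cmap.labels == labels).mean() == 1.0
        assert timing.seconds >= 0

    def test_all_nodata_gives_all_zero(self, rng):
        stack, model, _ = self._stack_and_model(rng)
        cmap, _ = predict_map(model, stack, nodata_mask=np.ones(stack.shape, bool))
        assert (cmap.labels == 0).all()

    def test_missing_layer_rejected(self, rng):
        stack, model, _ = self._stack_and_model(rng)
        partial = FeatureStack({"a": stack.layers["a"]})
        with pytest.raises(KeyError, match="missing"):
            predict_map(model, partial)
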
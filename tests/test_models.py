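import numpy as np
import pytest

from crossgex import (
    TrainingConfig,
    build_cnn,
    build_knn,
    build_modified_autoencoder,
    build_naive_encoder,
    build_rrf,
    fit,
    pretrain_and_graft,
)
from crossgex.models import (
    AUTOENCODER_WIDTHS,
    NAIVE_ENCODER_WIDTHS,
    TrainedModel,
    _build_network,
    cnn_flat_dim,
    design_matrices,
)
from crossgex.nnet import AdamState, ConvGenes, Dense, Flatten, MaxPoolGenes, Network

FAST = TrainingConfig(epochs=3, batch_size=16, seed=0)


class TestNaiveEncoder:
    def test_hidden_widths(self):
        spec = build_naive_encoder(150, 150)
        assert spec.hyperparams["hidden"] == (256, 160, 32, 96, 256)

    def test_bottleneck_property(self):
        hidden = NAIVE_ENCODER_WIDTHS
        assert hidden[2] < min(hidden[1], hidden[3])

    def test_parameter_count_closed_form(self):
        # sum of (in*out + out) over all six dense layers
        spec = build_naive_encoder(150, 150)
        net = _build_network(spec, TrainingConfig(), np.random.default_rng(0))
        built = sum(getattr(layer, name).size for name, layer in net.parameters())
        dims = [150, 256, 160, 32, 96, 256, 150]
        expected = sum(a * b + b for a, b in zip(dims, dims[1:]))
        assert built == expected

    def test_bad_dims(self):
        with pytest.raises(ValueError):
            build_naive_encoder(0, 10)


class TestModifiedAutoencoder:
    def test_hidden_widths(self):
        spec = build_modified_autoencoder(150, 150)
        assert spec.hyperparams["hidden"] == (70, 70, 60, 70, 70)

    def test_graft_is_bit_for_bit(self, rng):
        x = rng.uniform(0, 1, size=(40, 24))
        y = rng.uniform(0, 1, size=(40, 30))
        cfg = TrainingConfig(epochs=2, batch_size=16, seed=3)
        grafted, src_ae, tgt_ae = pretrain_and_graft(x, y, cfg)
        gw = grafted.get_weights()
        sw = src_ae.get_weights()
        tw = tgt_ae.get_weights()
        # encoder half (3 dense layers = 6 arrays) from the source AE
        for i in range(6):
            np.testing.assert_array_equal(gw[i], sw[i])
        # decoder half + output from the target AE
        for i in range(6, 12):
            np.testing.assert_array_equal(gw[i], tw[i])

    def test_zero_pretrain_epochs_graft_is_random_init(self, rng):
        x = rng.uniform(0, 1, size=(10, 12))
        y = rng.uniform(0, 1, size=(10, 12))
        cfg = TrainingConfig(epochs=5, pretrain_epochs=0, seed=1)
        grafted, src_ae, _ = pretrain_and_graft(x, y, cfg)
        # with no pre-training the grafted encoder equals the source AE's
        # untouched random initialization
        np.testing.assert_array_equal(grafted.get_weights()[0], src_ae.get_weights()[0])

    def test_fit_runs_and_predicts_in_unit_interval(self, tiny_examples):
        spec = build_modified_autoencoder(24, 24)
        model = fit(spec, tiny_examples, FAST)
        x, _ = design_matrices(tiny_examples, spec.kind)
        pred = model.predict(x)
        assert pred.shape == (len(tiny_examples), 24)
        assert pred.min() >= 0.0 and pred.max() <= 1.0


class TestCnn:
    def test_shape_propagation_g50(self):
        # 50 -> 25 -> 12 -> 6 genes after three pool layers; 6*3*4 = 72 flat
        assert cnn_flat_dim(50, 3) == 72
        spec = build_cnn(50, 3, 150)
        net = _build_network(spec, TrainingConfig(), np.random.default_rng(0))
        out = net.forward(np.zeros((2, 50, 3, 1)))
        assert out.shape == (2, 150)
        flatten_idx = [i for i, l in enumerate(net.layers) if isinstance(l, Flatten)][0]
        dense_in = net.layers[flatten_idx + 1].W.shape[0]
        assert dense_in == 72

    def test_filter_counts(self):
        spec = build_cnn(76, 3, 228)
        assert spec.hyperparams["filters"] == (16, 8, 4)
        assert spec.hyperparams["kernels"] == (10, 10, 2)

    def test_matrix_input_76x3(self):
        spec = build_cnn(76, 3, 228)
        assert spec.input_shape == (76, 3)

    def test_small_gene_set_admissible(self):
        # same-padding keeps an 18-gene set valid through the 10-wide kernels
        spec = build_cnn(18, 3, 54)
        net = _build_network(spec, TrainingConfig(), np.random.default_rng(0))
        out = net.forward(np.zeros((1, 18, 3, 1)))
        assert out.shape == (1, 54)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="two genes"):
            build_cnn(1, 3, 3)

    def test_fit_and_predict(self, tiny_examples):
        spec = build_cnn(8, 3, 24)
        model = fit(spec, tiny_examples, FAST)
        x, y = design_matrices(tiny_examples, "cnn")
        pred = model.predict(x)
        assert pred.shape == y.shape
        assert pred.min() >= 0.0 and pred.max() <= 1.0


class TestKnn:
    def test_k1_memorizes(self, tiny_examples):
        # restrict to one target replicate so every source vector is unique
        unique = [e for e in tiny_examples if e.target_replicate == 1]
        model = fit(build_knn(k=1, output_dim=24), unique, FAST)
        ex = unique[5]
        pred = model.predict(ex.source.flat)
        np.testing.assert_allclose(pred[0], ex.target.flat, atol=1e-12)

    def test_k2_equidistant_mean(self):
        # two training points equidistant from the query: prediction is the
        # elementwise mean of their targets
        from crossgex.encoding import from_flat
        from crossgex.pairing import LearningExample

        src_a = from_flat(np.array([0.0, 0.0]), 2, compound="a", dose="low")
        src_b = from_flat(np.array([1.0, 1.0]), 2, compound="b", dose="low")
        tgt_a = from_flat(np.array([0.2, 0.4]), 2, compound="a", dose="low")
        tgt_b = from_flat(np.array([0.8, 0.6]), 2, compound="b", dose="low")
        examples = [
            LearningExample(src_a, tgt_a, "a", "low", 1, 1),
            LearningExample(src_b, tgt_b, "b", "low", 1, 1),
        ]
        model = fit(build_knn(k=2, output_dim=2), examples, FAST)
        pred = model.predict(np.array([0.5, 0.5]))
        np.testing.assert_allclose(pred[0], [0.5, 0.5], atol=1e-12)

    def test_k_larger_than_training_set(self, tiny_examples):
        with pytest.raises(ValueError, match="exceeds"):
            fit(build_knn(k=10_000, output_dim=24), tiny_examples, FAST)

    def test_duplicating_examples_leaves_predictions_unchanged(self, tiny_examples):
        # with k even, doubling every example keeps each query's k-neighbour
        # set composed of the same (duplicated) points
        m1 = fit(build_knn(k=2, output_dim=24), tiny_examples, FAST)
        m2 = fit(build_knn(k=4, output_dim=24), list(tiny_examples) * 2, FAST)
        x, _ = design_matrices(tiny_examples, "knn")
        np.testing.assert_allclose(m1.predict(x), m2.predict(x), atol=1e-12)

    def test_convex_hull_property(self, tiny_examples, rng):
        # KNN predictions are means of observed targets: elementwise within
        # the min/max of the training targets
        model = fit(build_knn(k=3, output_dim=24), tiny_examples, FAST)
        _, y = design_matrices(tiny_examples, "knn")
        queries = rng.uniform(0, 1, size=(10, 24))
        preds = model.predict(queries)
        assert np.all(preds >= y.min(axis=0) - 1e-12)
        assert np.all(preds <= y.max(axis=0) + 1e-12)


class TestRrf:
    def test_single_tree_single_example(self, tiny_examples):
        model = fit(build_rrf(n_trees=1, output_dim=24), tiny_examples[:1], FAST)
        pred = model.predict(np.zeros(24))
        np.testing.assert_allclose(pred[0], tiny_examples[0].target.flat, atol=1e-12)

    def test_duplicating_examples_changes_little(self, tiny_examples):
        m = fit(build_rrf(n_trees=10, output_dim=24), tiny_examples, FAST)
        x, y = design_matrices(tiny_examples, "rrf")
        preds = m.predict(x)
        assert np.all(preds >= y.min(axis=0) - 1e-12)
        assert np.all(preds <= y.max(axis=0) + 1e-12)

    def test_seed_determinism(self, tiny_examples):
        cfg = TrainingConfig(seed=4)
        m1 = fit(build_rrf(n_trees=5, output_dim=24), tiny_examples, cfg)
        m2 = fit(build_rrf(n_trees=5, output_dim=24), tiny_examples, cfg)
        x, _ = design_matrices(tiny_examples, "rrf")
        np.testing.assert_array_equal(m1.predict(x), m2.predict(x))


class TestFitContract:
    def test_empty_training_set(self):
        with pytest.raises(ValueError, match="empty"):
            fit(build_knn(k=1, output_dim=4), [], FAST)

    def test_epochs_zero_is_untrained_forward_pass(self, tiny_examples):
        spec = build_naive_encoder(24, 24)
        cfg0 = TrainingConfig(epochs=0, seed=9)
        m1 = fit(spec, tiny_examples, cfg0)
        m2 = fit(spec, tiny_examples, cfg0)
        x, _ = design_matrices(tiny_examples, spec.kind)
        np.testing.assert_array_equal(m1.predict(x), m2.predict(x))

    def test_fit_seed_determinism(self, tiny_examples):
        spec = build_naive_encoder(24, 24)
        cfg = TrainingConfig(epochs=3, seed=17)
        m1 = fit(spec, tiny_examples, cfg)
        m2 = fit(spec, tiny_examples, cfg)
        x, _ = design_matrices(tiny_examples, spec.kind)
        np.testing.assert_array_equal(m1.predict(x), m2.predict(x))

    def test_training_reduces_loss(self, tiny_examples):
        spec = build_naive_encoder(24, 24)
        model = fit(spec, tiny_examples, TrainingConfig(epochs=25, seed=0))
        assert model.history[-1] < model.history[0]

    def test_save_load_round_trip(self, tiny_examples, tmp_path):
        for spec in (build_naive_encoder(24, 24), build_knn(k=2, output_dim=24)):
            model = fit(spec, tiny_examples, FAST)
            model.save(tmp_path / spec.kind)
            back = TrainedModel.load(tmp_path / spec.kind)
            x, _ = design_matrices(tiny_examples, spec.kind)
            np.testing.assert_allclose(back.predict(x), model.predict(x), atol=1e-12)


class TestGradients:
    """Hand-written backprop checked against central finite differences."""

    @staticmethod
    def _numeric_grad(net, x, y, param_layer, name, idx, eps=1e-6):
        w = getattr(param_layer, name)
        orig = w.flat[idx]
        w.flat[idx] = orig + eps
        up = net.loss(net.forward(x), y)
        w.flat[idx] = orig - eps
        down = net.loss(net.forward(x), y)
        w.flat[idx] = orig
        return (up - down) / (2 * eps)

    def _check(self, net, x, y, n_checks=30):
        pred = net.forward(x)
        # smooth surrogate of MAE for finite differences is unnecessary:
        # avoid sampling points where |pred - y| ~ 0 kinks by construction
        net._backward_from_loss(pred, y)
        rng = np.random.default_rng(0)
        for name, layer in net.parameters():
            grad = getattr(layer, "d" + name)
            for idx in rng.choice(grad.size, size=min(n_checks, grad.size), replace=False):
                num = self._numeric_grad(net, x, y, layer, name, idx)
                assert abs(num - grad.flat[idx]) < 1e-5, (name, idx, num, grad.flat[idx])

    def test_dense_network_gradients(self, rng):
        net = Network([
            Dense(5, 7, "relu", activity_l1=1e-3, rng=rng),
            Dense(7, 4, "sigmoid", rng=rng),
        ])
        x = rng.uniform(0.1, 0.9, size=(6, 5))
        y = rng.uniform(0.1, 0.9, size=(6, 4))
        self._check(net, x, y)

    def test_cnn_gradients(self, rng):
        net = Network([
            ConvGenes(3, 1, 4, "relu", rng=rng),
            MaxPoolGenes(2),
            Flatten(),
            Dense(4 * 3 * 4, 5, "relu", activity_l1=1e-3, rng=rng),
            Dense(5, 6, "sigmoid", rng=rng),
        ])
        x = rng.uniform(0.1, 0.9, size=(4, 9, 3, 1))
        y = rng.uniform(0.1, 0.9, size=(4, 6))
        self._check(net, x, y)

    def test_adam_descends_quadratic(self, rng):
        # single linear layer on an exactly-representable mapping: loss must
        # shrink under Adam steps
        net = Network([Dense(3, 3, "linear", rng=rng)])
        x = rng.uniform(-1, 1, size=(64, 3))
        y = x @ np.array([[1.0, 0, 0], [0, 0.5, 0], [0, 0, 2.0]])
        adam = AdamState(lr=1e-2)
        history = net.fit(x, y, epochs=50, batch_size=16, adam=adam,
                          rng=np.random.default_rng(1))
        assert history[-1] < history[0] * 0.5
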
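"""Classifier families: specs, training contracts, prediction rules."""

import numpy as np
import pytest

from syndromedx.classifiers import (
    ALGORITHMS,
    ClassifierSpec,
    TrainedModel,
    UnsupportedPairError,
    default_spec,
    predict,
    train,
)
from syndromedx.embeddings import ContractError


@pytest.fixture(scope="module")
def separable_toy():
    """Two well-separated Gaussian blobs in 8 dimensions."""
    rng = np.random.default_rng(0)
    a = rng.normal(0, 0.1, size=(40, 8))
    b = rng.normal(3, 0.1, size=(40, 8))
    X = np.vstack([a, b])
    y = ["cold wheezing"] * 40 + ["hot wheezing"] * 40
    return X, y


@pytest.fixture(scope="module")
def toy_sequences():
    """Index sequences where tokens 1-2 mark class A and 3-4 class B."""
    rng = np.random.default_rng(1)
    Xa = rng.integers(1, 3, size=(40, 12))
    Xb = rng.integers(3, 5, size=(40, 12))
    X = np.vstack([Xa, Xb]).astype(np.int64)
    y = ["cold wheezing"] * 40 + ["hot wheezing"] * 40
    emb = (np.random.default_rng(2).random((5, 8)) - 0.5)
    emb[0] = 0.0
    return X, y, emb


class TestDefaultSpecs:
    def test_rf_uses_1000_trees(self):
        assert default_spec("rf", "multiclass").hyperparameters["n_estimators"] == 1000

    def test_svm_is_linear_kernel_and_multiclass_only(self):
        assert default_spec("svm", "multiclass").hyperparameters["kernel"] == "linear"
        with pytest.raises(UnsupportedPairError):
            default_spec("svm", "multilabel")

    def test_mlp_has_six_hidden_layers_within_stated_range(self):
        widths = default_spec("mlp", "multiclass").hyperparameters["hidden_layer_sizes"]
        assert len(widths) == 6
        assert all(64 <= w <= 1024 for w in widths)

    def test_cnn_layer_stack_parameters_are_recorded(self):
        hp = default_spec("cnn", "multiclass").hyperparameters
        assert {"filters", "kernel_size", "dense_units"} <= set(hp)

    def test_knn_and_xgboost_defaults_are_explicit(self):
        assert default_spec("knn", "multiclass").hyperparameters["n_neighbors"] == 5
        hp = default_spec("xgboost", "multiclass").hyperparameters
        assert hp == {"n_estimators": 100, "max_depth": 6, "learning_rate": 0.3}

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(UnsupportedPairError):
            default_spec("naive_bayes", "multiclass")


def _small_spec(algorithm, mode, seed=0):
    overrides = {
        "rf": {"n_estimators": 30},
        "mlp": {"hidden_layer_sizes": (64, 64, 64, 64, 64, 64), "max_iter": 600},
        "cnn": {"filters": 16, "dense_units": 16, "epochs": 30, "val_fraction": 0.0},
    }.get(algorithm, {})
    return default_spec(algorithm, mode, seed=seed, **overrides)


class TestTrainPredict:
    @pytest.mark.parametrize("algorithm", [a for a in ALGORITHMS if a != "cnn"])
    def test_separable_toy_reaches_perfect_training_accuracy(self, separable_toy, algorithm):
        X, y = separable_toy
        model = train(_small_spec(algorithm, "multiclass"), X, y)
        preds = predict(model, X)
        assert preds.labels == y

    def test_cnn_separable_sequences_reach_perfect_training_accuracy(self, toy_sequences):
        X, y, emb = toy_sequences
        model = train(_small_spec("cnn", "multiclass"), X, y, embedding_matrix=emb)
        preds = predict(model, X)
        assert preds.labels == y

    @pytest.mark.parametrize("algorithm", [a for a in ALGORITHMS if a != "cnn"])
    def test_multiclass_probabilities_sum_to_one(self, separable_toy, algorithm):
        X, y = separable_toy
        model = train(_small_spec(algorithm, "multiclass"), X, y)
        sums = predict(model, X).probabilities.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_multilabel_output_covers_the_nine_elements(self, small_records, rb):
        # element labels from rule-consistent synthetic data -> 9 outputs
        rng = np.random.default_rng(0)
        X = rng.random((len(small_records), 8))
        y = [r.elements for r in small_records]
        model = train(default_spec("rf", "multilabel", n_estimators=10), X, y)
        preds = predict(model, X)
        assert preds.probabilities.shape[1] == 9
        assert len(model.labels) == 9

    def test_cnn_rejects_float_feature_vectors(self, separable_toy):
        X, y = separable_toy
        with pytest.raises(ContractError):
            train(_small_spec("cnn", "multiclass"), X, y)

    def test_zero_instance_class_is_reported(self, separable_toy):
        X, y = separable_toy
        with pytest.raises(ValueError, match="yin-deficiency of lung"):
            train(
                _small_spec("rf", "multiclass"), X, y,
                label_inventory=["cold wheezing", "hot wheezing", "yin-deficiency of lung"],
            )

    def test_feature_dimension_mismatch_is_a_contract_error(self, separable_toy):
        X, y = separable_toy
        model = train(_small_spec("rf", "multiclass"), X, y)
        with pytest.raises(ContractError):
            predict(model, X[:, :4])

    def test_fixed_seed_gives_identical_hard_labels(self, separable_toy):
        X, y = separable_toy
        a = predict(train(_small_spec("rf", "multiclass", seed=9), X, y), X)
        b = predict(train(_small_spec("rf", "multiclass", seed=9), X, y), X)
        assert a.labels == b.labels
        np.testing.assert_array_equal(a.probabilities, b.probabilities)


class _StubProba:
    def __init__(self, probs, classes):
        self._p = np.asarray(probs)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        return self._p


class TestHardLabelRules:
    def _model(self, mode, labels, probs):
        spec = ClassifierSpec("rf", mode, {}, 0)
        impl = _StubProba(probs, list(range(len(labels))))
        return TrainedModel(spec=spec, labels=labels, impl=impl, n_features=1)

    def test_argmax_picks_highest_probability_pattern(self):
        m = self._model("multiclass", ["cold wheezing", "hot wheezing"], [[0.2, 0.8]])
        assert predict(m, np.zeros((1, 1))).labels == ["hot wheezing"]

    def test_tie_goes_to_lexicographically_first_label(self):
        m = self._model("multiclass", ["cold wheezing", "hot wheezing"], [[0.5, 0.5]])
        assert predict(m, np.zeros((1, 1))).labels == ["cold wheezing"]

    def test_all_probabilities_below_threshold_give_empty_element_set(self):
        spec = ClassifierSpec("mlp", "multilabel", {}, 0)
        impl = _StubProba([[0.4, 0.3, 0.1]], [0, 1, 2])
        m = TrainedModel(spec=spec, labels=["cold", "heat", "lung"], impl=impl, n_features=1)
        assert predict(m, np.zeros((1, 1))).labels == [frozenset()]

    def test_threshold_is_inclusive(self):
        spec = ClassifierSpec("mlp", "multilabel", {}, 0)
        impl = _StubProba([[0.5, 0.3, 0.9]], [0, 1, 2])
        m = TrainedModel(spec=spec, labels=["cold", "heat", "lung"], impl=impl, n_features=1)
        assert predict(m, np.zeros((1, 1))).labels == [frozenset({"cold", "lung"})]


def test_every_family_recovers_patterns_on_highsignal_data(
    highsignal_split, highsignal_word_model, rb
):
    """On noise-free, disjoint-lexicon data every algorithm family
    reaches >= 0.95 test accuracy (n=2000, 10 patterns)."""
    from syndromedx.embeddings import (
        cnn_embedding_matrix,
        representation_matrix,
        suggest_max_len,
    )

    train_records, test_records = highsignal_split
    emb = highsignal_word_model
    docs_tr = [r.tokens for r in train_records]
    docs_te = [r.tokens for r in test_records]
    Xtr = representation_matrix(emb, docs_tr, "mean_vector")
    Xte = representation_matrix(emb, docs_te, "mean_vector")
    y_tr = [r.pattern for r in train_records]
    y_te = [r.pattern for r in test_records]
    accuracies = {}
    for algorithm in ALGORITHMS:
        if algorithm == "cnn":
            max_len = suggest_max_len(docs_tr)
            Str = representation_matrix(emb, docs_tr, "index_sequence", max_len)
            Ste = representation_matrix(emb, docs_te, "index_sequence", max_len)
            spec = default_spec("cnn", "multiclass", seed=7, filters=64, epochs=20)
            model = train(spec, Str, y_tr, embedding_matrix=cnn_embedding_matrix(emb))
            preds = predict(model, Ste)
        else:
            spec = _small_spec(algorithm, "multiclass", seed=7)
            if algorithm == "rf":
                spec.hyperparameters["n_estimators"] = 200
            model = train(spec, Xtr, y_tr)
            preds = predict(model, Xte)
        accuracies[algorithm] = np.mean(
            [p == t for p, t in zip(preds.labels, y_te)]
        )
    assert all(acc >= 0.95 for acc in accuracies.values()), accuracies
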
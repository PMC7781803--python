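"""Metric suite, repeated CV, and the paired corpus comparison."""

import numpy as np
import pytest

from syndromedx.evaluation import (
    CVResult,
    compare_corpora,
    element_density,
    multiclass_metrics,
    multilabel_metrics,
    repeated_cv,
)
from syndromedx.rulebase import ELEMENTS, PATTERNS
from syndromedx.synthetic import GeneratorConfig, Lexicon, StratificationError, generate_records


def brute_force_confusion_metrics(y_true, y_pred, labels):
    """Independent oracle: explicit confusion-matrix counting."""
    rows = {}
    for c in labels:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        rows[c] = (prec, rec, f1, tp + fn)
    total = sum(r[3] for r in rows.values())
    weighted = [
        sum(r[i] * r[3] for r in rows.values()) / total for i in range(3)
    ]
    acc = sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(y_true)
    return acc, weighted, rows


class TestMulticlassMetrics:
    def test_all_correct_gives_unit_metrics(self):
        y = list(PATTERNS)
        rep = multiclass_metrics(y, y)
        assert rep.accuracy == 1.0
        assert (rep.per_class["f1"] == 1.0).all()

    def test_hand_computed_confusion_example(self):
        # one class with TP=8, FP=2, FN=1
        y_true = ["a"] * 9 + ["b"] * 2 + ["b"] * 5
        y_pred = ["a"] * 8 + ["b"] + ["a"] * 2 + ["b"] * 5
        rep = multiclass_metrics(y_true, y_pred, labels=["a", "b"])
        row = rep.per_class.set_index("label").loc["a"]
        assert row["precision"] == pytest.approx(0.8)
        assert row["recall"] == pytest.approx(8 / 9)
        assert row["f1"] == pytest.approx(2 * 0.8 * (8 / 9) / (0.8 + 8 / 9))

    def test_never_predicted_class_has_zero_precision(self):
        rep = multiclass_metrics(["a", "b"], ["a", "a"], labels=["a", "b"])
        assert rep.per_class.set_index("label").loc["b", "precision"] == 0.0

    def test_none_predictions_are_always_incorrect(self):
        rep = multiclass_metrics(["a", "a"], ["a", None], labels=["a"])
        assert rep.accuracy == 0.5

    def test_length_mismatch_is_a_contract_error(self):
        with pytest.raises(ValueError):
            multiclass_metrics(["a"], ["a", "b"])

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(123)
        labels = sorted(PATTERNS)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            y_true = [labels[i] for i in rng.integers(0, 10, n)]
            y_pred = [labels[i] for i in rng.integers(0, 10, n)]
            rep = multiclass_metrics(y_true, y_pred, labels=labels)
            acc, (prec, rec, f1), rows = brute_force_confusion_metrics(
                y_true, y_pred, labels
            )
            assert abs(rep.accuracy - acc) < 1e-12
            assert abs(rep.precision - prec) < 1e-12
            assert abs(rep.recall - rec) < 1e-12
            assert abs(rep.f1 - f1) < 1e-12

    def test_weighted_average_identity(self):
        rng = np.random.default_rng(7)
        labels = sorted(PATTERNS)
        y_true = [labels[i] for i in rng.integers(0, 10, 500)]
        y_pred = [labels[i] for i in rng.integers(0, 10, 500)]
        rep = multiclass_metrics(y_true, y_pred, labels=labels)
        pc = rep.per_class
        manual = (pc["f1"] * pc["support"]).sum() / pc["support"].sum()
        assert abs(rep.f1 - manual) < 1e-12


class TestMultilabelMetrics:
    def test_perfect_elements_and_patterns_give_unit_metrics(self):
        sets = [frozenset({"lung", "phlegm"}), frozenset({"cold"})]
        rep = multilabel_metrics(sets, sets, [True, True])
        assert rep.accuracy == 1.0
        assert rep.f1 == 1.0

    def test_ambiguous_rules_lower_accuracy_but_not_element_f1(self):
        # perfect elements but 10% of patterns wrong (duplicate-rule effect)
        sets = [frozenset({"lung"})] * 10
        flags = [True] * 9 + [False]
        rep = multilabel_metrics(sets, sets, flags)
        assert rep.accuracy == pytest.approx(0.9)
        assert rep.f1 == 1.0

    def test_always_missed_element_has_zero_recall_with_support_share(self):
        true = [frozenset({"lung", "kidney"})] * 4 + [frozenset({"lung"})] * 4
        pred = [frozenset({"lung"})] * 8
        rep = multilabel_metrics(true, pred, [True] * 8)
        pc = rep.per_class.set_index("label")
        assert pc.loc["kidney", "recall"] == 0.0
        assert rep.recall == pytest.approx(8 / 12)  # lung 8/8, kidney 0/4

    def test_unknown_element_is_rejected(self):
        with pytest.raises(ValueError):
            multilabel_metrics([frozenset({"dampness"})], [frozenset()], [False])


@pytest.fixture(scope="module")
def cv_records(rb, lexicon):
    return generate_records(GeneratorConfig(n_records=300, seed=13), rb, lexicon)


class TestRepeatedCV:
    def test_constant_classifier_gives_zero_width_ci(self, cv_records):
        def majority_pipeline(train, test, seed):
            counts = {}
            for r in train:
                counts[r.pattern] = counts.get(r.pattern, 0) + 1
            top = max(sorted(counts), key=counts.get)
            return multiclass_metrics(
                [r.pattern for r in test], [top] * len(test), labels=sorted(PATTERNS)
            )

        # stratified folds make per-fold class shares (hence scores) equal
        results = repeated_cv(majority_pipeline, cv_records, folds=5, repeats=2, seed=0)
        acc = results["accuracy"]
        assert acc.n_scores == 10
        assert acc.ci_high - acc.ci_low <= 0.02

    def test_reduced_run_score_count_and_ci_ordering(self, cv_records):
        def noisy_pipeline(train, test, seed):
            rng = np.random.default_rng(seed + len(test))
            labels = sorted(PATTERNS)
            preds = [
                r.pattern if rng.random() < 0.8 else labels[rng.integers(0, 10)]
                for r in test
            ]
            return multiclass_metrics([r.pattern for r in test], preds, labels=labels)

        results = repeated_cv(noisy_pipeline, cv_records, folds=5, repeats=2, seed=1)
        for res in results.values():
            assert res.n_scores == 10
            assert res.ci_low <= res.mean <= res.ci_high

    def test_small_class_raises_stratification_error(self, rb, lexicon):
        records = generate_records(GeneratorConfig(n_records=30, seed=2), rb, lexicon)
        with pytest.raises(StratificationError):
            repeated_cv(lambda a, b, s: None, records, folds=25, repeats=1)

    def test_cv_result_rejects_ci_not_containing_mean(self):
        with pytest.raises(ValueError):
            CVResult(metric="accuracy", mean=0.5, ci_low=0.6, ci_high=0.7, n_scores=1)


class TestCompareCorpora:
    def test_uninformative_priors_give_small_delta(self, rb):
        # when the diagnosis carries no information about the pattern the
        # two corpora should perform within a small margin of each other
        uniform = {
            d: {p: 0.1 for p in PATTERNS}
            for d in GeneratorConfig().disease_priors
        }
        cfg = GeneratorConfig(
            n_records=800, seed=12, pattern_given_disease=uniform,
            noise_token_rate=0.0, tokens_per_element=6.0,
        )
        records = generate_records(cfg, rb, Lexicon.default(seed=12))

        from syndromedx.pipeline import PipelineConfig, corpus_pipeline

        pipe = corpus_pipeline(
            PipelineConfig(
                algorithm="rf", dimension=32, embed_epochs=8,
                classifier_overrides={"n_estimators": 100},
            ),
            rb,
        )
        cmp = compare_corpora(records, pipe, seed=12)
        assert abs(cmp.delta_accuracy) < 0.02
        assert "Average (weighted)" in cmp.table.index

    def test_missing_disease_labels_are_rejected(self, small_records):
        import dataclasses

        bad = [dataclasses.replace(small_records[0], disease="")]
        with pytest.raises(ValueError):
            compare_corpora(bad * 60, lambda *a: None, seed=0)


def test_element_density_reproduces_published_value():
    # 35,992 syndrome elements over 14,075 syndrome patterns
    assert element_density(35_992, 14_075) == 2.56
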
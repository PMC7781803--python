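"""End-to-end pipeline composition: records → embedding → classifier → report.

One :class:`PipelineConfig` describes a full experiment arm (embedding
level, classifier family, diagnosis path, corpus variant and scale
parameters), so repeated cross-validation, the corpus comparison and
the scaling grid can all run the same code path.  Scale parameters
(embedding dimension, training epochs, classifier overrides) default to
desk-scale values; the reference configuration (256-d word vectors,
192-d document vectors, full-width MLP) is reachable by overrides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .classifiers import TrainedModel, default_spec, predict, train
from .corpus import build_corpus
from .embeddings import (
    cnn_embedding_matrix,
    representation_matrix,
    suggest_max_len,
    train_doc_model,
    train_word_model,
)
from .evaluation import MetricsReport, multiclass_metrics, multilabel_metrics
from .hybrid import Diagnosis, diagnose_from_elements
from .rulebase import RuleBase, load_rulebase
from .synthetic import ClinicalRecord

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "cv_pipeline", "corpus_pipeline"]


@dataclass
class PipelineConfig:
    """One experiment arm of the diagnosis benchmark."""

    embedding: str = "word"            # "word" or "doc"
    algorithm: str = "cnn"
    path: str = "mbr"                  # "mbr" or "mbr_rbr"
    corpus_variant: int = 1
    dimension: int = 32
    window: int = 5
    min_count: int = 2
    embed_epochs: int = 3
    representation: Optional[str] = None
    max_len: Optional[int] = None
    threshold: float = 0.5
    fallback: str = "best_overlap"
    classifier_overrides: dict = field(default_factory=dict)

    def resolved_representation(self) -> str:
        if self.representation:
            return self.representation
        if self.algorithm == "cnn":
            return "index_sequence"
        return "doc_vector" if self.embedding == "doc" else "mean_vector"


@dataclass
class PipelineResult:
    report: MetricsReport
    diagnoses: list[Diagnosis]
    model: TrainedModel


def run_pipeline(
    train_records: Sequence[ClinicalRecord],
    test_records: Sequence[ClinicalRecord],
    cfg: PipelineConfig,
    rb: Optional[RuleBase] = None,
    seed: int = 0,
) -> PipelineResult:
    """Train one experiment arm on ``train_records``, score on ``test_records``."""
    corpus_tr = build_corpus(train_records, cfg.corpus_variant)
    corpus_te = build_corpus(test_records, cfg.corpus_variant)
    mode = cfg.resolved_representation()
    if cfg.embedding == "word":
        emb = train_word_model(
            corpus_tr, dimension=cfg.dimension, window=cfg.window,
            min_count=cfg.min_count, seed=seed, epochs=cfg.embed_epochs,
        )
    elif cfg.embedding == "doc":
        # PV-DBOW needs more passes than the word model; train and test
        # documents are both represented by inference so the two sides
        # of the classifier see exchangeable vectors
        emb = train_doc_model(
            corpus_tr, dimension=cfg.dimension, window=cfg.window,
            min_count=cfg.min_count, seed=seed, epochs=max(cfg.embed_epochs, 20),
        )
    else:
        raise ValueError("embedding must be 'word' or 'doc'")
    max_len = cfg.max_len
    if mode == "index_sequence" and max_len is None:
        max_len = suggest_max_len(corpus_tr.token_lists)
    X_tr = representation_matrix(emb, corpus_tr.token_lists, mode, max_len)
    X_te = representation_matrix(emb, corpus_te.token_lists, mode, max_len)

    clf_mode = "multiclass" if cfg.path == "mbr" else "multilabel"
    spec = default_spec(cfg.algorithm, clf_mode, seed=seed, **cfg.classifier_overrides)
    emb_matrix = cnn_embedding_matrix(emb) if cfg.algorithm == "cnn" else None

    if cfg.path == "mbr":
        y_tr = [r.pattern for r in train_records]
        model = train(spec, X_tr, y_tr, embedding_matrix=emb_matrix)
        model.meta["corpus_variant"] = cfg.corpus_variant
        preds = predict(model, X_te)
        y_te = [r.pattern for r in test_records]
        inventory = sorted(set(y_te) | set(model.labels))
        report = multiclass_metrics(y_te, preds.labels, labels=inventory)
        diagnoses = [
            Diagnosis(r.record_id, "mbr", p)
            for r, p in zip(test_records, preds.labels)
        ]
    elif cfg.path == "mbr_rbr":
        rb = rb if rb is not None else load_rulebase()
        y_tr = [r.elements for r in train_records]
        model = train(spec, X_tr, y_tr, embedding_matrix=emb_matrix)
        model.meta["corpus_variant"] = cfg.corpus_variant
        preds = predict(model, X_te, threshold=cfg.threshold)
        diagnoses = diagnose_from_elements(
            rb, [r.record_id for r in test_records], preds.labels, cfg.fallback
        )
        flags = [
            d.predicted_pattern == r.pattern
            for d, r in zip(diagnoses, test_records)
        ]
        report = multilabel_metrics(
            [r.elements for r in test_records], preds.labels, flags
        )
    else:
        raise ValueError("path must be 'mbr' or 'mbr_rbr'")
    return PipelineResult(report=report, diagnoses=diagnoses, model=model)


def cv_pipeline(
    cfg: PipelineConfig, rb: Optional[RuleBase] = None
) -> Callable[[list, list, int], MetricsReport]:
    """Adapter for :func:`syndromedx.evaluation.repeated_cv`."""

    def _run(train_records, test_records, seed):
        return run_pipeline(train_records, test_records, cfg, rb=rb, seed=seed).report

    return _run


def corpus_pipeline(
    cfg: PipelineConfig, rb: Optional[RuleBase] = None
) -> Callable[[list, list, int, int], MetricsReport]:
    """Adapter for :func:`syndromedx.evaluation.compare_corpora`."""
    from dataclasses import replace

    def _run(train_records, test_records, variant, seed):
        arm = replace(cfg, corpus_variant=variant)
        return run_pipeline(train_records, test_records, arm, rb=rb, seed=seed).report

    return _run
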
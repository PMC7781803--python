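"""The two diagnosis paths.

- MBR: a multiclass classifier maps a document representation straight
  to a syndrome pattern.
- MBR+RBR: a multilabel classifier predicts the syndrome-element set,
  which the rule knowledge base combines into a pattern by forward
  reasoning.  Records whose predicted elements match no rule are kept
  and scored as incorrect (never silently dropped), so reported
  accuracies cover every test record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .classifiers import TrainedModel, predict
from .embeddings import EmbeddingModel, representation_matrix
from .rulebase import RuleBase
from .synthetic import ClinicalRecord

__all__ = [
    "Diagnosis",
    "diagnose_mbr",
    "diagnose_mbr_rbr",
    "diagnose_from_elements",
]


@dataclass
class Diagnosis:
    record_id: str
    path: str
    predicted_pattern: Optional[str]
    predicted_elements: frozenset = frozenset()
    match_status: Optional[str] = None


def _representations(
    model: TrainedModel,
    records: Sequence[ClinicalRecord],
    emb: EmbeddingModel,
    mode: str,
    max_len: Optional[int],
) -> np.ndarray:
    docs = [r.tokens for r in records]
    return representation_matrix(emb, docs, mode=mode, max_len=max_len)


def _check_variant(model: TrainedModel, records: Sequence[ClinicalRecord]) -> None:
    trained_on = model.meta.get("corpus_variant")
    if trained_on is None or not records:
        return
    seen = {r.corpus_variant for r in records}
    if seen != {trained_on}:
        warnings.warn(
            f"model trained on corpus variant {trained_on} applied to records of "
            f"variant(s) {sorted(seen)}; missing tokens degrade silently"
        )


def diagnose_mbr(
    model: TrainedModel,
    records: Sequence[ClinicalRecord],
    emb: EmbeddingModel,
    mode: str = "mean_vector",
    max_len: Optional[int] = None,
) -> list[Diagnosis]:
    """Direct pattern diagnosis with a multiclass classifier."""
    if model.spec.mode != "multiclass":
        raise ValueError("diagnose_mbr requires a multiclass model")
    if not records:
        return []
    _check_variant(model, records)
    X = _representations(model, records, emb, mode, max_len)
    preds = predict(model, X)
    return [
        Diagnosis(record_id=r.record_id, path="mbr", predicted_pattern=p)
        for r, p in zip(records, preds.labels)
    ]


def diagnose_from_elements(
    rb: RuleBase,
    record_ids: Sequence[str],
    element_sets: Sequence[frozenset],
    fallback: str = "best_overlap",
) -> list[Diagnosis]:
    """Rule combination of (predicted or oracle) element sets into patterns."""
    if fallback not in ("none", "best_overlap"):
        raise ValueError("fallback must be 'none' or 'best_overlap'")
    out = []
    for rid, els in zip(record_ids, element_sets):
        if not els:
            out.append(Diagnosis(rid, "mbr_rbr", None, frozenset(), "none"))
            continue
        res = rb.pattern_for_elements(els)
        pattern = res.pattern
        if fallback == "none" and res.status != "exact":
            pattern = None
        out.append(Diagnosis(rid, "mbr_rbr", pattern, frozenset(els), res.status))
    return out


def diagnose_mbr_rbr(
    model: TrainedModel,
    rb: RuleBase,
    records: Sequence[ClinicalRecord],
    emb: EmbeddingModel,
    mode: str = "mean_vector",
    threshold: float = 0.5,
    fallback: str = "best_overlap",
    max_len: Optional[int] = None,
) -> list[Diagnosis]:
    """Hybrid diagnosis: multilabel element prediction, then rule combination."""
    if model.spec.mode != "multilabel":
        raise ValueError("diagnose_mbr_rbr requires a multilabel model")
    report = rb.validate()
    if report.missing_patterns:
        raise ValueError(
            f"rule base lacks rules for patterns: {report.missing_patterns}"
        )
    if not records:
        return []
    _check_variant(model, records)
    X = _representations(model, records, emb, mode, max_len)
    preds = predict(model, X, threshold=threshold)
    return diagnose_from_elements(
        rb, [r.record_id for r in records], preds.labels, fallback=fallback
    )
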
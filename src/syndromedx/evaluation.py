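"""Metric suite, repeated cross-validation and the corpus comparison.

Accuracy is always the exact-match fraction over all records (an
unmatched hybrid prediction counts as incorrect).  Precision, recall
and F1 are support-weighted means of per-class rows: per-pattern rows
in multiclass reports, per-element rows in multilabel (hybrid) reports
— in the hybrid path the paper-style report pairs end-to-end pattern
accuracy with element-level P/R/F1, which is why precision can exceed
accuracy there.

Repeated CV follows the 5-fold × 20-repeat protocol; the 95% CI of each
metric is taken from the empirical 2.5/97.5 percentiles of the 100 fold
scores (a normal-approximation option is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .rulebase import ELEMENTS
from .synthetic import ClinicalRecord, StratificationError

__all__ = [
    "MetricsReport",
    "CVResult",
    "CorpusComparison",
    "multiclass_metrics",
    "multilabel_metrics",
    "repeated_cv",
    "compare_corpora",
    "element_density",
]


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: pd.DataFrame
    support: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "support": self.support,
        }


@dataclass
class CVResult:
    metric: str
    mean: float
    ci_low: float
    ci_high: float
    n_scores: int
    scores: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("CI must contain the mean")


def _prf_rows(labels: Sequence[str], tp: np.ndarray, fp: np.ndarray, fn: np.ndarray) -> pd.DataFrame:
    # zero-denominator convention: precision/recall/F1 = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        rec = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / np.maximum(prec + rec, 1e-300), 0.0)
    return pd.DataFrame(
        {
            "label": list(labels),
            "precision": prec,
            "recall": rec,
            "f1": f1,
            "support": (tp + fn).astype(int),
        }
    )


def _weighted(per_class: pd.DataFrame) -> tuple[float, float, float]:
    support = per_class["support"].to_numpy(dtype=float)
    total = support.sum()
    if total == 0:
        return 0.0, 0.0, 0.0
    return tuple(
        float((per_class[m].to_numpy() * support).sum() / total)
        for m in ("precision", "recall", "f1")
    )


def multiclass_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[Optional[str]],
    labels: Optional[Sequence[str]] = None,
) -> MetricsReport:
    """Per-pattern P/R/F1 rows with support, plus weighted averages.

    ``None`` predictions are always incorrect and count as false
    negatives of the true class only.
    """
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    inventory = list(labels) if labels is not None else sorted(set(y_true))
    pos = {l: i for i, l in enumerate(inventory)}
    tp = np.zeros(len(inventory))
    fp = np.zeros(len(inventory))
    fn = np.zeros(len(inventory))
    correct = 0
    for t, p in zip(y_true, y_pred):
        if t not in pos:
            raise ValueError(f"true label {t!r} outside the label inventory")
        if p == t:
            tp[pos[t]] += 1
            correct += 1
        else:
            fn[pos[t]] += 1
            if p is not None and p in pos:
                fp[pos[p]] += 1
    per_class = _prf_rows(inventory, tp, fp, fn)
    precision, recall, f1 = _weighted(per_class)
    return MetricsReport(
        accuracy=correct / len(y_true) if y_true else 0.0,
        precision=precision,
        recall=recall,
        f1=f1,
        per_class=per_class,
        support=len(y_true),
    )


def multilabel_metrics(
    true_sets: Sequence[frozenset],
    pred_sets: Sequence[frozenset],
    pattern_correct: Sequence[bool],
    elements: Sequence[str] = ELEMENTS,
) -> MetricsReport:
    """Hybrid-path report: end-to-end pattern accuracy + element P/R/F1.

    ``accuracy`` is the fraction of records whose final pattern is
    exactly right; the P/R/F1 columns are support-weighted per-element
    values (per-element support = count of true occurrences).
    """
    if not (len(true_sets) == len(pred_sets) == len(pattern_correct)):
        raise ValueError("inputs must have equal length")
    inventory = list(elements)
    known = set(inventory)
    tp = np.zeros(len(inventory))
    fp = np.zeros(len(inventory))
    fn = np.zeros(len(inventory))
    for ts, ps in zip(true_sets, pred_sets):
        bad = (set(ts) | set(ps)) - known
        if bad:
            raise ValueError(f"elements outside the vocabulary: {sorted(bad)}")
        for j, el in enumerate(inventory):
            in_t, in_p = el in ts, el in ps
            tp[j] += in_t and in_p
            fp[j] += in_p and not in_t
            fn[j] += in_t and not in_p
    per_class = _prf_rows(inventory, tp, fp, fn)
    precision, recall, f1 = _weighted(per_class)
    n = len(true_sets)
    return MetricsReport(
        accuracy=float(np.mean([bool(c) for c in pattern_correct])) if n else 0.0,
        precision=precision,
        recall=recall,
        f1=f1,
        per_class=per_class,
        support=int(per_class["support"].sum()),
    )


def repeated_cv(
    pipeline: Callable[[list[ClinicalRecord], list[ClinicalRecord], int], MetricsReport],
    records: Sequence[ClinicalRecord],
    folds: int = 5,
    repeats: int = 20,
    seed: int = 0,
    ci_method: str = "percentile",
) -> dict[str, CVResult]:
    """Stratified k-fold CV repeated with reshuffled folds; 95% CIs.

    ``pipeline(train, test, seed) -> MetricsReport`` is called once per
    fold; fold assignment is reshuffled on every repeat from the seed
    stream, giving ``folds × repeats`` scores per metric.
    """
    records = list(records)
    y = [r.pattern for r in records]
    counts: dict[str, int] = {}
    for p in y:
        counts[p] = counts.get(p, 0) + 1
    too_small = sorted(c for c, n in counts.items() if n < folds)
    if too_small:
        raise StratificationError(
            f"classes with fewer than {folds} records: {too_small}"
        )
    rng = np.random.default_rng(seed)
    scores: dict[str, list[float]] = {m: [] for m in ("accuracy", "precision", "recall", "f1")}
    for _ in range(repeats):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
        for tr_idx, te_idx in skf.split(np.zeros(len(records)), y):
            report = pipeline(
                [records[i] for i in tr_idx],
                [records[i] for i in te_idx],
                fold_seed,
            )
            for m in scores:
                scores[m].append(getattr(report, m))
    out = {}
    for m, vals in scores.items():
        arr = np.asarray(vals)
        mean = float(arr.mean())
        if ci_method == "percentile":
            lo, hi = np.percentile(arr, [2.5, 97.5])
        elif ci_method == "normal":
            half = 1.959963984540054 * arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
            lo, hi = mean - half, mean + half
        else:
            raise ValueError("ci_method must be 'percentile' or 'normal'")
        out[m] = CVResult(
            metric=m, mean=mean, ci_low=float(min(lo, mean)),
            ci_high=float(max(hi, mean)), n_scores=len(arr), scores=arr,
        )
    return out


@dataclass
class CorpusComparison:
    corpus1: MetricsReport
    corpus2: MetricsReport
    delta_accuracy: float
    table: pd.DataFrame


def compare_corpora(
    records: Sequence[ClinicalRecord],
    pipeline: Callable[[list[ClinicalRecord], list[ClinicalRecord], int, int], MetricsReport],
    seed: int = 0,
) -> CorpusComparison:
    """Paired corpus-1 vs corpus-2 run: identical records, split and seeds.

    ``pipeline(train, test, variant, seed) -> MetricsReport``.  The
    returned table lays per-pattern (or per-element) P/R/F1/support rows
    of both arms side by side.
    """
    records = list(records)
    if any(not r.disease for r in records):
        raise ValueError("corpus comparison requires disease labels on all records")
    from .synthetic import split_dataset

    train, test = split_dataset(records, (4, 1), stratify_by="pattern", seed=seed)
    rep1 = pipeline(train, test, 1, seed)
    rep2 = pipeline(train, test, 2, seed)
    t1 = rep1.per_class.set_index("label")
    t2 = rep2.per_class.set_index("label")
    table = pd.concat({"corpus1": t1, "corpus2": t2}, axis=1)
    avg = {
        ("corpus1", "precision"): rep1.precision,
        ("corpus1", "recall"): rep1.recall,
        ("corpus1", "f1"): rep1.f1,
        ("corpus1", "support"): int(t1["support"].sum()),
        ("corpus2", "precision"): rep2.precision,
        ("corpus2", "recall"): rep2.recall,
        ("corpus2", "f1"): rep2.f1,
        ("corpus2", "support"): int(t2["support"].sum()),
    }
    table.loc["Average (weighted)"] = pd.Series(avg)
    return CorpusComparison(
        corpus1=rep1,
        corpus2=rep2,
        delta_accuracy=rep2.accuracy - rep1.accuracy,
        table=table,
    )


def element_density(n_elements: int, n_patterns: int) -> float:
    """Mean syndrome elements per syndrome pattern, rounded to 2 decimals."""
    if n_patterns <= 0:
        raise ValueError("n_patterns must be positive")
    return round(n_elements / n_patterns, 2)
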
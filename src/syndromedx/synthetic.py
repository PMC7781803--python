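"""Synthetic tokenized-EMR generator.

The real clinical records behind this pipeline (lung-disease ward EMRs)
are private, so every downstream stage is exercised on synthetic records
that reproduce the *statistical structure* the analysis assumes:

- 8 lung-disease labels with configurable priors (defaults follow the
  published development-set proportions);
- 10 syndrome patterns drawn from a disease-conditional table, each
  decomposed into its rule-base element set, so generated labels are
  rule-consistent by construction;
- per-element symptom/sign tokens drawn from a synthetic lexicon, spread
  over the five clinical sections (chief complaint, syndromes, chest
  signs, tongue, pulse), plus disease-correlated tokens and optional
  noise tokens.

Tokens are abstract ASCII identifiers (``el_phlegm_07``): the pipeline
operates on token sequences, not on any particular language.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .rulebase import ELEMENTS, PATTERNS, RuleBase, SyndromePattern

__all__ = [
    "DISEASES",
    "DEFAULT_DISEASE_PRIORS",
    "DEFAULT_PATTERN_GIVEN_DISEASE",
    "SECTION_ORDER",
    "GeneratorConfig",
    "Lexicon",
    "ClinicalRecord",
    "ConfigError",
    "RecordParseError",
    "StratificationError",
    "disease_token",
    "generate_records",
    "generate_balanced",
    "expected_elements_per_record",
    "split_dataset",
    "write_records",
    "read_records",
]

#: The eight common lung diseases of the study setting.
DISEASES: tuple[str, ...] = (
    "lung cancer",
    "pulmonary infection",
    "acute bronchitis",
    "interstitial pneumonia",
    "chronic bronchitis",
    "chronic obstructive pulmonary disease",
    "bronchiectasis",
    "asthma",
)

# Published development-set disease proportions (normalised to sum to 1).
_RAW_PRIORS = {
    "lung cancer": 0.1842,
    "pulmonary infection": 0.1859,
    "acute bronchitis": 0.0839,
    "interstitial pneumonia": 0.0166,
    "chronic bronchitis": 0.0978,
    "chronic obstructive pulmonary disease": 0.2598,
    "bronchiectasis": 0.0431,
    "asthma": 0.1288,
}
_Z = sum(_RAW_PRIORS.values())
DEFAULT_DISEASE_PRIORS: dict[str, float] = {d: p / _Z for d, p in _RAW_PRIORS.items()}

# Disease-conditional syndrome-pattern table.  Each disease concentrates
# on 2-5 clinically plausible patterns, which makes the modern-medicine
# diagnosis informative for the pattern (the corpus-2 effect).  The
# per-disease rows are invented study conditions, not clinical fact; the
# implied support-weighted mean element count per pattern sits near the
# published 2.56.
DEFAULT_PATTERN_GIVEN_DISEASE: dict[str, dict[str, float]] = {
    "lung cancer": {
        "yin-deficiency of lung": 0.40,
        "deficiency of qi and yin": 0.30,
        "qi-deficiency of lung and spleen": 0.20,
        "phlegm obstruction in lung": 0.10,
    },
    "pulmonary infection": {
        "phlegm-heat obstruction in lung": 0.35,
        "wind-heat attacking lung": 0.20,
        "phlegm obstruction in lung": 0.35,
        "hot wheezing": 0.10,
    },
    "acute bronchitis": {
        "wind-cold attacking lung": 0.40,
        "wind-heat attacking lung": 0.40,
        "phlegm obstruction in lung": 0.20,
    },
    "interstitial pneumonia": {
        "yin-deficiency of lung": 0.50,
        "deficiency of qi and yin": 0.30,
        "qi-deficiency of lung and kidney": 0.20,
    },
    "chronic bronchitis": {
        "phlegm obstruction in lung": 0.40,
        "qi-deficiency of lung and spleen": 0.30,
        "wind-cold attacking lung": 0.20,
        "phlegm-heat obstruction in lung": 0.10,
    },
    "chronic obstructive pulmonary disease": {
        "qi-deficiency of lung and kidney": 0.25,
        "qi-deficiency of lung and spleen": 0.20,
        "phlegm obstruction in lung": 0.35,
        "phlegm-heat obstruction in lung": 0.20,
    },
    "bronchiectasis": {
        "phlegm-heat obstruction in lung": 0.40,
        "yin-deficiency of lung": 0.30,
        "phlegm obstruction in lung": 0.30,
    },
    "asthma": {
        "cold wheezing": 0.25,
        "hot wheezing": 0.25,
        "deficiency of qi and yin": 0.20,
        "qi-deficiency of lung and kidney": 0.15,
        "phlegm obstruction in lung": 0.15,
    },
}

#: Fixed clinical-section order of every record's token stream.
SECTION_ORDER: tuple[str, ...] = (
    "chief_complaint",
    "syndromes",
    "chest_signs",
    "tongue",
    "pulse",
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


class RecordParseError(ValueError):
    """A JSON-lines record file could not be parsed."""

    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class StratificationError(ValueError):
    """A class is too small for the requested stratified split/folding."""


def _slug(name: str) -> str:
    return name.replace(" ", "_").replace("-", "_")


def disease_token(disease: str) -> str:
    """The single modern-medicine diagnosis token appended in corpus 2."""
    return f"dx={_slug(disease)}"


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic-EMR generator.

    ``tokens_per_element`` is the Poisson mean (minimum 1) of symptom
    tokens emitted per syndrome element; ``noise_token_rate`` is the
    expected fraction of non-informative tokens in a record.
    """

    n_records: int = 1000
    disease_priors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_PRIORS)
    )
    pattern_given_disease: dict[str, dict[str, float]] = field(
        default_factory=lambda: {d: dict(r) for d, r in DEFAULT_PATTERN_GIVEN_DISEASE.items()}
    )
    tokens_per_element: float = 4.0
    noise_token_rate: float = 0.1
    section_order: tuple[str, ...] = SECTION_ORDER
    seed: int = 0
    corpus_variant: int = 1

    def validate(self) -> None:
        if self.n_records <= 0:
            raise ConfigError("n_records must be positive")
        if not (0.0 <= self.noise_token_rate < 1.0):
            raise ConfigError("noise_token_rate must be in [0, 1)")
        if self.tokens_per_element <= 0:
            raise ConfigError("tokens_per_element must be positive")
        if self.corpus_variant not in (1, 2):
            raise ConfigError("corpus_variant must be 1 or 2")
        if abs(sum(self.disease_priors.values()) - 1.0) > 1e-9:
            raise ConfigError("disease_priors must sum to 1")
        for d, row in self.pattern_given_disease.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ConfigError(f"pattern_given_disease[{d!r}] must sum to 1")
            for p in row:
                SyndromePattern(p)  # vocabulary check
        for d in self.disease_priors:
            if d not in self.pattern_given_disease:
                raise ConfigError(f"no pattern row for disease {d!r}")


@dataclass
class Lexicon:
    """Synthetic token inventories for elements, diseases and noise.

    ``overlap`` > 0 at construction replaces that fraction of every
    element's list with tokens from a shared ambiguous pool, creating
    controlled label ambiguity for stress tests.
    """

    element_tokens: dict[str, list[str]]
    disease_tokens: dict[str, list[str]]
    noise_tokens: list[str]

    def validate(self, elements: Iterable[str] = ELEMENTS) -> None:
        for el in elements:
            if not self.element_tokens.get(el):
                raise ConfigError(f"lexicon has no tokens for element {el!r}")
        if any(not t for toks in self.element_tokens.values() for t in toks):
            raise ConfigError("lexicon tokens must be non-empty strings")

    @classmethod
    def default(
        cls,
        tokens_per_element: int = 24,
        tokens_per_disease: int = 6,
        n_noise: int = 60,
        overlap: float = 0.0,
        seed: int = 0,
    ) -> "Lexicon":
        if not (0.0 <= overlap < 1.0):
            raise ConfigError("overlap must be in [0, 1)")
        rng = np.random.default_rng(seed)
        shared = [f"amb_{i:03d}" for i in range(max(tokens_per_element, 12))]
        element_tokens = {}
        for el in ELEMENTS:
            own = [f"el_{_slug(el)}_{i:02d}" for i in range(tokens_per_element)]
            n_shared = int(round(overlap * tokens_per_element))
            if n_shared:
                picks = rng.choice(len(shared), size=n_shared, replace=False)
                for j, k in enumerate(picks):
                    own[j] = shared[k]
            element_tokens[el] = own
        disease_tokens = {
            d: [f"sx_{_slug(d)}_{i:02d}" for i in range(tokens_per_disease)]
            for d in DISEASES
        }
        noise = [f"noise_{i:03d}" for i in range(n_noise)]
        return cls(element_tokens, disease_tokens, noise)


@dataclass
class ClinicalRecord:
    """One tokenized clinical case with its gold labels."""

    record_id: str
    disease: str
    pattern: str
    elements: frozenset[str]
    tokens: list[str]
    corpus_variant: int = 1

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "disease": self.disease,
            "pattern": self.pattern,
            "elements": sorted(self.elements),
            "tokens": list(self.tokens),
            "corpus_variant": self.corpus_variant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClinicalRecord":
        return cls(
            record_id=d["record_id"],
            disease=d["disease"],
            pattern=d["pattern"],
            elements=frozenset(d["elements"]),
            tokens=list(d["tokens"]),
            corpus_variant=int(d.get("corpus_variant", 1)),
        )


def _check_rulebase(rb: RuleBase, patterns_needed: Iterable[str]) -> None:
    report = rb.validate()
    for p in patterns_needed:
        if p not in rb:
            raise ConfigError(f"rule base has no rule for pattern {p!r}")
        if not report.roundtrip.get(p, False):
            raise ConfigError(
                f"rule base is not round-trip exact for pattern {p!r}; "
                "generated labels would not be rule-consistent"
            )


def _make_record(
    rng: np.random.Generator,
    record_id: str,
    disease: str,
    pattern: str,
    rb: RuleBase,
    lex: Lexicon,
    cfg: GeneratorConfig,
) -> ClinicalRecord:
    elements = rb.elements_for_pattern(pattern)
    sections: dict[str, list[str]] = {s: [] for s in cfg.section_order}
    section_names = list(cfg.section_order)
    for el in sorted(elements):
        pool = lex.element_tokens[el]
        count = max(1, rng.poisson(cfg.tokens_per_element))
        for tok_idx in rng.integers(0, len(pool), size=count):
            sec = section_names[rng.integers(0, len(section_names))]
            sections[sec].append(pool[tok_idx])
    # disease-correlated symptom tokens land in the chief complaint
    dpool = lex.disease_tokens.get(disease, [])
    if dpool:
        for tok_idx in rng.integers(0, len(dpool), size=1 + rng.integers(0, 2)):
            sections[section_names[0]].append(dpool[tok_idx])
    tokens: list[str] = []
    for sec in section_names:
        sec_tokens = sections[sec]
        rng.shuffle(sec_tokens)
        tokens.extend(sec_tokens)
    if cfg.noise_token_rate > 0 and lex.noise_tokens:
        rate = cfg.noise_token_rate
        n_noise = rng.poisson(len(tokens) * rate / (1.0 - rate))
        for tok_idx in rng.integers(0, len(lex.noise_tokens), size=n_noise):
            pos = rng.integers(0, len(tokens) + 1)
            tokens.insert(int(pos), lex.noise_tokens[tok_idx])
    if cfg.corpus_variant == 2:
        tokens.append(disease_token(disease))
    return ClinicalRecord(
        record_id=record_id,
        disease=disease,
        pattern=pattern,
        elements=frozenset(str(e) for e in elements),
        tokens=tokens,
        corpus_variant=cfg.corpus_variant,
    )


def generate_records(
    cfg: GeneratorConfig, rb: RuleBase, lex: Optional[Lexicon] = None
) -> list[ClinicalRecord]:
    """Draw ``cfg.n_records`` rule-consistent records; reproducible per seed."""
    cfg.validate()
    lex = lex if lex is not None else Lexicon.default()
    lex.validate()
    patterns_needed = {p for row in cfg.pattern_given_disease.values() for p in row}
    _check_rulebase(rb, patterns_needed)
    rng = np.random.default_rng(cfg.seed)
    diseases = list(cfg.disease_priors)
    dprobs = np.array([cfg.disease_priors[d] for d in diseases])
    dprobs = dprobs / dprobs.sum()
    records = []
    for i in range(cfg.n_records):
        disease = diseases[rng.choice(len(diseases), p=dprobs)]
        row = cfg.pattern_given_disease[disease]
        pats = list(row)
        pprobs = np.array([row[p] for p in pats])
        pattern = pats[rng.choice(len(pats), p=pprobs / pprobs.sum())]
        records.append(_make_record(rng, f"rec_{i:06d}", disease, pattern, rb, lex, cfg))
    return records


def generate_balanced(
    cfg: GeneratorConfig,
    rb: RuleBase,
    lex: Optional[Lexicon],
    patterns: Sequence[str],
    per_class_n: int,
) -> list[ClinicalRecord]:
    """Draw exactly ``per_class_n`` records per listed pattern.

    The disease is sampled from the Bayes inversion of the configured
    disease priors and disease-conditional pattern table, so balanced
    draws keep the disease-pattern dependence of the full generator.
    """
    cfg.validate()
    lex = lex if lex is not None else Lexicon.default()
    lex.validate()
    _check_rulebase(rb, patterns)
    rng = np.random.default_rng(cfg.seed)
    diseases = list(cfg.disease_priors)
    records = []
    i = 0
    for pattern in patterns:
        weights = np.array(
            [
                cfg.disease_priors[d] * cfg.pattern_given_disease[d].get(pattern, 0.0)
                for d in diseases
            ]
        )
        if weights.sum() <= 0:
            raise ConfigError(f"pattern {pattern!r} has zero mass under the generator")
        weights = weights / weights.sum()
        for _ in range(per_class_n):
            disease = diseases[rng.choice(len(diseases), p=weights)]
            records.append(
                _make_record(rng, f"rec_{i:06d}", disease, pattern, rb, lex, cfg)
            )
            i += 1
    return records


def expected_elements_per_record(cfg: GeneratorConfig, rb: RuleBase) -> float:
    """Rule-table-implied expectation of |elements| per generated record."""
    total = 0.0
    for d, pd in cfg.disease_priors.items():
        for p, pp in cfg.pattern_given_disease[d].items():
            total += pd * pp * len(rb.elements_for_pattern(p))
    return total


def split_dataset(
    records: Sequence[ClinicalRecord],
    ratio: tuple[int, int] = (4, 1),
    stratify_by: str = "pattern",
    seed: int = 0,
) -> tuple[list[ClinicalRecord], list[ClinicalRecord]]:
    """Exact train/test partition at ``ratio``; remainder rows go to train.

    A 4:1 split of 14,075 records therefore yields a 2,815-record test
    partition.  Stratified splitting keeps per-pattern test proportions
    within one record of the global proportion.
    """
    train_part, test_part = ratio
    if train_part <= 0 or test_part <= 0:
        raise ValueError("ratio parts must be positive")
    n = len(records)
    parts = train_part + test_part
    n_test = (n * test_part) // parts
    rng = np.random.default_rng(seed)
    if stratify_by == "none":
        order = rng.permutation(n)
        test_idx = set(order[:n_test].tolist())
    elif stratify_by == "pattern":
        by_class: dict[str, list[int]] = {}
        for i, r in enumerate(records):
            by_class.setdefault(r.pattern, []).append(i)
        too_small = [c for c, idxs in by_class.items() if len(idxs) < parts]
        if too_small:
            raise StratificationError(
                f"classes with fewer than {parts} records: {sorted(too_small)}"
            )
        base: dict[str, int] = {}
        frac: list[tuple[float, str]] = []
        for c, idxs in sorted(by_class.items()):
            exact = len(idxs) * test_part / parts
            base[c] = int(math.floor(exact))
            frac.append((exact - base[c], c))
        short = n_test - sum(base.values())
        for _, c in sorted(frac, key=lambda t: (-t[0], t[1]))[:short]:
            base[c] += 1
        test_idx = set()
        for c, idxs in sorted(by_class.items()):
            order = rng.permutation(len(idxs))
            test_idx.update(idxs[j] for j in order[: base[c]])
    else:
        raise ValueError("stratify_by must be 'pattern' or 'none'")
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test


def write_records(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    """Write records as UTF-8 JSON-lines, one record per line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(r.to_dict(), ensure_ascii=False) + "\n")


def read_records(path: str | Path) -> list[ClinicalRecord]:
    """Read a JSON-lines record file; parse failures name the line."""
    records = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                records.append(ClinicalRecord.from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError) as exc:
                raise RecordParseError(lineno, str(exc)) from exc
    return records
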
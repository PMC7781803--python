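"""Rule knowledge base linking syndrome elements to syndrome patterns.

This is the rule-based-reasoning (RBR) half of the hybrid diagnosis
pipeline.  A *syndrome element* is an atomic unit of TCM syndrome
classification (nine controlled labels: phlegm, wind, cold, heat,
qi-deficiency, yin-deficiency, lung, spleen, kidney).  A *syndrome
pattern* is a categorized diagnostic label (ten controlled labels);
each pattern is defined by a combination of elements, and forward
reasoning recovers the pattern from a predicted element set.

The default rule table ships with the package as an editable JSON file
(``data/default_rules.json``); any table conforming to the same schema
can be loaded in its place, so the reasoning engine stays correct under
a revised or site-specific knowledge base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "ELEMENTS",
    "PATTERNS",
    "SyndromeElement",
    "SyndromePattern",
    "CombinationRule",
    "RuleBase",
    "MatchResult",
    "ValidationReport",
    "RuleBaseError",
    "SchemaError",
    "VocabularyError",
    "PatternLookupError",
    "load_rulebase",
    "elements_for_pattern",
    "pattern_for_elements",
    "validate_rulebase",
]

#: Closed vocabulary of the nine syndrome-element types.
ELEMENTS: tuple[str, ...] = (
    "phlegm",
    "wind",
    "cold",
    "heat",
    "qi-deficiency",
    "yin-deficiency",
    "lung",
    "spleen",
    "kidney",
)

#: Closed vocabulary of the ten syndrome-pattern types.
PATTERNS: tuple[str, ...] = (
    "qi-deficiency of lung and spleen",
    "qi-deficiency of lung and kidney",
    "yin-deficiency of lung",
    "wind-cold attacking lung",
    "wind-heat attacking lung",
    "cold wheezing",
    "deficiency of qi and yin",
    "hot wheezing",
    "phlegm-heat obstruction in lung",
    "phlegm obstruction in lung",
)


class RuleBaseError(Exception):
    """Base class for rule-base errors."""


class SchemaError(RuleBaseError):
    """The rule-base file violates the JSON schema."""


class VocabularyError(RuleBaseError):
    """A label is outside the closed element/pattern vocabulary."""


class PatternLookupError(RuleBaseError, KeyError):
    """Requested pattern has no rule in the rule base."""


class SyndromeElement(str):
    """A syndrome-element label; membership in :data:`ELEMENTS` is enforced."""

    __slots__ = ()

    def __new__(cls, name: str) -> "SyndromeElement":
        if name not in ELEMENTS:
            raise VocabularyError(
                f"unknown syndrome element {name!r}; expected one of {ELEMENTS}"
            )
        return super().__new__(cls, name)


class SyndromePattern(str):
    """A syndrome-pattern label; membership in :data:`PATTERNS` is enforced."""

    __slots__ = ()

    def __new__(cls, name: str) -> "SyndromePattern":
        if name not in PATTERNS:
            raise VocabularyError(
                f"unknown syndrome pattern {name!r}; expected one of {PATTERNS}"
            )
        return super().__new__(cls, name)


@dataclass(frozen=True)
class CombinationRule:
    """One rule: an element combination that defines a syndrome pattern.

    ``priority`` is an integer rank, lower = preferred when several rules
    tie on overlap (e.g. duplicate element sets).  Tie-breaking by explicit
    priority rather than file order keeps reasoning reproducible under
    re-serialization of the rule file.
    """

    pattern: SyndromePattern
    elements: frozenset[SyndromeElement]
    priority: int

    def __post_init__(self) -> None:
        if not self.elements:
            raise SchemaError(f"rule for {self.pattern!r} has an empty element set")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of forward reasoning from an element set to a pattern.

    ``status``:

    - ``exact`` — the element set equals a single rule's set (Jaccard 1).
    - ``partial`` — a unique rule maximizes the Jaccard overlap above the
      partial-match floor.
    - ``ambiguous`` — several rules tie at the maximal overlap; resolved to
      the lowest priority rank, but all tied rules are listed.
    - ``none`` — no rule reaches the floor; ``pattern`` is ``None``.
    """

    pattern: Optional[SyndromePattern]
    status: str
    matched_rule_ids: tuple[int, ...]
    overlap_score: float

    def to_dict(self) -> dict:
        return {
            "pattern": str(self.pattern) if self.pattern is not None else None,
            "status": self.status,
            "matched_rule_ids": list(self.matched_rule_ids),
            "overlap_score": self.overlap_score,
        }


@dataclass
class ValidationReport:
    """Report-only validation of a rule base (no exceptions raised)."""

    missing_patterns: list[str] = field(default_factory=list)
    duplicate_sets: list[tuple[int, int]] = field(default_factory=list)
    unused_elements: list[str] = field(default_factory=list)
    roundtrip: dict[str, bool] = field(default_factory=dict)

    @property
    def roundtrip_ok(self) -> bool:
        return all(self.roundtrip.values())

    @property
    def ok(self) -> bool:
        return not self.missing_patterns and not self.duplicate_sets and self.roundtrip_ok


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


@dataclass
class RuleBase:
    """Ordered collection of combination rules plus a free-text version tag."""

    rules: list[CombinationRule]
    version: str = "unversioned"
    partial_floor: float = 0.5

    def __post_init__(self) -> None:
        priorities = [r.priority for r in self.rules]
        if len(set(priorities)) != len(priorities):
            raise SchemaError("rule priorities must be unique within a rule base")

    def __contains__(self, pattern: str) -> bool:
        return any(r.pattern == pattern for r in self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def patterns(self) -> list[SyndromePattern]:
        """Patterns covered by the rule base, in rule order (deduplicated)."""
        seen: dict[str, SyndromePattern] = {}
        for r in self.rules:
            seen.setdefault(str(r.pattern), r.pattern)
        return list(seen.values())

    def elements_for_pattern(self, pattern: str) -> frozenset[SyndromeElement]:
        """Element set of the highest-priority (lowest rank) rule for ``pattern``."""
        candidates = [r for r in self.rules if r.pattern == pattern]
        if not candidates:
            raise PatternLookupError(pattern)
        return min(candidates, key=lambda r: r.priority).elements

    def pattern_for_elements(self, elements: Iterable[str]) -> MatchResult:
        """Forward reasoning: combine an element set into a syndrome pattern.

        Exact set equality with a rule wins outright; otherwise the rule(s)
        maximizing the Jaccard overlap ``|a∩b| / |a∪b|`` compete, subject to
        the partial-match floor.  Ties (including duplicate element sets)
        resolve to the lowest priority rank but every tied rule id is
        reported, so ambiguity is visible to callers.
        """
        els = frozenset(SyndromeElement(e) for e in elements)
        if not els:
            raise ValueError("element set must be non-empty")
        scores = [(_jaccard(els, r.elements), i) for i, r in enumerate(self.rules)]
        best = max(s for s, _ in scores)
        maximizers = [i for s, i in scores if s == best]
        if best >= 1.0:
            status = "exact" if len(maximizers) == 1 else "ambiguous"
        elif best >= self.partial_floor:
            status = "partial" if len(maximizers) == 1 else "ambiguous"
        else:
            return MatchResult(None, "none", (), best)
        winner = min(maximizers, key=lambda i: self.rules[i].priority)
        return MatchResult(
            self.rules[winner].pattern, status, tuple(maximizers), best
        )

    def validate(self) -> ValidationReport:
        """Coverage, duplicate-set, unused-element and round-trip checks."""
        report = ValidationReport()
        report.missing_patterns = [p for p in PATTERNS if p not in self]
        for i in range(len(self.rules)):
            for j in range(i + 1, len(self.rules)):
                if self.rules[i].elements == self.rules[j].elements:
                    report.duplicate_sets.append((i, j))
        used = frozenset().union(*(r.elements for r in self.rules)) if self.rules else frozenset()
        report.unused_elements = [e for e in ELEMENTS if e not in used]
        for p in self.patterns:
            res = self.pattern_for_elements(self.elements_for_pattern(p))
            report.roundtrip[str(p)] = res.status == "exact" and res.pattern == p
        return report

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "rules": [
                {
                    "pattern": str(r.pattern),
                    "elements": sorted(r.elements),
                    "priority": r.priority,
                }
                for r in self.rules
            ],
        }


def _parse_rule(obj: dict, index: int) -> CombinationRule:
    try:
        pattern = obj["pattern"]
        elements = obj["elements"]
        priority = obj["priority"]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"rule #{index}: missing field {exc}") from exc
    if not isinstance(elements, list) or not elements:
        raise SchemaError(f"rule #{index} ({pattern!r}): elements must be a non-empty list")
    if not isinstance(priority, int):
        raise SchemaError(f"rule #{index} ({pattern!r}): priority must be an integer")
    return CombinationRule(
        pattern=SyndromePattern(pattern),
        elements=frozenset(SyndromeElement(e) for e in elements),
        priority=priority,
    )


def load_rulebase(path: Optional[str | Path] = None) -> RuleBase:
    """Load and validate a rule base; the packaged default table if ``path`` is None."""
    if path is None:
        text = resources.files("syndromedx.data").joinpath("default_rules.json").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"rule-base file is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "rules" not in payload:
        raise SchemaError("rule-base file must be an object with a 'rules' array")
    rules = [_parse_rule(r, i) for i, r in enumerate(payload["rules"])]
    return RuleBase(rules=rules, version=str(payload.get("version", "unversioned")))


def elements_for_pattern(rb: RuleBase, pattern: str) -> frozenset[SyndromeElement]:
    return rb.elements_for_pattern(pattern)


def pattern_for_elements(rb: RuleBase, elements: Iterable[str]) -> MatchResult:
    return rb.pattern_for_elements(elements)


def validate_rulebase(rb: RuleBase) -> ValidationReport:
    return rb.validate()
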
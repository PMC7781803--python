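"""Corpus assembly: records → token documents, with a pluggable segmenter.

Corpus 1 carries the syndrome/sign sections only ("four diagnoses"
context); corpus 2 additionally carries one modern-medicine diagnosis
token per record, appended at the end of the document so the two corpora
differ by a deterministic delta.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from .synthetic import ClinicalRecord, disease_token

__all__ = ["Corpus", "build_corpus", "segment_text", "write_line_sentences"]


@dataclass
class Corpus:
    """Ordered token documents plus their vocabulary counts."""

    documents: list[tuple[str, list[str]]]
    variant: int
    vocabulary: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def token_lists(self) -> list[list[str]]:
        return [toks for _, toks in self.documents]


def build_corpus(records: Sequence[ClinicalRecord], variant: int = 1) -> Corpus:
    """Assemble the variant-1 or variant-2 corpus from records.

    Variant 2 appends the diagnosis token unless the record already
    carries it (records generated with ``corpus_variant=2``).
    """
    if variant not in (1, 2):
        raise ValueError("variant must be 1 or 2")
    documents: list[tuple[str, list[str]]] = []
    vocab: Counter = Counter()
    for r in records:
        tokens = list(r.tokens)
        if variant == 2:
            if not r.disease:
                raise ValueError(f"record {r.record_id!r} has no disease label")
            dtok = disease_token(r.disease)
            if r.corpus_variant != 2:
                tokens.append(dtok)
            elif not tokens or tokens[-1] != dtok:
                tokens.append(dtok)
        elif r.corpus_variant == 2:
            # strip the appended diagnosis token to recover the plain context
            dtok = disease_token(r.disease)
            if tokens and tokens[-1] == dtok:
                tokens = tokens[:-1]
        documents.append((r.record_id, tokens))
        vocab.update(tokens)
    return Corpus(documents=documents, variant=variant, vocabulary=vocab)


def segment_text(
    raw_text: str, segmenter: Optional[Callable[[str], Iterable[str]]] = None
) -> list[str]:
    """Tokenize raw text with a user-supplied word-cutting function.

    No segmentation is built in (Chinese word-cutting is out of scope);
    the segmenter's output is passed through unchanged apart from
    whitespace trimming and empty-token removal.
    """
    if segmenter is None:
        raise ValueError(
            "a segmenter callable is required for raw-text input; "
            "pre-tokenized records bypass segmentation entirely"
        )
    return [t.strip() for t in segmenter(raw_text) if t and t.strip()]


def write_line_sentences(corpus: Corpus, path: str | Path) -> None:
    """Export one space-joined document per line (line-sentence format)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for _, tokens in corpus.documents:
            fh.write(" ".join(tokens) + "\n")
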
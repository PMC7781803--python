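"""Word- and document-level embeddings for tokenized clinical text.

Compact numpy implementations of the two classical embedding trainers:

- skip-gram with negative sampling (word level) — each vocabulary token
  gets a dense vector trained to predict its window context;
- PV-DBOW (document level) — each document gets a dense vector trained
  to predict its own tokens, and vectors for unseen documents are
  obtained by gradient inference against the frozen word output matrix.

Both are single-threaded and fully deterministic under a fixed seed.
Defaults follow the reference configuration (word: 256 dimensions,
window 5, min_count 10; document: 192 dimensions), with every
hyperparameter configurable downward for desk-scale runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "EmbeddingModel",
    "DocumentEmbeddingModel",
    "DocumentRepresentation",
    "EmptyVocabularyError",
    "ContractError",
    "train_word_model",
    "train_doc_model",
    "represent",
    "representation_matrix",
    "suggest_max_len",
    "cnn_embedding_matrix",
]


class EmptyVocabularyError(ValueError):
    """No token survived the min_count threshold."""


class ContractError(TypeError):
    """Representation mode incompatible with the model level or input."""


TokenDocs = Sequence[Sequence[str]]


def _token_lists(corpus) -> list[list[str]]:
    if hasattr(corpus, "token_lists"):
        return corpus.token_lists
    return [list(doc) for doc in corpus]


def _build_vocab(docs: TokenDocs, min_count: int) -> tuple[list[str], np.ndarray]:
    counts: dict[str, int] = {}
    for doc in docs:
        for tok in doc:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    if not vocab:
        raise EmptyVocabularyError(
            f"no token reaches min_count={min_count}; lower the threshold"
        )
    return vocab, np.array([counts[t] for t in vocab], dtype=np.float64)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _sgns_train(
    pairs: np.ndarray,
    w_in: np.ndarray,
    w_out: np.ndarray,
    noise_probs: np.ndarray,
    epochs: int,
    learning_rate: float,
    negative: int,
    rng: np.random.Generator,
    batch_size: int = 1024,
    update_out: bool = True,
) -> None:
    """In-place negative-sampling training over (input, output-word) pairs."""
    n_pairs = len(pairs)
    if n_pairs == 0:
        return
    total_batches = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    step = 0
    noise_cdf = np.cumsum(noise_probs)
    noise_cdf[-1] = 1.0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            lr = learning_rate * max(1e-4, 1.0 - step / total_batches)
            step += 1
            batch = pairs[order[start : start + batch_size]]
            ci, oi = batch[:, 0], batch[:, 1]
            b = len(batch)
            neg = np.searchsorted(noise_cdf, rng.random((b, negative)))
            ctx = np.concatenate([oi[:, None], neg], axis=1)
            labels = np.zeros((b, negative + 1))
            labels[:, 0] = 1.0
            h = w_in[ci]
            u = w_out[ctx]
            g = (_sigmoid(np.einsum("bd,bkd->bk", h, u)) - labels) * lr
            dh = np.einsum("bk,bkd->bd", g, u)
            if update_out:
                np.add.at(w_out, ctx, -g[:, :, None] * h[:, None, :])
            np.add.at(w_in, ci, -dh)


@dataclass
class EmbeddingModel:
    """Token → vector lookup trained at word level."""

    level: str
    dimension: int
    window: int
    min_count: int
    vocab: list[str]
    vectors: np.ndarray
    out_weights: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.vocab)}

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def vocabulary(self) -> list[str]:
        return list(self.vocab)

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.index[token]]

    def save_word2vec_format(self, path: str | Path) -> None:
        """Plain-text word-vector format: header ``vocab_size dimension``."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocab)} {self.dimension}\n")
            for tok, vec in zip(self.vocab, self.vectors):
                fh.write(tok + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")

    @classmethod
    def load_word2vec_format(cls, path: str | Path) -> "EmbeddingModel":
        with Path(path).open("r", encoding="utf-8") as fh:
            header = fh.readline().split()
            n, dim = int(header[0]), int(header[1])
            vocab, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vocab.append(parts[0])
                rows.append([float(x) for x in parts[1 : dim + 1]])
        if len(vocab) != n:
            raise ValueError(f"header promises {n} vectors, file has {len(vocab)}")
        vecs = np.asarray(rows, dtype=np.float64)
        return cls(
            level="word", dimension=dim, window=0, min_count=0,
            vocab=vocab, vectors=vecs, out_weights=np.zeros_like(vecs),
        )


class DocumentEmbeddingModel(EmbeddingModel):
    """PV-DBOW model: stored training-document vectors plus inference."""

    def __init__(
        self,
        dimension: int,
        window: int,
        min_count: int,
        vocab: list[str],
        out_weights: np.ndarray,
        noise_probs: np.ndarray,
        doc_ids: list[str],
        doc_vectors: np.ndarray,
        seed: int = 0,
        infer_epochs: int = 50,
        negative: int = 5,
        learning_rate: float = 0.025,
    ):
        super().__init__(
            level="document", dimension=dimension, window=window,
            min_count=min_count, vocab=vocab,
            vectors=np.zeros((len(vocab), dimension)),
            out_weights=out_weights, seed=seed,
        )
        self.doc_ids = doc_ids
        self.doc_vectors = doc_vectors
        self.infer_epochs = infer_epochs
        self.negative = negative
        self.learning_rate = learning_rate
        self._noise_probs = noise_probs

    def infer(self, tokens: Sequence[str], seed: Optional[int] = None) -> np.ndarray:
        """Gradient inference of a document vector against frozen word weights."""
        widx = np.array([self.index[t] for t in tokens if t in self.index], dtype=np.int64)
        rng = np.random.default_rng(self.seed if seed is None else seed)
        v = (rng.random((1, self.dimension)) - 0.5) / self.dimension
        if len(widx) == 0:
            warnings.warn("document has no in-vocabulary token; returning the random init")
            return v[0]
        pairs = np.stack([np.zeros_like(widx), widx], axis=1)
        _sgns_train(
            pairs, v, self.out_weights, self._noise_probs,
            epochs=self.infer_epochs, learning_rate=self.learning_rate,
            negative=self.negative, rng=rng, update_out=False,
        )
        return v[0]


@dataclass
class DocumentRepresentation:
    """Fixed-length numeric representation of one document."""

    mode: str
    payload: np.ndarray


def train_word_model(
    corpus,
    dimension: int = 256,
    window: int = 5,
    min_count: int = 10,
    seed: int = 0,
    epochs: int = 5,
    negative: int = 5,
    learning_rate: float = 0.025,
) -> EmbeddingModel:
    """Skip-gram negative-sampling training on a tokenized corpus."""
    docs = _token_lists(corpus)
    if not docs:
        raise ValueError("corpus is empty")
    vocab, counts = _build_vocab(docs, min_count)
    index = {t: i for i, t in enumerate(vocab)}
    pair_chunks = []
    for doc in docs:
        idx = np.array([index[t] for t in doc if t in index], dtype=np.int64)
        for off in range(1, window + 1):
            if len(idx) <= off:
                break
            a, b = idx[:-off], idx[off:]
            pair_chunks.append(np.stack([a, b], axis=1))
            pair_chunks.append(np.stack([b, a], axis=1))
    pairs = (
        np.concatenate(pair_chunks) if pair_chunks else np.empty((0, 2), dtype=np.int64)
    )
    rng = np.random.default_rng(seed)
    w_in = (rng.random((len(vocab), dimension)) - 0.5) / dimension
    w_out = np.zeros((len(vocab), dimension))
    noise = counts**0.75
    noise /= noise.sum()
    _sgns_train(pairs, w_in, w_out, noise, epochs, learning_rate, negative, rng)
    return EmbeddingModel(
        level="word", dimension=dimension, window=window, min_count=min_count,
        vocab=vocab, vectors=w_in, out_weights=w_out, seed=seed,
    )


def train_doc_model(
    corpus,
    dimension: int = 192,
    window: int = 5,
    min_count: int = 10,
    seed: int = 0,
    epochs: int = 20,
    negative: int = 5,
    learning_rate: float = 0.05,
    infer_epochs: int = 100,
) -> DocumentEmbeddingModel:
    """PV-DBOW training: document vectors predicting their own tokens.

    Defaults are heavier than the word trainer's because the document
    task sees each (doc, word) pair once per epoch; downstream use
    should represent *all* documents (training ones included) by
    :meth:`DocumentEmbeddingModel.infer` so representations are
    exchangeable between fitting and scoring.
    """
    docs = _token_lists(corpus)
    if not docs:
        raise ValueError("corpus is empty")
    doc_ids = [
        doc_id for doc_id, _ in getattr(corpus, "documents", [])
    ] or [f"doc_{i}" for i in range(len(docs))]
    vocab, counts = _build_vocab(docs, min_count)
    index = {t: i for i, t in enumerate(vocab)}
    pair_chunks = []
    for di, doc in enumerate(docs):
        idx = np.array([index[t] for t in doc if t in index], dtype=np.int64)
        if len(idx):
            pair_chunks.append(np.stack([np.full_like(idx, di), idx], axis=1))
    pairs = (
        np.concatenate(pair_chunks) if pair_chunks else np.empty((0, 2), dtype=np.int64)
    )
    rng = np.random.default_rng(seed)
    d_in = (rng.random((len(docs), dimension)) - 0.5) / dimension
    w_out = np.zeros((len(vocab), dimension))
    noise = counts**0.75
    noise /= noise.sum()
    _sgns_train(pairs, d_in, w_out, noise, epochs, learning_rate, negative, rng)
    return DocumentEmbeddingModel(
        dimension=dimension, window=window, min_count=min_count, vocab=vocab,
        out_weights=w_out, noise_probs=noise, doc_ids=doc_ids, doc_vectors=d_in,
        seed=seed, infer_epochs=infer_epochs, negative=negative,
        learning_rate=learning_rate,
    )


def represent(
    model: EmbeddingModel,
    tokens: Sequence[str],
    mode: str = "mean_vector",
    max_len: Optional[int] = None,
) -> DocumentRepresentation:
    """Turn one token sequence into a classifier-ready representation.

    - ``mean_vector``: unweighted mean of in-vocabulary word vectors
      (zero vector, with a warning, when nothing is in vocabulary);
    - ``index_sequence``: vocabulary indices shifted by +1 (0 = padding
      and unknown), right-padded/truncated to ``max_len`` keeping the
      earliest tokens;
    - ``doc_vector``: PV-DBOW inference (document models only).
    """
    if mode == "doc_vector":
        if model.level != "document":
            raise ContractError("doc_vector mode requires a document-level model")
        return DocumentRepresentation(mode, model.infer(tokens))
    if model.level != "word":
        raise ContractError(f"{mode} mode requires a word-level model")
    if mode == "mean_vector":
        vecs = [model.vector(t) for t in tokens if t in model]
        if not vecs:
            warnings.warn("all tokens out of vocabulary; returning the zero vector")
            return DocumentRepresentation(mode, np.zeros(model.dimension))
        return DocumentRepresentation(mode, np.mean(vecs, axis=0))
    if mode == "index_sequence":
        if max_len is None:
            raise ContractError("index_sequence mode requires max_len")
        seq = np.zeros(max_len, dtype=np.int64)
        kept = [model.index.get(t, -1) + 1 for t in tokens[:max_len]]
        seq[: len(kept)] = kept
        return DocumentRepresentation(mode, seq)
    raise ContractError(f"unknown representation mode {mode!r}")


def representation_matrix(
    model: EmbeddingModel,
    docs: TokenDocs,
    mode: str = "mean_vector",
    max_len: Optional[int] = None,
) -> np.ndarray:
    """Stack :func:`represent` over documents into one 2-D array."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.stack([represent(model, d, mode, max_len).payload for d in docs])


def suggest_max_len(docs: TokenDocs, percentile: float = 95.0) -> int:
    """Default sequence length: the 95th percentile of document lengths."""
    lengths = [len(d) for d in docs]
    if not lengths:
        raise ValueError("no documents")
    return max(1, int(np.ceil(np.percentile(lengths, percentile))))


def cnn_embedding_matrix(model: EmbeddingModel) -> np.ndarray:
    """Embedding-layer initializer: row 0 = padding/unknown (zeros)."""
    if model.level != "word":
        raise ContractError("CNN embeddings require a word-level model")
    return np.vstack([np.zeros((1, model.dimension)), model.vectors])
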
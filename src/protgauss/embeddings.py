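"""k-mer embedding tables and per-sequence feature matrices.

An :class:`EmbeddingTable` maps length-``k`` amino-acid tokens to
``d``-dimensional real vectors. Tables can be loaded from the plain-text
one-token-per-line convention used by distributed protein k-mer
embeddings, or trained here with a skip-gram negative-sampling (SGNS)
word-embedding model on k-mer token streams.

``featurize`` stacks the vectors of a sequence's overlapping k-mers into
an ``L' x d`` matrix, skipping (and counting) tokens absent from the
table — the raw material for the Gaussian sequence representation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ValidationError
from .seqio import ProteinSequence, split_subsequences

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingTable:
    """Mapping from k-mer tokens to d-dimensional embedding vectors."""

    k: int
    d: int
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValidationError("embedding dimension must be positive")
        for tok, vec in self.vectors.items():
            if len(tok) != self.k:
                raise ValidationError(f"token {tok!r} does not have length {self.k}")
            if vec.shape != (self.d,):
                raise ValidationError(f"vector for {tok!r} does not have length {self.d}")

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def save(self, path) -> None:
        """Write the table as text: token followed by d floats per line."""
        with open(path, "w") as fh:
            for tok in self.vectors:
                vals = " ".join(repr(float(v)) for v in self.vectors[tok])
                fh.write(f"{tok} {vals}\n")


@dataclass
class FeatureMatrix:
    """Embedded k-mers of one sequence, one row per embeddable token."""

    parent_id: str
    rows: np.ndarray
    n_skipped: int = 0

    @property
    def n_tokens(self) -> int:
        return self.rows.shape[0]


def load_embedding_table(path) -> EmbeddingTable:
    """Parse a whitespace-delimited token-plus-floats embedding file.

    An optional leading header of two integers ("vocab_size d") is
    accepted and ignored. Duplicate tokens keep the last definition with
    a warning; ragged rows or mixed token lengths are format errors.
    """
    vectors: dict[str, np.ndarray] = {}
    k = d = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2 and parts[0].isdigit() and parts[1].isdigit():
                continue  # gensim-style "vocab d" header
            token, floats = parts[0], parts[1:]
            try:
                vec = np.array([float(x) for x in floats], dtype=float)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric embedding value") from exc
            if d is None:
                if vec.size == 0:
                    raise FormatError(f"{path}:{lineno}: no embedding values on line")
                k, d = len(token), vec.size
            if len(token) != k:
                raise FormatError(
                    f"{path}:{lineno}: token {token!r} has length {len(token)}, expected {k}"
                )
            if vec.size != d:
                raise FormatError(
                    f"{path}:{lineno}: expected {d} values, found {vec.size}"
                )
            if token in vectors:
                logger.warning("duplicate token %r at line %d: last definition wins", token, lineno)
            vectors[token] = vec
    if not vectors:
        raise FormatError(f"{path}: no embedding vectors found")
    return EmbeddingTable(k=k, d=d, vectors=vectors)


@dataclass
class TrainingParams:
    """SGNS hyperparameters (word2vec lineage defaults, all overridable)."""

    window: int = 5
    negative: int = 5
    min_count: int = 1
    epochs: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    seed: int = 0
    corpus_style: str = "overlapping"  # or "shifted"


def _token_streams(corpus: list[ProteinSequence], k: int, style: str) -> list[list[str]]:
    """Tokenize each sequence into one or more sentences of k-mers.

    ``overlapping``: one sentence of all l-k+1 overlapping k-mers.
    ``shifted``: k sentences of non-overlapping k-mers at phase offsets
    0..k-1 (the original protein-word2vec corpus construction).
    """
    sentences: list[list[str]] = []
    for seq in corpus:
        if len(seq) < k:
            continue
        if style == "overlapping":
            sentences.append(list(split_subsequences(seq, k).tokens))
        elif style == "shifted":
            for phase in range(k):
                toks = [
                    seq.residues[i : i + k]
                    for i in range(phase, len(seq) - k + 1, k)
                ]
                if toks:
                    sentences.append(toks)
        else:
            raise ValidationError(f"unknown corpus style {style!r}")
    return sentences


def _sigmoid(x: float) -> float:
    if x > 30:
        return 1.0
    if x < -30:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


def train_embeddings(
    corpus: list[ProteinSequence],
    k: int,
    d: int = 100,
    params: TrainingParams | None = None,
) -> EmbeddingTable:
    """Train a skip-gram negative-sampling embedding on k-mer sentences.

    Single-threaded stochastic gradient descent over all (center,
    context) pairs within a per-position random dynamic window, with
    ``negative`` noise tokens per pair drawn from the unigram^0.75
    distribution. Deterministic for a fixed seed.
    """
    if not corpus:
        raise ValidationError("training corpus is empty")
    if k < 1 or d < 2:
        raise ValidationError("require k >= 1 and d >= 2")
    p = params or TrainingParams()

    sentences = _token_streams(corpus, k, p.corpus_style)
    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(tok for tok, c in counts.items() if c >= p.min_count)
    if not vocab:
        raise ValidationError("corpus yields no tokens at the requested min_count")
    index = {tok: i for i, tok in enumerate(vocab)}
    V = len(vocab)

    rng = np.random.default_rng(p.seed)
    w_in = (rng.random((V, d)) - 0.5) / d
    w_out = np.zeros((V, d))

    # unigram^0.75 cumulative table for negative sampling
    freq = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
    cum = np.cumsum(freq / freq.sum())

    encoded = [
        np.array([index[t] for t in sent if t in index], dtype=np.int64)
        for sent in sentences
    ]
    encoded = [s for s in encoded if s.size > 0]

    total_positions = sum(s.size for s in encoded) * p.epochs
    pos_done = 0
    lr0, lr1 = p.learning_rate, p.min_learning_rate
    for _epoch in range(p.epochs):
        for sent in encoded:
            n = sent.size
            for i in range(n):
                lr = max(lr1, lr0 * (1.0 - pos_done / max(total_positions, 1)))
                pos_done += 1
                b = int(rng.integers(1, p.window + 1))
                center = sent[i]
                for j in range(max(0, i - b), min(n, i + b + 1)):
                    if j == i:
                        continue
                    ctx = sent[j]
                    vi = w_in[center]
                    grad_in = np.zeros(d)
                    # positive pair
                    f = _sigmoid(float(vi @ w_out[ctx]))
                    g = (1.0 - f) * lr
                    grad_in += g * w_out[ctx]
                    w_out[ctx] += g * vi
                    # negative samples
                    for _ in range(p.negative):
                        neg = int(np.searchsorted(cum, rng.random()))
                        if neg == ctx:
                            continue
                        f = _sigmoid(float(vi @ w_out[neg]))
                        g = -f * lr
                        grad_in += g * w_out[neg]
                        w_out[neg] += g * vi
                    w_in[center] += grad_in

    return EmbeddingTable(k=k, d=d, vectors={t: w_in[index[t]].copy() for t in vocab})


def featurize(seq: ProteinSequence, table: EmbeddingTable, k: int) -> FeatureMatrix:
    """Stack the table vectors of ``seq``'s overlapping k-mers row-wise.

    Tokens absent from the table are skipped and counted; a sequence
    with zero embeddable tokens is an error.
    """
    if k != table.k:
        raise ValidationError(
            f"requested subsequence length {k} does not match table k={table.k}"
        )
    tokens = split_subsequences(seq, k).tokens
    rows = [table.vectors[t] for t in tokens if t in table.vectors]
    n_skipped = len(tokens) - len(rows)
    if not rows:
        raise ValidationError(f"sequence {seq.id!r} has no tokens covered by the table")
    return FeatureMatrix(parent_id=seq.id, rows=np.array(rows, dtype=float), n_skipped=n_skipped)
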
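"""Vocabularies, embedding tables and document featurization.

Per-token model input is the concatenation of the enabled embeddings:
50-dim word vectors, optionally 5-dim POS and 5-dim NER (BIO) vectors,
giving input widths 50/55/60.  All embedding tables are trainable model
parameters; the PAD row is pinned to zero so padded positions are inert.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .corpus_io import Document, Label, LabeledCorpus

__all__ = [
    "PAD_ID",
    "UNK_ID",
    "Vocabulary",
    "EmbeddingKind",
    "EmbeddingTable",
    "FeaturizedDocument",
    "build_vocab",
    "build_tag_vocab",
    "load_word_vectors",
    "encode_bio",
    "featurize",
]

PAD_ID = 0
UNK_ID = 1
_RESERVED = ("<pad>", "<unk>")


@dataclass
class Vocabulary:
    """Token ↔ integer id bijection with reserved PAD=0 and UNK=1."""

    token_to_id: dict[str, int]
    id_to_token: list[str]

    def __len__(self) -> int:
        return len(self.id_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def get(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    @classmethod
    def from_tokens(cls, tokens: list[str]) -> "Vocabulary":
        id_to_token = list(_RESERVED) + tokens
        return cls({t: i for i, t in enumerate(id_to_token)}, id_to_token)


class EmbeddingKind(Enum):
    WORD = "word"
    POS = "pos"
    NER = "ner"


@dataclass
class EmbeddingTable:
    kind: EmbeddingKind
    dim: int
    vectors: np.ndarray  # (vocab_size, dim)
    trainable: bool = True

    def __post_init__(self) -> None:
        if self.vectors.shape[1] != self.dim:
            raise ValueError("vector width does not match dim")

    @classmethod
    def random(
        cls, kind: EmbeddingKind, vocab: Vocabulary, dim: int, seed: int = 0
    ) -> "EmbeddingTable":
        rng = np.random.default_rng(seed)
        vectors = rng.uniform(-0.05, 0.05, size=(len(vocab), dim))
        vectors[PAD_ID] = 0.0
        return cls(kind=kind, dim=dim, vectors=vectors)


@dataclass
class FeaturizedDocument:
    """Integer id sequences per sentence, ready for a model."""

    doc_id: str
    word_ids: list[list[int]]
    pos_ids: list[list[int]] | None = None
    ner_ids: list[list[int]] | None = None
    label: int | None = None  # 0/1; None for unlabeled

    def __post_init__(self) -> None:
        shape = [len(s) for s in self.word_ids]
        for ids, name in ((self.pos_ids, "pos_ids"), (self.ner_ids, "ner_ids")):
            if ids is not None and [len(s) for s in ids] != shape:
                raise ValueError(f"{name} shape differs from word_ids")

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.word_ids)

    def flat_word_ids(self) -> list[int]:
        return [i for s in self.word_ids for i in s]


def build_vocab(corpus: LabeledCorpus, min_count: int = 1) -> Vocabulary:
    """Tokens with frequency >= min_count, ordered by frequency then
    lexicographically; corpus must be preprocessed."""
    if len(corpus) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: Counter[str] = Counter()
    for doc in corpus:
        if doc.sentences is None:
            raise ValueError(f"document {doc.doc_id!r} is not preprocessed")
        for sent in doc.sentences:
            counts.update(sent)
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    return Vocabulary.from_tokens(kept)


def build_tag_vocab(tag_lists: list[list[str]]) -> Vocabulary:
    """Vocabulary over a closed tag set (POS or BIO-NER)."""
    tags = sorted({t for sent in tag_lists for t in sent})
    return Vocabulary.from_tokens(tags)


def load_word_vectors(
    path: str | Path,
    vocab: Vocabulary,
    seed: int = 0,
    expected_dim: int | None = None,
) -> EmbeddingTable:
    """Load word2vec/fastText plain-text vectors for a vocabulary.

    Rows for vocabulary tokens present in the file are copied verbatim;
    missing tokens (UNK included) are drawn from a seeded uniform on
    [-0.05, 0.05].  An optional "count dim" header line is tolerated.
    """
    path = Path(path)
    file_vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            if lineno == 1 and len(parts) == 2:
                continue  # header: "<count> <dim>"
            if len(parts) < 2:
                continue
            token, values = parts[0], parts[1:]
            vec = np.array([float(v) for v in values if v], dtype=np.float64)
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise ValueError(
                    f"inconsistent vector length at line {lineno}: {vec.size} != {dim}"
                )
            file_vectors[token] = vec
    if dim is None:
        raise ValueError(f"no vectors found in {path}")
    if expected_dim is not None and dim != expected_dim:
        raise ValueError(f"vector dim {dim} does not match configured dim {expected_dim}")
    rng = np.random.default_rng(seed)
    vectors = np.empty((len(vocab), dim))
    for idx, token in enumerate(vocab.id_to_token):
        if token in file_vectors:
            vectors[idx] = file_vectors[token]
        else:
            vectors[idx] = rng.uniform(-0.05, 0.05, size=dim)
    vectors[PAD_ID] = 0.0
    return EmbeddingTable(kind=EmbeddingKind.WORD, dim=dim, vectors=vectors)


def encode_bio(tokens: list[str], entity_spans: list[tuple[int, int, str]]) -> list[str]:
    """BIO tags from half-open token spans (start, end, entity_type)."""
    n = len(tokens)
    tags = ["O"] * n
    occupied = [False] * n
    for start, end, etype in entity_spans:
        if not (0 <= start < end <= n):
            raise ValueError(f"span ({start}, {end}) out of bounds for {n} tokens")
        if any(occupied[start:end]):
            raise ValueError(f"span ({start}, {end}) overlaps a previous span")
        for i in range(start, end):
            occupied[i] = True
            tags[i] = f"{'B' if i == start else 'I'}-{etype}"
    return tags


def featurize(
    doc: Document,
    vocab: Vocabulary,
    pos_vocab: Vocabulary | None = None,
    ner_vocab: Vocabulary | None = None,
    use_pos: bool = False,
    use_ner: bool = False,
) -> FeaturizedDocument:
    """Map a preprocessed document to integer id sequences (UNK fallback)."""
    if doc.sentences is None:
        raise ValueError(f"document {doc.doc_id!r} is not preprocessed")
    word_ids = [[vocab.get(t) for t in sent] for sent in doc.sentences]
    pos_ids = ner_ids = None
    if use_pos:
        if doc.pos_tags is None or pos_vocab is None:
            raise ValueError("POS features enabled but tags or vocabulary missing")
        pos_ids = [[pos_vocab.get(t) for t in sent] for sent in doc.pos_tags]
    if use_ner:
        if doc.ner_tags is None or ner_vocab is None:
            raise ValueError("NER features enabled but tags or vocabulary missing")
        ner_ids = [[ner_vocab.get(t) for t in sent] for sent in doc.ner_tags]
    label = None if doc.label is Label.UNKNOWN else int(doc.label.value)
    return FeaturizedDocument(
        doc_id=doc.doc_id, word_ids=word_ids, pos_ids=pos_ids, ner_ids=ner_ids, label=label
    )
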
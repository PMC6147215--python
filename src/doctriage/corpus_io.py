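"""Labeled document collections: reading, writing and splitting.

The on-disk dialect is line-delimited JSON (UTF-8), one record per line
with keys ``id``, ``title``, ``abstract`` and optionally ``label`` (1/0),
``sentences`` (tokenized), ``pos`` and ``ner`` (token-aligned tag lists).
A record without a label is an unlabeled document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = ["Label", "Document", "LabeledCorpus", "read_corpus", "write_corpus", "split_train_dev"]


class Label(Enum):
    NEGATIVE = 0
    POSITIVE = 1
    UNKNOWN = -1


@dataclass
class Document:
    """One article: identifier, text fields, label and optional annotations."""

    doc_id: str
    title: str
    abstract: str
    label: Label = Label.UNKNOWN
    sentences: list[list[str]] | None = None
    pos_tags: list[list[str]] | None = None
    ner_tags: list[list[str]] | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        for tags, name in ((self.pos_tags, "pos_tags"), (self.ner_tags, "ner_tags")):
            if tags is not None:
                if self.sentences is None:
                    raise ValueError(f"{name} present but document has no sentences")
                if [len(s) for s in tags] != [len(s) for s in self.sentences]:
                    raise ValueError(f"{name} shape does not match sentences")

    def copy(self) -> "Document":
        return replace(
            self,
            sentences=None if self.sentences is None else [list(s) for s in self.sentences],
            pos_tags=None if self.pos_tags is None else [list(s) for s in self.pos_tags],
            ner_tags=None if self.ner_tags is None else [list(s) for s in self.ner_tags],
        )


@dataclass
class LabeledCorpus:
    """An ordered document collection with unique identifiers."""

    name: str
    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            raise ValueError(f"corpus {self.name!r} contains duplicate doc_ids")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def label_counts(self) -> dict[Label, int]:
        counts = {Label.POSITIVE: 0, Label.NEGATIVE: 0, Label.UNKNOWN: 0}
        for d in self.documents:
            counts[d.label] += 1
        return counts


def _doc_to_record(doc: Document) -> dict:
    rec: dict = {"id": doc.doc_id, "title": doc.title, "abstract": doc.abstract}
    if doc.label is not Label.UNKNOWN:
        rec["label"] = doc.label.value
    if doc.sentences is not None:
        rec["sentences"] = doc.sentences
    if doc.pos_tags is not None:
        rec["pos"] = doc.pos_tags
    if doc.ner_tags is not None:
        rec["ner"] = doc.ner_tags
    return rec


def _record_to_doc(rec: dict, lineno: int) -> Document:
    try:
        label = Label.UNKNOWN if "label" not in rec else Label(int(rec["label"]))
        return Document(
            doc_id=str(rec["id"]),
            title=rec["title"],
            abstract=rec["abstract"],
            label=label,
            sentences=rec.get("sentences"),
            pos_tags=rec.get("pos"),
            ner_tags=rec.get("ner"),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"malformed record at line {lineno}: {exc}") from exc


def read_corpus(path: str | Path, name: str | None = None) -> LabeledCorpus:
    """Read a line-delimited JSON corpus, preserving document order."""
    path = Path(path)
    docs: list[Document] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"malformed JSON at line {lineno}: {exc}") from exc
            doc = _record_to_doc(rec, lineno)
            if doc.doc_id in seen:
                raise ValueError(f"duplicate doc_id {doc.doc_id!r} at line {lineno}")
            seen.add(doc.doc_id)
            docs.append(doc)
    return LabeledCorpus(name=name or path.stem, documents=docs)


def write_corpus(corpus: LabeledCorpus, path: str | Path) -> None:
    """Write one JSON record per document; read_corpus inverts this."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(json.dumps(_doc_to_record(doc), ensure_ascii=False) + "\n")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_train_dev(
    corpus: LabeledCorpus, dev_fraction: float, seed: int
) -> tuple[LabeledCorpus, LabeledCorpus]:
    """Uniform random disjoint split; dev size = round(n * dev_fraction)."""
    if not 0 < dev_fraction < 1:
        raise ValueError("dev_fraction must be in (0, 1)")
    n = len(corpus)
    if n == 0:
        raise ValueError("cannot split an empty corpus")
    n_dev = _round_half_up(n * dev_fraction)
    if n_dev == 0 or n_dev == n:
        raise ValueError(f"dev split of size {n_dev} out of {n} is degenerate")
    rng = np.random.default_rng(seed)
    dev_idx = set(rng.choice(n, size=n_dev, replace=False).tolist())
    train_docs = [d for i, d in enumerate(corpus.documents) if i not in dev_idx]
    dev_docs = [d for i, d in enumerate(corpus.documents) if i in dev_idx]
    return (
        LabeledCorpus(name=f"{corpus.name}-train", documents=train_docs),
        LabeledCorpus(name=f"{corpus.name}-dev", documents=dev_docs),
    )
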
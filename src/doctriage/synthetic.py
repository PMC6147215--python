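"""Synthetic corpora with planted lexical signal.

Emulates the target/auxiliary relationship of the triage problem: a
small target corpus whose positive class is marked by planted keywords,
and a larger auxiliary corpus whose positive-signal vocabulary overlaps
the target's by a controllable fraction.  Auxiliary negatives never
carry target-positive signal (the auxiliary concept subsumes the
target's).  Documents occasionally contain dash-joined entity pairs
("prota–protb") to exercise the tokenizer and the BIO tagger.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .corpus_io import Document, Label, LabeledCorpus
from .features import Vocabulary, encode_bio
from .preprocess import DASH_CHARS

__all__ = ["SyntheticSpec", "generate_corpus", "generate_auxiliary_corpus", "generate_tags", "write_toy_vectors"]

_POS_TAGS = ("NN", "VB", "JJ", "DT", "IN", "CD")


@dataclass(frozen=True)
class SyntheticSpec:
    n_docs: int = 200
    vocab_size: int = 120
    n_signal_pos: int = 10
    n_signal_neg: int = 10
    signal_rate: float = 1.0
    noise_rate: float = 0.0
    shared_signal_fraction: float = 0.8
    sent_len: tuple[int, int] = (4, 8)
    n_sent: tuple[int, int] = (2, 4)
    positive_prior: float = 0.5
    dash_pair_rate: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        for name in ("signal_rate", "noise_rate", "shared_signal_fraction", "positive_prior", "dash_pair_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.vocab_size <= self.n_signal_pos + self.n_signal_neg:
            raise ValueError("vocab_size must exceed the number of signal tokens")
        if self.n_docs < 1:
            raise ValueError("n_docs must be positive")
        for name in ("sent_len", "n_sent"):
            lo, hi = getattr(self, name)
            if not 1 <= lo <= hi:
                raise ValueError(f"invalid range for {name}")


def _token_sets(spec: SyntheticSpec, prefix: str) -> tuple[list[str], list[str], list[str]]:
    n_bg = spec.vocab_size - spec.n_signal_pos - spec.n_signal_neg
    background = [f"w{i:04d}" for i in range(n_bg)]
    pos_signal = [f"{prefix}pos{i:03d}" for i in range(spec.n_signal_pos)]
    neg_signal = [f"{prefix}neg{i:03d}" for i in range(spec.n_signal_neg)]
    return background, pos_signal, neg_signal


def _make_doc(
    rng: np.random.Generator,
    doc_id: str,
    label: int,
    spec: SyntheticSpec,
    background: list[str],
    own_signal: list[str],
    other_signal: list[str],
) -> Document:
    n_sent = int(rng.integers(spec.n_sent[0], spec.n_sent[1] + 1))
    sentences: list[str] = []
    for _ in range(n_sent):
        length = int(rng.integers(spec.sent_len[0], spec.sent_len[1] + 1))
        tokens = [background[i] for i in rng.integers(0, len(background), size=length)]
        if own_signal and rng.random() < spec.signal_rate:
            tokens[int(rng.integers(0, len(tokens)))] = own_signal[int(rng.integers(0, len(own_signal)))]
        if other_signal and rng.random() < spec.noise_rate:
            tokens[int(rng.integers(0, len(tokens)))] = other_signal[int(rng.integers(0, len(other_signal)))]
        if rng.random() < spec.dash_pair_rate:
            a = background[int(rng.integers(0, len(background)))]
            b = background[int(rng.integers(0, len(background)))]
            tokens.append(f"prot{a}–prot{b}")
        sentences.append(tokens[0].capitalize() + " " + " ".join(tokens[1:]) + ".")
    return Document(
        doc_id=doc_id,
        title=sentences[0].rstrip("."),
        abstract=" ".join(sentences[1:]) if len(sentences) > 1 else "",
        label=Label(label),
    )


def generate_corpus(spec: SyntheticSpec, name: str = "synthetic", id_prefix: str = "doc") -> LabeledCorpus:
    """Class-conditional token-mixture corpus, deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    background, pos_signal, neg_signal = _token_sets(spec, "t")
    docs = []
    for i in range(spec.n_docs):
        label = int(rng.random() < spec.positive_prior)
        own, other = (pos_signal, neg_signal) if label == 1 else (neg_signal, pos_signal)
        docs.append(_make_doc(rng, f"{id_prefix}{i:05d}", label, spec, background, own, other))
    return LabeledCorpus(name=name, documents=docs)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def generate_auxiliary_corpus(
    spec: SyntheticSpec, target_spec: SyntheticSpec, name: str = "auxiliary"
) -> LabeledCorpus:
    """Auxiliary corpus whose positive-signal vocabulary shares
    spec.shared_signal_fraction of the target's positive-signal tokens;
    auxiliary negatives never contain target-positive signal."""
    spec.validate()
    target_spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    background, _, _ = _token_sets(spec, "a")
    _, target_pos, _ = _token_sets(target_spec, "t")
    n_shared = _round_half_up(spec.shared_signal_fraction * len(target_pos))
    shared = target_pos[:n_shared]
    extra = [f"apos{i:03d}" for i in range(spec.n_signal_pos - min(spec.n_signal_pos, n_shared))]
    aux_pos = shared + extra
    if not aux_pos:
        raise ValueError("auxiliary positive-signal vocabulary is empty")
    aux_neg = [f"aneg{i:03d}" for i in range(spec.n_signal_neg)]
    docs = []
    for i in range(spec.n_docs):
        label = int(rng.random() < spec.positive_prior)
        own, other = (aux_pos, aux_neg) if label == 1 else (aux_neg, [])
        docs.append(_make_doc(rng, f"aux{i:05d}", label, spec, background, own, other))
    return LabeledCorpus(name=name, documents=docs)


def _dash_spans(tokens: list[str]) -> list[tuple[int, int, str]]:
    spans = []
    for i, tok in enumerate(tokens):
        if tok in set(DASH_CHARS) and 0 < i < len(tokens) - 1:
            spans.append((i - 1, i, "gene"))
            spans.append((i + 1, i + 2, "gene"))
    # drop duplicates from consecutive dashes
    seen: set[tuple[int, int]] = set()
    out = []
    for s in spans:
        if (s[0], s[1]) not in seen:
            seen.add((s[0], s[1]))
            out.append(s)
    return out


def generate_tags(corpus: LabeledCorpus, seed: int = 0) -> LabeledCorpus:
    """Attach synthetic POS tags and BIO NER tags to a preprocessed corpus.

    Signal tokens and dash-pair members get noun tags; punctuation gets
    PUNCT; the rest draw deterministically from a small closed tag set.
    Entity spans cover the members of dash-joined pairs.
    """
    rng = np.random.default_rng(seed)
    docs = []
    for doc in corpus:
        if doc.sentences is None:
            raise ValueError(f"document {doc.doc_id!r} is not preprocessed")
        pos_tags: list[list[str]] = []
        ner_tags: list[list[str]] = []
        for sent in doc.sentences:
            tags = []
            for tok in sent:
                if not tok[0].isalnum():
                    tags.append("PUNCT")
                elif tok[0] in "tap" and ("pos" in tok or "neg" in tok or tok.startswith("prot")):
                    tags.append("NN")
                else:
                    tags.append(_POS_TAGS[int(rng.integers(0, len(_POS_TAGS)))])
            pos_tags.append(tags)
            ner_tags.append(encode_bio(sent, _dash_spans(sent)))
        out = doc.copy()
        out.pos_tags = pos_tags
        out.ner_tags = ner_tags
        docs.append(out)
    return LabeledCorpus(name=corpus.name, documents=docs)


def write_toy_vectors(vocab: Vocabulary, dim: int, seed: int, path) -> None:
    """Standard-format vector file: one seeded random unit vector per
    vocabulary token, with a "count dim" header line."""
    rng = np.random.default_rng(seed)
    lines = [f"{len(vocab)} {dim}"]
    for token in vocab.id_to_token:
        v = rng.normal(size=dim)
        v /= np.linalg.norm(v)
        lines.append(token + " " + " ".join(repr(float(x)) for x in v))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
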
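"""Sentence splitting, tokenization and lowercasing.

Tokenization deliberately breaks tokens at every dash character so that
dash-joined entity pairs such as ``Utp6–Utp21`` become three tokens
(``utp6``, ``–``, ``utp21``): the pair members are what downstream
models need to see.  All other punctuation also becomes its own token;
nothing is filtered.
"""

from __future__ import annotations

import re

from .corpus_io import Document

__all__ = ["DASH_CHARS", "split_sentences", "tokenize", "preprocess_document"]

#: hyphen-minus, en dash, em dash
DASH_CHARS = "-–—"

# Abbreviations that do not end a sentence even when followed by an
# uppercase letter.  Single capital letters ("E. coli") are guarded
# separately.
_ABBREVIATIONS = frozenset(
    {
        "e.g", "i.e", "al", "fig", "figs", "eq", "eqs", "ref", "refs",
        "dr", "mr", "mrs", "ms", "prof", "vs", "cf", "ca", "approx",
        "no", "st", "etc", "spp", "subsp",
    }
)

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)
_BOUNDARY_RE = re.compile(r"[.?!]+(?=(\s+)[A-Z])")
_LAST_WORD_RE = re.compile(r"(\S+)$")


def _is_abbreviation(prefix: str) -> bool:
    """True when the text ending at a period should not break a sentence."""
    m = _LAST_WORD_RE.search(prefix)
    if m is None:
        return False
    word = m.group(1).rstrip(".")
    # Genus initials ("E. coli") need no entry here: the boundary rule
    # already requires an uppercase letter after the period.
    return word.lower() in _ABBREVIATIONS


def split_sentences(text: str) -> list[str]:
    """Split free text into sentences at terminal punctuation.

    A boundary is a run of ``.?!`` followed by whitespace and an
    uppercase letter, unless the preceding word is on the abbreviation
    guard list.  Concatenating the output (with single spaces) recovers
    the input modulo boundary whitespace.
    """
    if not text or not text.strip():
        return []
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        if _is_abbreviation(text[start : m.start()]):
            continue
        sentences.append(text[start:end].strip())
        start = end
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def tokenize(sentence: str) -> list[str]:
    """Lowercase tokens; every punctuation character (dashes included)
    is emitted as its own token."""
    return _TOKEN_RE.findall(sentence.lower())


def preprocess_document(doc: Document) -> Document:
    """Fill ``doc.sentences``: the whole title as one pseudo-sentence,
    then each abstract sentence.  Idempotent; returns a new Document."""
    if not doc.title.strip() and not doc.abstract.strip():
        raise ValueError(f"document {doc.doc_id!r} has neither title nor abstract")
    sentences: list[list[str]] = []
    title_tokens = tokenize(doc.title)
    if title_tokens:
        sentences.append(title_tokens)
    for sent in split_sentences(doc.abstract):
        tokens = tokenize(sent)
        if tokens:
            sentences.append(tokens)
    out = doc.copy()
    out.sentences = sentences
    return out
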
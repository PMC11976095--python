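"""Report text cleaning, sentence segmentation and tokenization.

The contract (rather than any particular NLP engine) is the interface:

* :func:`normalize_text` lowercases, folds unicode dashes/quotes to
  ASCII, strips control characters and collapses whitespace runs; it is
  idempotent and deterministic.
* :func:`segment` splits normalized text into sentences at terminal
  punctuation (``.``, ``;``, newline) with guards for common
  abbreviations (``e.g.``, ``no.``) and decimal numbers, and tokenizes
  each sentence on whitespace/punctuation while keeping intra-word
  hyphens and numerals.

Character offsets are 0-based half-open into the normalized text, so
``normalized_text[start:end] == sentence.text`` always holds.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

__all__ = ["Sentence", "Document", "normalize_text", "segment", "tokenize"]

_DASHES = dict.fromkeys(map(ord, "‐‑‒–—―−"), "-")
_QUOTES = dict.fromkeys(map(ord, "‘’‚‛"), "'")
_DQUOTES = dict.fromkeys(map(ord, "“”„‟"), '"')
_CHAR_MAP = {**_DASHES, **_QUOTES, **_DQUOTES}

# words after which a period is not a sentence boundary
_ABBREVIATIONS = frozenset(
    {"no", "nos", "e.g", "i.e", "vs", "cf", "fig", "figs", "dr", "approx", "et.al"}
)

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


@dataclass(frozen=True)
class Sentence:
    """One segmented sentence with tokens and its span in the document."""

    index: int
    text: str
    tokens: tuple[str, ...]
    char_span: tuple[int, int]

    @property
    def token_spans(self) -> tuple[tuple[int, int], ...]:
        """Token offsets within the sentence (recomputed, not stored)."""
        return tuple(m.span() for m in _TOKEN_RE.finditer(self.text))


@dataclass(frozen=True)
class Document:
    """A normalized report with its sentence segmentation."""

    report_id: str
    raw_text: str
    normalized_text: str
    sentences: tuple[Sentence, ...] = field(default_factory=tuple)


def normalize_text(raw: str) -> str:
    """Clean raw report text: lowercase, ASCII-fold punctuation, collapse
    whitespace, drop control characters. Empty input maps to empty output."""
    text = raw.translate(_CHAR_MAP)
    text = "".join(
        ch for ch in text if ch == "\n" or unicodedata.category(ch)[0] != "C"
    )
    text = text.lower()
    text = re.sub(r"\s+", " ", text).strip()
    return text


def tokenize(text: str) -> tuple[str, ...]:
    """Lowercase word/number tokens; intra-word hyphens are kept."""
    return tuple(_TOKEN_RE.findall(text))


def _is_boundary(text: str, i: int) -> bool:
    """Is the punctuation character at ``text[i]`` a sentence terminator?"""
    ch = text[i]
    if ch == "\n":
        return True
    if ch not in ".;":
        return False
    nxt = text[i + 1] if i + 1 < len(text) else " "
    if not (nxt == " " or nxt == "\n"):
        return False  # "3.5", "e.g" internal period, "x;y"
    if ch == ".":
        word = re.search(r"[\w.#-]*$", text[:i])
        prev = word.group(0).rstrip(".") if word else ""
        if prev in _ABBREVIATIONS:
            return False
    return True


def segment(normalized: str, report_id: str = "") -> Document:
    """Segment normalized text into sentences and tokens.

    The input is expected to be :func:`normalize_text` output; arbitrary
    text is still handled (segmentation simply sees its raw form).
    """
    sentences: list[Sentence] = []
    n = len(normalized)
    start = 0
    i = 0
    while i < n:
        if _is_boundary(normalized, i):
            end = i + 1 if normalized[i] in ".;" else i
            _append_sentence(sentences, normalized, start, end)
            start = i + 1
        i += 1
    _append_sentence(sentences, normalized, start, n)
    return Document(
        report_id=report_id,
        raw_text=normalized,
        normalized_text=normalized,
        sentences=tuple(sentences),
    )


def _append_sentence(
    sentences: list[Sentence], text: str, start: int, end: int
) -> None:
    # trim surrounding whitespace but keep the span anchored to the text
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    if start >= end:
        return
    chunk = text[start:end]
    tokens = tokenize(chunk)
    if not tokens:  # pure punctuation, e.g. a stray "..." — not a sentence
        return
    sentences.append(
        Sentence(
            index=len(sentences),
            text=chunk,
            tokens=tokens,
            char_span=(start, end),
        )
    )


def preprocess(raw: str, report_id: str = "") -> Document:
    """normalize_text + segment in one call, keeping the original raw text."""
    normalized = normalize_text(raw)
    doc = segment(normalized, report_id=report_id)
    return Document(
        report_id=report_id,
        raw_text=raw,
        normalized_text=normalized,
        sentences=doc.sentences,
    )
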
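"""Shared low-level text utilities: tokenization, bags of words, sentence spans.

Every downstream stage (mention post-processing, distillation, identifier
extraction, species co-occurrence, assignment indicators) operates on the same
sentence segmentation and word tokenization defined here, so the offsets they
exchange are always comparable.
"""

from __future__ import annotations

import re

__all__ = ["to_bag_of_words", "split_sentences", "sentence_of", "word_spans", "strip_xml"]

_WORD_RE = re.compile(r"[A-Za-z0-9]+")

# Tokens that commonly precede a non-terminal period: species genus
# abbreviations are handled separately (single letter + dot).
_ABBREVIATIONS = frozenset({
    "str", "substr", "subsp", "var", "pv", "bv", "cf", "sp", "spp",
    "fig", "figs", "e.g", "i.e", "et al", "al",
})

_BOUNDARY_RE = re.compile(r"[.?!]+(?=\s)")


def to_bag_of_words(text: str) -> list[str]:
    """Split ``text`` into lowercase words on every non-alphanumeric character.

    Empty fragments are dropped; original word order is preserved (the result
    is a list, not a set, so term frequencies remain countable).

    >>> to_bag_of_words("Hypoxia-inducible factor-1 alpha")
    ['hypoxia', 'inducible', 'factor', '1', 'alpha']
    """
    return [w.lower() for w in _WORD_RE.findall(text)]


def word_spans(text: str) -> list[tuple[int, int]]:
    """Return (start, end) offsets of every alphanumeric token in ``text``."""
    return [m.span() for m in _WORD_RE.finditer(text)]


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence segmentation returning half-open character spans.

    Splits after ``.``, ``?`` or ``!`` followed by whitespace, except when the
    period terminates a single-letter abbreviation ("E. coli", "S. cerevisiae")
    or a known non-terminal token such as "str." / "subsp." / "fig.".
    """
    if not text:
        return []
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        if m.group().startswith("."):
            # token immediately before the period
            head = text[start:m.start()]
            tok = re.split(r"\s+", head)[-1] if head.strip() else ""
            tok = tok.rstrip(".")
            bare = tok.lstrip("(\"'[")
            if len(bare) == 1 and bare.isalpha():
                continue  # "E." in "E. coli"
            if bare.lower() in _ABBREVIATIONS:
                continue
        spans.append((start, m.end()))
        # skip whitespace to the next sentence start
        nxt = m.end()
        while nxt < len(text) and text[nxt].isspace():
            nxt += 1
        start = nxt
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def sentence_of(offset: int, sentences: list[tuple[int, int]]) -> tuple[int, int]:
    """Return the sentence span containing character ``offset``.

    Falls back to the last sentence for trailing offsets (e.g. final newline).
    """
    for s, e in sentences:
        if s <= offset < e:
            return (s, e)
    return sentences[-1] if sentences else (0, 0)


_TAG_RE = re.compile(r"<[^<>]+>")


def strip_xml(raw: str) -> str:
    """Strip XML/NXML markup, returning plain text with tags removed.

    Uses lxml when the document parses; falls back to a regex sweep for
    fragments that are not well-formed.
    """
    try:
        from lxml import etree

        root = etree.fromstring(raw.encode("utf-8"))
        return " ".join(t.strip() for t in root.itertext() if t.strip())
    except Exception:
        return _TAG_RE.sub(" ", raw)
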
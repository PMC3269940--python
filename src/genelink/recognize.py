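"""Gene-mention recognition: tagger contract, post-processing, distillation.

A pluggable tagger produces raw spans; this module turns them into clean,
tokenized gene mentions. Post-processing rewrites each tagged string through a
fixed rule cascade (parenthetical isolation → conjunction splitting →
enumeration expansion → Roman/Greek number translation → head-word stripping),
then a distillation step drops mentions that sit inside family-name, figure,
antibody, or generic-biomedical contexts. A separate identifier-extraction
pass harvests database identifiers (locus tags, cross-references) that generic
taggers miss; those mentions arrive pre-normalized to a (gene_id, tax_id).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .lexicon import GeneIndex, normalize_symbol
from .textutils import split_sentences, to_bag_of_words

logger = logging.getLogger(__name__)

__all__ = [
    "RawTag", "GeneMention", "DictionaryTagger", "tag",
    "translate_number_type", "split_conjunctions", "expand_enumerations",
    "split_parentheses", "strip_headwords", "postprocess", "distill",
    "extract_identifiers",
]


@dataclass(frozen=True)
class RawTag:
    """A tagger output span: ``article_text[start:end] == text``."""
    text: str
    start: int
    end: int


@dataclass
class GeneMention:
    surface: str
    origin: RawTag
    bag: list[str] = field(default_factory=list)
    source: str = "tagger"            # "tagger" | "identifier"
    matched_gene: tuple[int, int] | None = None   # (gene_id, tax_id)

    def __post_init__(self):
        if not self.bag:
            self.bag = to_bag_of_words(self.surface)


# --------------------------------------------------------------------------
# taggers

class DictionaryTagger:
    """Longest-match dictionary tagger over the gene dictionary's entities.

    A deliberately simple built-in satisfying the tagger contract: it tags
    exact (case-sensitive) occurrences of any dictionary entity at word
    boundaries. Adapters around external statistical taggers plug in the same
    way — any callable ``text -> iterable of (text, start, end)`` works.
    """

    def __init__(self, index: GeneIndex, min_length: int = 2):
        entities = sorted(
            {e for rec in index.records.values() for e in rec.entities
             if len(e) >= min_length},
            key=lambda s: (-len(s), s),
        )
        if entities:
            body = "|".join(re.escape(e) for e in entities)
            self._pattern = re.compile(
                rf"(?<![A-Za-z0-9])(?:{body})(?![A-Za-z0-9])")
        else:
            self._pattern = None

    def __call__(self, article_text: str):
        if self._pattern is None:
            return []
        return [(m.group(), m.start(), m.end())
                for m in self._pattern.finditer(article_text)]


def tag(article_text: str, tagger) -> list[RawTag]:
    """Run ``tagger`` and return non-overlapping :class:`RawTag` spans.

    Overlaps are resolved by keeping the longer span (ties: the earlier one).
    """
    raw = [RawTag(str(t), int(s), int(e)) for t, s, e in tagger(article_text)]
    for r in raw:
        if article_text[r.start:r.end] != r.text:
            raise ValueError(f"tagger span mismatch at {r.start}:{r.end}")
    raw.sort(key=lambda r: (r.start, -(r.end - r.start)))
    out: list[RawTag] = []
    for r in raw:
        if out and r.start < out[-1].end:
            if (r.end - r.start) > (out[-1].end - out[-1].start):
                out[-1] = r
            continue
        out.append(r)
    return out


# --------------------------------------------------------------------------
# post-processing rules

_ROMAN = {
    "i": 1, "ii": 2, "iii": 3, "iv": 4, "v": 5, "vi": 6, "vii": 7, "viii": 8,
    "ix": 9, "x": 10, "xi": 11, "xii": 12, "xiii": 13, "xiv": 14, "xv": 15,
    "xvi": 16, "xvii": 17, "xviii": 18, "xix": 19, "xx": 20,
}

# first Latin letter of each Greek letter name
_GREEK = {g: g[0] for g in (
    "alpha beta gamma delta epsilon zeta eta theta iota kappa lambda mu nu "
    "xi omicron pi rho sigma tau upsilon phi chi psi omega".split()
)}

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def translate_number_type(text: str) -> str:
    """Unify number types: Roman numerals → Arabic, Greek letters → Latin.

    Only standalone tokens are rewritten; Roman numerals are recognized
    uppercase-only and up to XX so ordinary words ("MIX", "Vi") survive.
    """
    def repl(m: re.Match) -> str:
        tok = m.group()
        if tok.isupper() and tok.lower() in _ROMAN:
            return str(_ROMAN[tok.lower()])
        if tok.lower() in _GREEK:
            return _GREEK[tok.lower()]
        return tok

    return _TOKEN_RE.sub(repl, text)


_CONJ_RE = re.compile(r"\s+(?:and|or)\s+")


def split_conjunctions(text: str) -> list[str]:
    """Split a mention on token-bounded " and " / " or ".

    A mention that is a number enumeration ("SMADs 1, 5 and 8") is left intact
    for the enumeration rule: its "and" joins list numbers, not gene names.
    """
    if _ENUM_RE.match(text):
        return [text]
    parts = [p.strip() for p in _CONJ_RE.split(text)]
    return [p for p in parts if p]


_ENUM_RE = re.compile(
    r"^(?P<head>.*?[A-Za-z])s?\s*"
    r"(?P<nums>\d+(?:\s*(?:/|,|and)\s*\d+)+)\s*$"
)
_NUM_RE = re.compile(r"\d+")


def expand_enumerations(text: str) -> list[str]:
    """Expand a family-head + number-list mention into one mention per number.

    "Robo 1/2" → ["Robo 1", "Robo 2"]; a plural head is de-pluralized, so
    "SMADs 1, 5 and 8" → ["SMAD 1", "SMAD 5", "SMAD 8"]. Anything that is not
    a head followed by two or more list-separated numbers returns a singleton.
    """
    m = _ENUM_RE.match(text)
    if not m:
        return [text]
    head = m.group("head").strip()
    return [f"{head} {n}" for n in _NUM_RE.findall(m.group("nums"))]


_PAREN_RE = re.compile(r"\(([^()]*)\)")
_PUNCT_RE = re.compile(r"[^A-Za-z0-9]+")


def split_parentheses(text: str) -> list[str]:
    """Isolate parenthesized substrings as their own mentions.

    The remainder (parentheticals removed, punctuation normalized to spaces,
    whitespace collapsed) is returned first, followed by the parenthesized
    parts. Unbalanced parentheses are treated as absent.
    """
    if text.count("(") != text.count(")") or "(" not in text:
        return [text]
    parts = [p.strip() for p in _PAREN_RE.findall(text) if p.strip()]
    remainder = _PAREN_RE.sub(" ", text)
    remainder = _PUNCT_RE.sub(" ", remainder).strip()
    out = [remainder] if remainder else []
    out.extend(parts)
    return out if out else [text]


_HEADWORDS = frozenset({"protein", "proteins", "gene", "genes"})


def strip_headwords(text: str) -> str:
    """Remove leading/trailing "protein(s)" / "gene(s)" tokens."""
    tokens = text.split()
    while tokens and tokens[0].lower() in _HEADWORDS:
        tokens.pop(0)
    while tokens and tokens[-1].lower() in _HEADWORDS:
        tokens.pop()
    return " ".join(tokens)


def postprocess(text: str) -> list[str]:
    """Apply the full rewrite cascade to one tagged string.

    Order: parentheses → conjunctions → enumerations → number translation →
    head-word stripping. Parentheticals are isolated first so abbreviations
    never confuse the conjunction/enumeration logic; empty results are
    dropped. Idempotent on its own output.
    """
    surfaces: list[str] = []
    for para in split_parentheses(text):
        for conj in split_conjunctions(para):
            for enum in expand_enumerations(conj):
                s = strip_headwords(translate_number_type(enum)).strip()
                if s:
                    surfaces.append(s)
    return surfaces


def postprocess_tags(tags: list[RawTag]) -> list[GeneMention]:
    """Post-process every tag, keeping the originating span as provenance."""
    mentions: list[GeneMention] = []
    for t in tags:
        for surface in postprocess(t.text):
            mentions.append(GeneMention(surface=surface, origin=t))
    return mentions


# --------------------------------------------------------------------------
# distillation

# (filter-set name, pattern, index of the capture group holding the gene name)
DISTILLATION_FILTERS: tuple[tuple[str, re.Pattern, int], ...] = (
    ("family name",
     re.compile(r"([A-Za-z0-9]+)[^A-Za-z0-9](cell|family|subfamily|superfamily|domain|promotor)",
                re.IGNORECASE), 1),
    ("attachment",
     re.compile(r"(fig|figure|video|movie|tab|table)[^A-Za-z0-9]+([A-Za-z0-9]+)",
                re.IGNORECASE), 2),
    ("antibody name",
     re.compile(r"(anti)[^A-Za-z0-9]+([A-Za-z0-9]+)[^A-Za-z0-9]+(antibody|antibodies)",
                re.IGNORECASE), 2),
    ("biomedical words",
     re.compile(r"([A-Za-z0-9]+)[^A-Za-z0-9]+(binding peptide|pathway|domain|cell|function|isoforms)",
                re.IGNORECASE), 1),
)


def distill(mentions: list[GeneMention], article_text: str) -> list[GeneMention]:
    """Drop mentions whose span falls inside a filter pattern's name group.

    The four filters target family/figure/antibody/biomedical contexts in
    which a tagged token is not an actual gene mention ("anti-p53 antibody",
    "figure S4"). Removal is per occurrence; other occurrences of the same
    string elsewhere in the article are unaffected.
    """
    banned: list[tuple[int, int, str]] = []
    for name, pattern, group in DISTILLATION_FILTERS:
        for m in pattern.finditer(article_text):
            banned.append((m.start(group), m.end(group), name))
    out = []
    for mention in mentions:
        o = mention.origin
        hit = next((b for b in banned if b[0] <= o.start and o.end <= b[1]), None)
        if hit is None:
            out.append(mention)
        else:
            logger.info("distilled %r (filter set: %s)", mention.surface, hit[2])
    return out


# --------------------------------------------------------------------------
# identifier extraction

# tokens mixing digits and letters, plus the tail of the sentence for re-scan
_ID_PATTERNS = (
    re.compile(r"(\S*[0-9]+\S*[A-Za-z]+\S*)([^0-9A-Za-z]+.*)$"),
    re.compile(r"(\S*[A-Za-z]+\S*[0-9]+\S*)([^0-9A-Za-z]+.*)$"),
)


def extract_identifiers(article_text: str, index: GeneIndex) -> list[GeneMention]:
    """Harvest database-identifier mentions (locus tags, cross-references).

    Each sentence is scanned with the two mixed digit/letter token patterns;
    the second capture group (the sentence tail after the token) is re-scanned
    so several identifiers per sentence are found. Candidates are normalized
    with :func:`normalize_symbol` and looked up in ``index.by_ext_id``; exact
    hits become identifier-source mentions carrying their (gene_id, tax_id).
    """
    mentions: list[GeneMention] = []
    seen: set[tuple[int, int]] = set()
    for s_start, s_end in split_sentences(article_text):
        sentence = article_text[s_start:s_end]
        for pattern in _ID_PATTERNS:
            pos = 0
            while True:
                m = pattern.search(sentence, pos)
                if m is None:
                    break
                token = m.group(1)
                span = (s_start + m.start(1), s_start + m.end(1))
                hit = index.by_ext_id.get(normalize_symbol(token))
                if hit is not None and span not in seen:
                    seen.add(span)
                    origin = RawTag(token, span[0], span[1])
                    mentions.append(GeneMention(
                        surface=token, origin=origin,
                        source="identifier", matched_gene=hit))
                pos = m.start(2)
                if pos >= len(sentence):
                    break
    mentions.sort(key=lambda m: m.origin.start)
    return mentions
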
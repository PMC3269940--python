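"""Species mention extraction and resolution.

Species evidence in an article comes in four shapes: complete species names
(guaranteed — they pin a tax_id by themselves), genus words and bare cell-line
codes (unguaranteed — they need a guaranteed partner in the same article),
and strain-level sub-type designators (which uniquely identify one taxon and
can re-resolve an ambiguous species-family name in the same sentence). After
false-positive filtering and the two inference passes, the resolved mentions
are tallied into a per-article species frequency profile; the profile's argmax
is the majority species used as the assignment fallback.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .config import PipelineConfig
from .lexicon import SpeciesLexicon, _stripped_name_tokens
from .textutils import sentence_of, split_sentences, word_spans

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesMention", "SpeciesProfile", "match_species", "filter_species_fp",
    "guaranteed_inference", "cooccurrence_inference", "species_profile",
    "resolve_species",
]


@dataclass
class SpeciesMention:
    surface: str                     # matched text, lowercased
    start: int
    end: int
    mention_type: str                # general | genus | cell_line | sub_type
    candidates: set[int] = field(default_factory=set)
    tax_id: int | None = None
    guaranteed: bool = False
    genus: str | None = None         # genus word of the matched entry
    cell_code: str | None = None     # cell-line code for cell mentions

    @property
    def resolved(self) -> bool:
        return self.tax_id is not None


@dataclass
class SpeciesProfile:
    counts: dict[int, int] = field(default_factory=dict)
    per_name: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def majority(self) -> int | None:
        """Most frequent tax_id; ties broken toward the smaller id."""
        if not self.counts:
            return None
        return min(self.counts, key=lambda t: (-self.counts[t], t))


# --------------------------------------------------------------------------
# matching

def _matcher(lexicon: SpeciesLexicon) -> re.Pattern | None:
    keys: set[str] = set(lexicon.name_index)
    keys.update(lexicon.genus_index)
    keys.update(lexicon.subtype_index)
    for code in lexicon.cell_index:
        keys.update((code, f"{code} cell", f"{code} cells"))
    if not keys:
        return None
    body = "|".join(re.escape(k) for k in sorted(keys, key=lambda s: (-len(s), s)))
    return re.compile(rf"(?<![a-z0-9])(?:{body})(?![a-z0-9])")


def match_species(article_text: str, lexicon: SpeciesLexicon) -> list[SpeciesMention]:
    """Case-insensitive longest-match scan for species evidence.

    Complete species synonyms yield guaranteed general mentions (unless the
    name is family-ambiguous, i.e. a word-prefix of a strain-level entry — such
    mentions keep a provisional tax_id but stay unguaranteed so sub-type
    co-occurrence may re-resolve them). "<code> cell(s)" is a guaranteed
    cell-line mention; a bare code or a genus word is unguaranteed; a sub-type
    designator resolves to its unique taxon directly.
    """
    pattern = _matcher(lexicon)
    if pattern is None:
        return []
    lowered = article_text.lower()
    mentions: list[SpeciesMention] = []
    for m in pattern.finditer(lowered):
        surface = m.group()
        start, end = m.span()
        if surface in lexicon.name_index:
            tax = lexicon.name_index[surface]
            entry = lexicon.entries[tax]
            mentions.append(SpeciesMention(
                surface, start, end, "general", candidates={tax}, tax_id=tax,
                guaranteed=not entry.family_ambiguous, genus=entry.genus))
            continue
        stripped = re.sub(r"\s+cells?$", "", surface)
        if stripped != surface and stripped in lexicon.cell_index:
            tax = lexicon.cell_index[stripped]
            mentions.append(SpeciesMention(
                surface, start, end, "cell_line", candidates={tax}, tax_id=tax,
                guaranteed=True, cell_code=stripped))
        elif surface in lexicon.cell_index:
            mentions.append(SpeciesMention(
                surface, start, end, "cell_line",
                candidates={lexicon.cell_index[surface]}, cell_code=surface))
        elif surface in lexicon.genus_index:
            mentions.append(SpeciesMention(
                surface, start, end, "genus",
                candidates=set(lexicon.genus_index[surface]), genus=surface))
        elif surface in lexicon.subtype_index:
            tax = lexicon.subtype_index[surface]
            mentions.append(SpeciesMention(
                surface, start, end, "sub_type", candidates={tax}, tax_id=tax))
    return mentions


# --------------------------------------------------------------------------
# false-positive filtering

def filter_species_fp(
    mentions: list[SpeciesMention],
    article_text: str,
    config: PipelineConfig | None = None,
    sentences: list[tuple[int, int]] | None = None,
) -> list[SpeciesMention]:
    """Remove high-false-positive species mentions.

    Three filters: (1) surfaces on the high-FP list are dropped
    unconditionally; (2) a species word opening an experimental-technique
    phrase ("yeast two hybrid") is dropped when the article text at the
    mention actually spells the phrase; (3) a mention with an antibody-context
    token within a few tokens on either side (same sentence) is a reagent
    host and is dropped.
    """
    config = config or PipelineConfig()
    if sentences is None:
        sentences = split_sentences(article_text)
    lowered = article_text.lower()
    tokens = word_spans(article_text)
    antibody = {t.rstrip("-") for t in config.antibody_tokens}

    def antibody_context(m: SpeciesMention) -> bool:
        idx = [i for i, (s, e) in enumerate(tokens) if e > m.start and s < m.end]
        if not idx:
            return False
        sent = sentence_of(m.start, sentences)
        lo = max(0, idx[0] - config.antibody_window)
        hi = min(len(tokens), idx[-1] + 1 + config.antibody_window)
        for s, e in tokens[lo:idx[0]] + tokens[idx[-1] + 1:hi]:
            if not (sent[0] <= s < sent[1]):
                continue
            if lowered[s:e] in antibody:
                return True
        return False

    out: list[SpeciesMention] = []
    for m in mentions:
        if m.surface in config.high_fp:
            logger.info("species FP filtered: %r (high-FP list)", m.surface)
            continue
        window = lowered[m.start:m.start + 40].replace("-", " ")
        if any(t.startswith(m.surface + " ") and window.startswith(t)
               for t in config.experiment_terms):
            logger.info("species FP filtered: %r (experiment term)", m.surface)
            continue
        if antibody_context(m):
            logger.info("species FP filtered: %r (antibody context)", m.surface)
            continue
        out.append(m)
    return out


# --------------------------------------------------------------------------
# inference

def guaranteed_inference(mentions: list[SpeciesMention]) -> list[SpeciesMention]:
    """Resolve unguaranteed mentions via guaranteed partners in the article.

    A genus mention resolves to the taxon of a guaranteed complete species
    name sharing that genus; a bare cell-line code resolves to the taxon of a
    guaranteed "<code> cell(s)" mention. Two guaranteed partners implying
    different taxa leave the mention unresolved (logged). Unresolved
    unguaranteed mentions are excluded from the profile downstream.
    """
    genus_taxa: dict[str, set[int]] = {}
    cell_taxa: dict[str, set[int]] = {}
    for m in mentions:
        if m.guaranteed and m.tax_id is not None:
            if m.mention_type == "general" and m.genus:
                genus_taxa.setdefault(m.genus, set()).add(m.tax_id)
            elif m.mention_type == "cell_line" and m.cell_code:
                cell_taxa.setdefault(m.cell_code, set()).add(m.tax_id)

    for m in mentions:
        if m.resolved:
            continue
        partners: set[int] = set()
        if m.mention_type == "genus" and m.genus in genus_taxa:
            partners = genus_taxa[m.genus]
            if m.candidates:
                partners = partners & m.candidates or partners
        elif m.mention_type == "cell_line" and m.cell_code in cell_taxa:
            partners = cell_taxa[m.cell_code]
        if len(partners) == 1:
            m.tax_id = next(iter(partners))
        elif len(partners) > 1:
            logger.info("mention %r: conflicting guaranteed partners %s",
                        m.surface, sorted(partners))
    return mentions


def cooccurrence_inference(
    mentions: list[SpeciesMention],
    sentences: list[tuple[int, int]],
    lexicon: SpeciesLexicon,
) -> list[SpeciesMention]:
    """Resolve species/genus names through same-sentence sub-type designators.

    A sub-type mention (e.g. the substrain designator "mg1655") uniquely
    identifies one taxon. Any genus mention, or family-ambiguous species name
    whose designator-stripped scientific name prefixes the sub-type taxon's,
    occurring earlier in the same sentence is re-resolved to that taxon.
    Guaranteed mentions are never changed.
    """
    subtypes = [m for m in mentions if m.mention_type == "sub_type" and m.resolved]
    if not subtypes:
        return mentions
    for st in subtypes:
        st_entry = lexicon.entries.get(st.tax_id)
        if st_entry is None:
            continue
        st_tokens = _stripped_name_tokens(st_entry.scientific_name)
        sentence = next(((s, e) for s, e in sentences if s <= st.start < e), None)
        if sentence is None:
            continue
        for m in mentions:
            if m.guaranteed or m is st or not (sentence[0] <= m.start < st.start):
                continue
            if m.mention_type == "genus" and m.genus == st_entry.genus:
                m.tax_id = st.tax_id
            elif m.mention_type == "general" and m.tax_id is not None:
                own = _stripped_name_tokens(lexicon.entries[m.tax_id].scientific_name)
                if len(own) < len(st_tokens) and st_tokens[:len(own)] == own:
                    m.tax_id = st.tax_id
    return mentions


def species_profile(mentions: list[SpeciesMention]) -> SpeciesProfile:
    """Tally resolved mentions into the per-article species profile.

    Cell-line mentions are tallied under their code ("a549 cells" and "a549"
    both count as "a549"), everything else under its matched surface.
    """
    profile = SpeciesProfile()
    for m in mentions:
        if not m.resolved:
            continue
        profile.counts[m.tax_id] = profile.counts.get(m.tax_id, 0) + 1
        name = m.cell_code or m.surface
        profile.per_name[name] = profile.per_name.get(name, 0) + 1
    return profile


def resolve_species(
    article_text: str,
    lexicon: SpeciesLexicon,
    sentences: list[tuple[int, int]],
    config: PipelineConfig | None = None,
    infer: bool = True,
) -> tuple[list[SpeciesMention], SpeciesProfile]:
    """Convenience wrapper: match → FP-filter → inference → profile."""
    mentions = match_species(article_text, lexicon)
    mentions = filter_species_fp(mentions, article_text, config)
    if infer:
        mentions = guaranteed_inference(mentions)
        mentions = cooccurrence_inference(mentions, sentences, lexicon)
    return mentions, species_profile(mentions)
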
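"""Species assignment: give every gene mention a tax_id via a six-way cascade.

Indicators are tried in a fixed order and the first applicable one wins:

1. identifier — the mention came from identifier extraction and already
   carries its gene record's taxon;
2. prefix     — a single lowercase species letter prefixes an uppercase name
   ("hZIP 2" → human);
3. previous   — a resolved species mention immediately precedes the gene
   mention (at most one intervening token, no sentence break);
4. forward    — nearest resolved species mention before the gene in the same
   sentence;
5. backward   — nearest resolved species mention after the gene in the same
   sentence;
6. majority   — the article's most frequent species.

Mentions with no applicable indicator (empty profile, no context) are dropped
from normalization with a log line.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .config import PipelineConfig
from .recognize import GeneMention
from .species import SpeciesMention, SpeciesProfile
from .textutils import to_bag_of_words

logger = logging.getLogger(__name__)

__all__ = ["AssignedMention", "assign_species"]

INDICATORS = ("identifier", "prefix", "previous", "forward", "backward", "majority")

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")
_SENTENCE_BREAK_RE = re.compile(r"[.?!]\s")


@dataclass
class AssignedMention:
    mention: GeneMention
    tax_id: int
    indicator: str
    match_surface: str   # surface used for dictionary matching (prefix stripped)

    @property
    def match_bag(self) -> list[str]:
        return to_bag_of_words(self.match_surface)


def _same_sentence(offset_a: int, offset_b: int,
                   sentences: list[tuple[int, int]]) -> bool:
    for s, e in sentences:
        if s <= offset_a < e:
            return s <= offset_b < e
    return False


def assign_species(
    gene_mentions: list[GeneMention],
    species_mentions: list[SpeciesMention],
    profile: SpeciesProfile,
    sentences: list[tuple[int, int]],
    article_text: str,
    config: PipelineConfig | None = None,
) -> list[AssignedMention]:
    config = config or PipelineConfig()
    resolved = [m for m in species_mentions if m.resolved]
    resolved.sort(key=lambda m: m.start)
    assigned: list[AssignedMention] = []

    for g in gene_mentions:
        start, end = g.origin.start, g.origin.end
        tax: int | None = None
        indicator: str | None = None
        match_surface = g.surface

        if (config.enabled("indicator_identifier")
                and g.source == "identifier" and g.matched_gene is not None):
            tax, indicator = g.matched_gene[1], "identifier"

        if tax is None and config.enabled("indicator_prefix"):
            s = g.surface
            if (len(s) >= 2 and s[0].islower() and s[0] in config.prefix_map
                    and s[1].isupper()):
                tax, indicator = config.prefix_map[s[0]], "prefix"
                match_surface = s[1:]

        if tax is None and config.enabled("indicator_previous"):
            before = [m for m in resolved if m.end <= start]
            if before:
                nearest = max(before, key=lambda m: m.end)
                gap = article_text[nearest.end:start]
                if (len(_TOKEN_RE.findall(gap)) <= 1
                        and not _SENTENCE_BREAK_RE.search(gap)):
                    tax, indicator = nearest.tax_id, "previous"

        if tax is None and config.enabled("indicator_forward"):
            before = [m for m in resolved
                      if m.end <= start and _same_sentence(start, m.start, sentences)]
            if before:
                tax, indicator = max(before, key=lambda m: m.end).tax_id, "forward"

        if tax is None and config.enabled("indicator_backward"):
            after = [m for m in resolved
                     if m.start >= end and _same_sentence(start, m.start, sentences)]
            if after:
                tax, indicator = min(after, key=lambda m: m.start).tax_id, "backward"

        if tax is None and config.enabled("indicator_majority"):
            majority = profile.majority()
            if majority is not None:
                tax, indicator = majority, "majority"

        if tax is None:
            logger.info("gene mention %r left unassigned (no species evidence)",
                        g.surface)
            continue
        assigned.append(AssignedMention(g, tax, indicator, match_surface))
    return assigned
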
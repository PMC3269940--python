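"""Gene dictionary and species lexicon construction.

Two indexes are built here and consumed by the rest of the pipeline:

* :class:`GeneIndex` — an Entrez-style gene dictionary read from a
  ``gene_info`` TSV. Every gene record carries its name entities (symbol +
  synonyms), the union of their bags of words, and its normalized external
  identifiers (locus tags, cross-references). Document frequencies over gene
  records (``df_entity`` / ``df_word``) are pre-computed here because they are
  the IDF denominators of the candidate-ranking stage.

* :class:`SpeciesLexicon` — species and cell-line names compiled into matching
  patterns. Species names come from an NCBI-taxonomy-style names table
  restricted to the ranks species / no rank / subspecies / variants; genus
  words (first token of each multi-word scientific name) and strain-level
  sub-type designators are indexed separately because they resolve through
  inference rather than direct lookup. Multi-word names are extended with
  genus-initial abbreviations ("escherichia coli k-12" → "e. coli k-12"), and
  name collisions are resolved by rank priority.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import DEFAULT_PRIORITY_ORDER, DEFAULT_RANK_WHITELIST
from .textutils import to_bag_of_words

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_symbol", "extend_synonyms", "compile_species_pattern",
    "GeneRecord", "GeneIndex", "load_gene_info",
    "SpeciesEntry", "SpeciesLexicon", "build_species_lexicon",
]

_SYMBOL_STRIP_RE = re.compile(r"[\s\-\._]+")


def normalize_symbol(token: str) -> str:
    """Lowercase ``token`` and remove whitespace, hyphens, dots and underscores.

    The same normalization is applied to dictionary entries and to article
    tokens, so orthographic variants ("YCL057C-A" vs "YCL057CA", "TLR-7" vs
    "TLR7") collapse to one key. Idempotent.

    >>> normalize_symbol("YCL057C-A")
    'ycl057ca'
    """
    return _SYMBOL_STRIP_RE.sub("", token).lower()


def extend_synonyms(scientific_name: str) -> set[str]:
    """Generate genus-initial abbreviations of a species name.

    "escherichia coli k-12" yields itself plus "e.coli k-12" and
    "e. coli k-12" (genus replaced by its first letter, a dot, and optionally
    a space). Single-word names are returned unchanged.
    """
    name = scientific_name.strip().lower()
    if not name:
        raise ValueError("empty species name")
    parts = name.split()
    if len(parts) < 2:
        return {name}
    initial, rest = parts[0][0], " ".join(parts[1:])
    return {name, f"{initial}.{rest}", f"{initial}. {rest}"}


# --------------------------------------------------------------------------
# gene dictionary

@dataclass
class GeneRecord:
    gene_id: int
    tax_id: int
    entities: set[str]            # raw name strings (symbol + synonyms)
    words: set[str]               # union of bags of words of entities
    ext_ids: set[str]             # normalized locus tags / cross-references


@dataclass
class GeneIndex:
    records: dict[int, GeneRecord] = field(default_factory=dict)
    by_tax_entity: dict[tuple[int, str], set[int]] = field(default_factory=dict)
    by_tax_word: dict[tuple[int, str], set[int]] = field(default_factory=dict)
    by_ext_id: dict[str, tuple[int, int]] = field(default_factory=dict)
    df_entity: dict[str, int] = field(default_factory=dict)
    df_word: dict[str, int] = field(default_factory=dict)
    genes_per_tax: dict[int, int] = field(default_factory=dict)

    @property
    def n_ids(self) -> int:
        """Total number of gene records (the IDF corpus size)."""
        return len(self.records)

    def add(self, rec: GeneRecord) -> None:
        if rec.gene_id in self.records:
            raise ValueError(f"duplicate gene_id {rec.gene_id}")
        self.records[rec.gene_id] = rec
        self.genes_per_tax[rec.tax_id] = self.genes_per_tax.get(rec.tax_id, 0) + 1
        norm_entities = {normalize_symbol(e) for e in rec.entities}
        norm_entities.discard("")
        for e in norm_entities:
            self.by_tax_entity.setdefault((rec.tax_id, e), set()).add(rec.gene_id)
            self.df_entity[e] = self.df_entity.get(e, 0) + 1
        for w in rec.words:
            self.by_tax_word.setdefault((rec.tax_id, w), set()).add(rec.gene_id)
            self.df_word[w] = self.df_word.get(w, 0) + 1
        for ext in rec.ext_ids:
            if ext and ext not in self.by_ext_id:
                self.by_ext_id[ext] = (rec.gene_id, rec.tax_id)
            elif ext:
                logger.warning("external id %r already mapped; keeping first", ext)


_GENE_INFO_COLUMNS = ("tax_id", "GeneID", "Symbol", "LocusTag", "Synonyms", "dbXrefs")


def _split_field(value: str) -> list[str]:
    if value in ("-", "", None) or pd.isna(value):
        return []
    return [v for v in str(value).split("|") if v and v != "-"]


def load_gene_info(path: str | Path) -> GeneIndex:
    """Read a ``gene_info``-style TSV into a :class:`GeneIndex`.

    Expected columns (header row, extra columns ignored): tax_id, GeneID,
    Symbol, LocusTag, Synonyms (pipe-separated), dbXrefs (pipe-separated
    ``db:id`` pairs). "-" denotes a missing value. External identifiers are
    the locus tag plus the part of each dbXref after its last colon, all
    passed through :func:`normalize_symbol`. Malformed rows are skipped with
    a warning; a duplicate GeneID is an error.
    """
    index = GeneIndex()
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame.columns = [c.lstrip("#") for c in frame.columns]
    missing = [c for c in _GENE_INFO_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"gene_info file lacks columns: {missing}")
    for row in frame.itertuples(index=False):
        try:
            gene_id = int(getattr(row, "GeneID"))
            tax_id = int(getattr(row, "tax_id"))
        except (TypeError, ValueError):
            logger.warning("skipping malformed gene_info row: %r", row)
            continue
        entities = set()
        symbol = getattr(row, "Symbol")
        if symbol and symbol != "-":
            entities.add(symbol)
        entities.update(_split_field(getattr(row, "Synonyms")))
        words = set()
        for e in entities:
            words.update(to_bag_of_words(e))
        ext_ids = set()
        locus = getattr(row, "LocusTag")
        if locus and locus != "-":
            ext_ids.add(normalize_symbol(locus))
        for xref in _split_field(getattr(row, "dbXrefs")):
            ident = xref.rsplit(":", 1)[-1]
            if ident:
                ext_ids.add(normalize_symbol(ident))
        ext_ids.discard("")
        index.add(GeneRecord(gene_id, tax_id, entities, words, ext_ids))
    return index


# --------------------------------------------------------------------------
# species lexicon

#: rank string in the names table → internal rank_type
_RANK_TYPE = {
    "species": "species",
    "no rank": "no-rank",
    "subspecies": "subspecies",
    "variants": "variant",
    "varietas": "variant",
}

#: designator markers introducing strain-level sub-type tokens
_SUBTYPE_MARKERS = frozenset({
    "str.", "substr.", "subsp.", "var.", "pv.", "bv.", "strain", "substrain",
})


@dataclass
class SpeciesEntry:
    tax_id: int
    scientific_name: str
    synonyms: set[str]
    rank_type: str
    genus: str
    sub_types: set[str] = field(default_factory=set)
    priority: int = 0
    family_ambiguous: bool = False   # name is a word-prefix of a strain-level entry
    pattern: re.Pattern | None = None


def compile_species_pattern(entry: SpeciesEntry) -> str:
    """Compile an entry's synonym set into one alternation pattern.

    The returned pattern fullmatch-es a string (case-insensitively) iff the
    string equals one of the entry's synonyms; regex metacharacters are
    escaped. Alternatives are ordered longest-first so the pattern is also
    safe in longest-match scanning contexts.
    """
    if not entry.synonyms:
        raise ValueError(f"entry {entry.tax_id} has no synonyms")
    alts = sorted(entry.synonyms, key=lambda s: (-len(s), s))
    return "(?:" + "|".join(re.escape(a) for a in alts) + ")"


def _stripped_name_tokens(name: str) -> tuple[str, ...]:
    """Scientific name tokens with designator markers removed.

    "escherichia coli str. k-12 substr. mg1655" → (escherichia, coli, k-12,
    mg1655). Used both for family-ambiguity detection and sub-type harvesting.
    """
    return tuple(t for t in name.lower().split() if t not in _SUBTYPE_MARKERS)


@dataclass
class SpeciesLexicon:
    entries: dict[int, SpeciesEntry] = field(default_factory=dict)
    name_index: dict[str, int] = field(default_factory=dict)
    genus_index: dict[str, set[int]] = field(default_factory=dict)
    subtype_index: dict[str, int] = field(default_factory=dict)
    cell_index: dict[str, int] = field(default_factory=dict)


def build_species_lexicon(
    names: str | Path | pd.DataFrame,
    cell_lines: str | Path | pd.DataFrame | None,
    gene_index: GeneIndex,
    rank_whitelist: tuple[str, ...] = DEFAULT_RANK_WHITELIST,
    priority_order: tuple[str, ...] = DEFAULT_PRIORITY_ORDER,
) -> SpeciesLexicon:
    """Aggregate taxonomy names and cell-line names into a species lexicon.

    The names table needs columns tax_id, name_txt, name_class, rank (one row
    per name; the row whose name_class is "scientific name" — or failing that
    the first row — defines the entry's scientific name). Processing:

    1. keep only whitelisted ranks; unknown ranks are excluded with a log line;
    2. drop every tax_id with zero genes in ``gene_index``;
    3. lowercase everything and extend every multi-word name with its
       genus-initial abbreviations;
    4. resolve name collisions by rank priority (losing synonym deleted), ties
       by smaller tax_id;
    5. index genus words of multi-word scientific names and the final-token
       sub-type designators of strain-level names (ambiguous designators are
       dropped with a warning);
    6. index cell-line names (columns name, tax_id).
    """
    if not isinstance(names, pd.DataFrame):
        names = pd.read_csv(names, sep="\t", dtype=str, keep_default_na=False)
    rank_to_priority = {r: i for i, r in enumerate(priority_order)}

    lex = SpeciesLexicon()
    for tax_str, group in names.groupby("tax_id", sort=True):
        rank = str(group["rank"].iloc[0]).strip().lower()
        if rank not in rank_whitelist:
            if rank not in _RANK_TYPE and rank != "genus":
                logger.info("tax %s: unknown rank %r excluded", tax_str, rank)
            continue
        tax_id = int(tax_str)
        if gene_index.genes_per_tax.get(tax_id, 0) == 0:
            continue  # species without any gene cannot be a normalization target
        sci_rows = group[group["name_class"].str.lower() == "scientific name"]
        scientific = (sci_rows["name_txt"].iloc[0] if len(sci_rows)
                      else group["name_txt"].iloc[0]).strip().lower()
        synonyms: set[str] = set()
        for raw in group["name_txt"]:
            name = str(raw).strip().lower()
            if not name:
                continue
            if len(name.split()) >= 2:
                synonyms.update(extend_synonyms(name))
            else:
                synonyms.add(name)
        synonyms.add(scientific)
        rank_type = _RANK_TYPE[rank]
        entry = SpeciesEntry(
            tax_id=tax_id,
            scientific_name=scientific,
            synonyms=synonyms,
            rank_type=rank_type,
            genus=scientific.split()[0],
            priority=rank_to_priority[rank_type],
        )
        lex.entries[tax_id] = entry

    # name collisions: higher priority (lower number) wins, ties → lower tax_id
    for tax_id, entry in sorted(lex.entries.items(),
                                key=lambda kv: (kv[1].priority, kv[0])):
        for syn in sorted(entry.synonyms):
            if syn in lex.name_index:
                logger.info("species name collision %r: tax %d loses to tax %d",
                            syn, tax_id, lex.name_index[syn])
                entry.synonyms.discard(syn)
            else:
                lex.name_index[syn] = tax_id
    # a collision may empty an entry; such a taxon is unmatched but retained
    # in ``entries`` for inference bookkeeping only if it still has names
    for tax_id in [t for t, e in lex.entries.items() if not e.synonyms]:
        del lex.entries[tax_id]

    # genus index and family ambiguity
    stripped = {t: _stripped_name_tokens(e.scientific_name)
                for t, e in lex.entries.items()}
    for tax_id, entry in lex.entries.items():
        if len(entry.scientific_name.split()) >= 2:
            lex.genus_index.setdefault(entry.genus, set()).add(tax_id)
        mine = stripped[tax_id]
        entry.family_ambiguous = any(
            other != tax_id and len(toks) > len(mine) and toks[: len(mine)] == mine
            for other, toks in stripped.items()
        )

    # sub-type designators: final token of strain-level scientific names
    seen_subtypes: dict[str, int] = {}
    ambiguous: set[str] = set()
    for tax_id, entry in sorted(lex.entries.items()):
        tokens = entry.scientific_name.split()
        if not any(t in _SUBTYPE_MARKERS for t in tokens):
            continue
        designator = _stripped_name_tokens(entry.scientific_name)[-1]
        if designator in seen_subtypes and seen_subtypes[designator] != tax_id:
            logger.warning("ambiguous sub-type designator %r dropped", designator)
            ambiguous.add(designator)
        else:
            seen_subtypes[designator] = tax_id
        entry.sub_types.add(designator)
    lex.subtype_index = {d: t for d, t in seen_subtypes.items() if d not in ambiguous}

    # cell lines
    if cell_lines is not None:
        if not isinstance(cell_lines, pd.DataFrame):
            cell_lines = pd.read_csv(cell_lines, sep="\t", dtype=str,
                                     keep_default_na=False)
        for row in cell_lines.itertuples(index=False):
            tax_id = int(getattr(row, "tax_id"))
            if gene_index.genes_per_tax.get(tax_id, 0) == 0:
                continue
            lex.cell_index[str(getattr(row, "name")).strip().lower()] = tax_id

    for entry in lex.entries.values():
        entry.pattern = re.compile(compile_species_pattern(entry), re.IGNORECASE)
    return lex
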
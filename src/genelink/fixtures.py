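"""Synthetic corpus generation with known ground truth.

The generator fabricates all four pipeline inputs — a gene dictionary, a
taxonomy names table, a cell-line table, and plain-text articles with gold
annotations — by applying the INVERSE of the normalization rules: a gene that
the dictionary knows as "SMAD 1", "SMAD 5", "SMAD 8" is rendered in the text
as "SMADs 1, 5 and 8", a Greek-lettered synonym is rendered with the spelled
Greek word, a strain is cued by its substrain designator, and so on. Every
planted mention is recorded in a plant log (offsets, rendered surface, gold
gene ids, expected taxon), so pipeline recovery is checkable mention by
mention. Regeneration with the same seed is byte-identical.

The universe is deliberately small (a few dozen genes across a dozen taxa)
but adversarial where it matters: cross-species orthologs sharing a name,
family members sharing words, cell-line codes, an E. coli strain family, and
decoy sentences (antibody contexts, figure labels, technique phrases) that a
correct pipeline must discard.
"""

from __future__ import annotations

import io
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .lexicon import GeneIndex, SpeciesLexicon, build_species_lexicon, load_gene_info

__all__ = ["FixtureConfig", "FixtureCorpus", "PlantRecord", "make_fixture_corpus",
           "PlantLogTagger", "profile_standin_article"]


# --------------------------------------------------------------------------
# the universe

# tax_id, GeneID, Symbol, LocusTag, Synonyms, dbXrefs
GENE_ROWS: tuple[tuple[int, int, str, str, str, str], ...] = (
    (9606, 7157, "TP53", "-", "tumor protein p53", "MIM:191170"),
    (9606, 51554, "ACKR4", "-", "CCRL1|CKRX|chemokine receptor like 1", "HGNC:HGNC:1611"),
    (9606, 4086, "SMAD1", "-", "SMAD family member 1", "-"),
    (9606, 4087, "SMAD2", "-", "SMAD family member 2", "-"),
    (9606, 4088, "SMAD3", "-", "SMAD family member 3", "-"),
    (9606, 4089, "SMAD4", "-", "SMAD family member 4", "-"),
    (9606, 4090, "SMAD5", "-", "SMAD family member 5", "-"),
    (9606, 4093, "SMAD8", "-", "SMAD family member 8|SMAD9", "-"),
    (9606, 51284, "TLR7", "-", "toll like receptor 7", "-"),
    (9606, 51311, "TLR8", "-", "toll like receptor 8", "-"),
    (9606, 11337, "GABARAP", "-", "GABA type A receptor associated protein", "-"),
    (9606, 5045, "FURIN", "-", "proprotein convertase|PCSK3", "-"),
    (9606, 2247, "FGF2", "-", "fibroblast growth factor 2|FGF-2", "-"),
    (9606, 29986, "ZIP2", "-", "ZIP 2|zinc transporter ZIP2", "-"),
    (9606, 5578, "PRKCA", "-", "PKC a|PKCA", "-"),
    (9606, 2158, "F9", "-", "factor 9|coagulation factor 9", "-"),
    (9606, 84676, "TRIM54", "-", "MURF 3|MURF3", "-"),
    (9606, 81631, "MAP1LC3B", "-", "light chain 3|LC3B", "-"),
    (10090, 22059, "Trp53", "-", "TP53|p53", "MGI:MGI:98834"),
    (10090, 170743, "Tlr7", "-", "TLR7", "-"),
    (10090, 17125, "Smad1", "-", "SMAD1", "-"),
    (10090, 16590, "Kit", "-", "-", "-"),
    (10116, 24842, "Ins1", "-", "-", "-"),
    (4932, 855978, "CAT8", "YOR019W", "-", "SGD:S000005545"),
    (4932, 850557, "PBN1", "YCL057C-A", "-", "SGD:S000000563"),
    (4932, 852846, "MIG1", "YGL035C", "-", "SGD:S000003003"),
    (4932, 856035, "RAD53", "YPL153C", "-", "-"),
    (7955, 30746, "ltk", "-", "leukocyte tyrosine kinase|Ltk", "-"),
    (7955, 58065, "robo1", "-", "Robo 1", "-"),
    (7955, 58066, "robo2", "-", "Robo 2", "-"),
    (7227, 32708, "Iswi", "-", "ISWI", "FLYBASE:FBgn0011604"),
    (7227, 38973, "Hcf", "-", "HCF", "-"),
    (8355, 397784, "tbxt", "-", "brachyury", "-"),
    (3702, 838982, "LFY", "-", "LEAFY", "-"),
    (562, 900100, "blaT", "-", "-", "-"),
    (83333, 944742, "thrL", "b0001", "-", "-"),
    (511145, 945803, "lacZ", "b0344", "beta-galactosidase", "-"),
    (511145, 947170, "recA", "b2699", "-", "-"),
    (9913, 281717, "PRNP", "-", "-", "-"),
    (9986, 100008633, "HBB1", "-", "-", "-"),
    (9925, 100861259, "CSN2", "-", "-", "-"),
    (9685, 493804, "FECH", "-", "-", "-"),
    (9793, 106842071, "LCN1", "-", "-", "-"),
    (10760, 1261050, "gp10", "-", "-", "-"),
    (11191, 1489818, "HN", "-", "-", "-"),
)

# tax_id, name_txt, name_class, rank
TAXONOMY_ROWS: tuple[tuple[int, str, str, str], ...] = (
    (9606, "Homo sapiens", "scientific name", "species"),
    (9606, "human", "genbank common name", "species"),
    (10090, "Mus musculus", "scientific name", "species"),
    (10090, "mouse", "genbank common name", "species"),
    (10090, "mice", "common name", "species"),
    (10090, "murine", "common name", "species"),
    (10116, "Rattus norvegicus", "scientific name", "species"),
    (10116, "rat", "genbank common name", "species"),
    (4932, "Saccharomyces cerevisiae", "scientific name", "species"),
    (4932, "yeast", "common name", "species"),
    (7227, "Drosophila melanogaster", "scientific name", "species"),
    (7227, "fruit fly", "genbank common name", "species"),
    (7955, "Danio rerio", "scientific name", "species"),
    (7955, "zebrafish", "genbank common name", "species"),
    (8355, "Xenopus laevis", "scientific name", "species"),
    (8355, "african clawed frog", "genbank common name", "species"),
    (3702, "Arabidopsis thaliana", "scientific name", "species"),
    (3702, "thale cress", "genbank common name", "species"),
    (562, "Escherichia coli", "scientific name", "species"),
    (83333, "Escherichia coli K-12", "scientific name", "no rank"),
    (83333, "Escherichia coli K12", "synonym", "no rank"),
    (511145, "Escherichia coli str. K-12 substr. MG1655", "scientific name", "no rank"),
    (9913, "Bos taurus", "scientific name", "species"),
    (9913, "bovine", "common name", "species"),
    (9986, "Oryctolagus cuniculus", "scientific name", "species"),
    (9986, "rabbit", "common name", "species"),
    (9925, "Capra hircus", "scientific name", "species"),
    (9925, "goat", "genbank common name", "species"),
    (9685, "Felis catus", "scientific name", "species"),
    (9685, "cat", "genbank common name", "species"),
    (9793, "Equus asinus", "scientific name", "species"),
    (9793, "ass", "common name", "species"),
    (10760, "Enterobacteria phage T7", "scientific name", "species"),
    (10760, "T7", "synonym", "species"),
    (11191, "Sendai virus", "scientific name", "species"),
    (99999, "Plantus imaginarius", "scientific name", "species"),   # gene-less
    (99988, "Bacteria", "scientific name", "genus"),                # excluded rank
)

CELL_LINE_ROWS: tuple[tuple[str, int], ...] = (
    ("a549", 9606),
    ("293", 9606),
    ("hela", 9606),
    ("3t3", 10090),
)

#: species cue surface per taxon (all guaranteed full names in the lexicon)
CUES: dict[int, str] = {
    9606: "human", 10090: "mouse", 10116: "rat", 4932: "yeast",
    7227: "Drosophila melanogaster", 7955: "zebrafish",
    8355: "Xenopus laevis", 3702: "Arabidopsis thaliana",
}

#: cross-species ambiguous names → gene id per taxon
AMBIGUOUS_ORTHOLOGS: dict[str, dict[int, int]] = {
    "TP53": {9606: 7157, 10090: 22059},
    "TLR7": {9606: 51284, 10090: 170743},
}

EXACT_POOL: tuple[tuple[int, str, int], ...] = (
    (9606, "GABARAP", 11337),
    (9606, "FURIN", 5045),
    (9606, "TLR8", 51311),
    (10090, "Kit", 16590),
    (10116, "Ins1", 24842),
    (4932, "MIG1", 852846),
    (7955, "ltk", 30746),
    (7227, "ISWI", 32708),
    (3702, "LFY", 838982),
    (8355, "brachyury", 397784),
)


# --------------------------------------------------------------------------
# plants

@dataclass
class PlantRecord:
    doc_id: str
    kind: str
    surface: str
    start: int
    end: int
    gold: tuple[int, ...]          # expected gene ids (empty for decoys)
    tax_id: int | None
    taggable: bool                 # True → the stand-in tagger emits this span
    cue: str | None = None         # cue style for ambiguous plants

    def as_dict(self) -> dict:
        return {
            "doc_id": self.doc_id, "kind": self.kind, "surface": self.surface,
            "start": self.start, "end": self.end, "gold": list(self.gold),
            "tax_id": self.tax_id, "taggable": self.taggable, "cue": self.cue,
        }


@dataclass
class _Sentence:
    """One generated sentence block with plant spans relative to its text."""
    text: str
    plants: list[tuple[int, int, str, tuple[int, ...], int | None, bool, str, str | None]] = \
        field(default_factory=list)


def _plant(text: str, surface: str, gold: tuple[int, ...], tax: int | None,
           kind: str, taggable: bool = True, cue: str | None = None) -> _Sentence:
    start = text.index(surface)
    return _Sentence(text, [(start, start + len(surface), surface, gold, tax,
                             taggable, kind, cue)])


def _exact(rng: random.Random) -> _Sentence:
    tax, name, gid = rng.choice(EXACT_POOL)
    return _plant(f"In {CUES[tax]} samples, {name} was strongly expressed.",
                  name, (gid,), tax, "exact")


def _enum_slash(rng: random.Random) -> _Sentence:
    return _plant("In zebrafish embryos, Robo 1/2 were analyzed.",
                  "Robo 1/2", (58065, 58066), 7955, "enumeration")


def _enum_list(rng: random.Random) -> _Sentence:
    return _plant("In human samples, SMADs 1, 5 and 8 were phosphorylated.",
                  "SMADs 1, 5 and 8", (4086, 4090, 4093), 9606, "enumeration")


def _conjunction(rng: random.Random) -> _Sentence:
    return _plant("In human samples, GABARAP and light chain 3 were detected.",
                  "GABARAP and light chain 3", (11337, 81631), 9606, "conjunction")


def _greek(rng: random.Random) -> _Sentence:
    return _plant("In human samples, PKC alpha was activated.",
                  "PKC alpha", (5578,), 9606, "greek")


def _roman(rng: random.Random) -> _Sentence:
    return _plant("In human samples, factor IX was depleted.",
                  "factor IX", (2158,), 9606, "roman")


def _parentheses(rng: random.Random) -> _Sentence:
    return _plant(
        "In human samples, fibroblast growth factor 2 (FGF2) was induced.",
        "fibroblast growth factor 2 (FGF2)", (2247,), 9606, "parentheses")


def _headword(rng: random.Random) -> _Sentence:
    return _plant("In human samples, MURF 3 protein was degraded.",
                  "MURF 3 protein", (84676,), 9606, "headword")


def _identifier(rng: random.Random) -> _Sentence:
    return _plant("Expression of YOR019W increased twofold.",
                  "YOR019W", (855978,), 4932, "identifier", taggable=False)


def _prefix(rng: random.Random) -> _Sentence:
    return _plant("Overexpression of hZIP 2 altered zinc uptake.",
                  "hZIP 2", (29986,), 9606, "prefix")


def _cell_line(rng: random.Random) -> _Sentence:
    return _plant(
        "A549 cells were cultured overnight. A549 lysates showed elevated "
        "FURIN levels.", "FURIN", (5045,), 9606, "cell_line")


def _subtype(rng: random.Random) -> _Sentence:
    return _plant(
        "Cultures of E. coli K12 (MG1655) overexpressed lacZ after induction.",
        "lacZ", (945803,), 511145, "subtype")


VARIATION_BUILDERS = (
    _exact, _enum_slash, _enum_list, _conjunction, _greek, _roman,
    _parentheses, _headword, _identifier, _prefix, _cell_line, _subtype,
)

_AMBIG_TEMPLATES = {
    "forward": "In {cue} samples, {name} expression doubled.",
    "backward": "{name} expression doubled in {cue} samples.",
    "previous": "Treated {cue} {name} lysates were analyzed.",
    "majority": "{name} expression doubled after treatment.",
}


def _ambiguous(rng: random.Random, cue_type: str, tax: int) -> _Sentence:
    name = rng.choice(sorted(AMBIGUOUS_ORTHOLOGS))
    gid = AMBIGUOUS_ORTHOLOGS[name][tax]
    text = _AMBIG_TEMPLATES[cue_type].format(cue=CUES[tax], name=name)
    s = _plant(text, name, (gid,), tax, "ambiguous")
    s.plants[0] = s.plants[0][:7] + (cue_type,)
    return s


def _decoys(rng: random.Random) -> list[_Sentence]:
    pool = [
        _plant("Blots were probed with anti-TP53 antibody overnight.",
               "TP53", (), None, "decoy_antibody"),
        _plant("Members of the SMAD4 family were compared.",
               "SMAD4", (), None, "decoy_family"),
        _plant("The construct map is provided in figure S4.",
               "S4", (), None, "decoy_figure"),
        _Sentence("Membranes were incubated with goat anti-FLAG monoclonal "
                  "antibody."),
        _Sentence("Binding was confirmed by yeast two hybrid assays."),
        _Sentence("Constructs were cloned downstream of the t7 promoter."),
    ]
    return rng.sample(pool, rng.randint(1, 2))


# --------------------------------------------------------------------------
# corpus

@dataclass
class FixtureConfig:
    variations: bool = True     # mention-variation plants (inverse rules)
    ambiguous: bool = True      # one cross-species ambiguous plant per doc
    decoys: bool = True         # FP decoy sentences at the end of each doc
    exact_min: int = 2          # exact plants per doc (when variations off: min..max)
    exact_max: int = 4


@dataclass
class FixtureCorpus:
    seed: int
    articles: dict[str, str]
    plants: list[PlantRecord]
    gene_info_tsv: str
    taxonomy_tsv: str
    cell_lines_tsv: str

    @property
    def gold(self) -> dict[str, set[int]]:
        gold: dict[str, set[int]] = {d: set() for d in self.articles}
        for p in self.plants:
            gold[p.doc_id].update(p.gold)
        return gold

    def gold_tsv(self) -> str:
        lines = ["doc_id\tgene_id"]
        for doc in sorted(self.gold):
            for gid in sorted(self.gold[doc]):
                lines.append(f"{doc}\t{gid}")
        return "\n".join(lines) + "\n"

    def gene_index(self) -> GeneIndex:
        return load_gene_info(io.StringIO(self.gene_info_tsv))

    def species_lexicon(self, gene_index: GeneIndex | None = None) -> SpeciesLexicon:
        gene_index = gene_index or self.gene_index()
        names = pd.read_csv(io.StringIO(self.taxonomy_tsv), sep="\t", dtype=str)
        cells = pd.read_csv(io.StringIO(self.cell_lines_tsv), sep="\t", dtype=str)
        return build_species_lexicon(names, cells, gene_index)

    def tagger(self) -> "PlantLogTagger":
        return PlantLogTagger(self)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        (directory / "articles").mkdir(parents=True, exist_ok=True)
        (directory / "gene_info.tsv").write_text(self.gene_info_tsv)
        (directory / "taxonomy.tsv").write_text(self.taxonomy_tsv)
        (directory / "cell_lines.tsv").write_text(self.cell_lines_tsv)
        (directory / "gold.tsv").write_text(self.gold_tsv())
        for doc_id in sorted(self.articles):
            (directory / "articles" / f"{doc_id}.txt").write_text(
                self.articles[doc_id])
        (directory / "plants.json").write_text(json.dumps(
            [p.as_dict() for p in self.plants], indent=1, sort_keys=True))


class PlantLogTagger:
    """A perfect-recall gene-mention tagger driven by the plant log.

    Stands in for an external statistical tagger: it emits exactly the
    taggable planted spans (gene variations and gene-looking decoys) of the
    article it is given, identified by text content lookup.
    """

    def __init__(self, corpus: FixtureCorpus):
        self._by_text = {corpus.articles[d]: d for d in corpus.articles}
        self._spans: dict[str, list[tuple[str, int, int]]] = {
            d: [] for d in corpus.articles}
        for p in corpus.plants:
            if p.taggable:
                self._spans[p.doc_id].append((p.surface, p.start, p.end))

    def __call__(self, article_text: str):
        doc = self._by_text.get(article_text)
        if doc is None:
            return []
        return list(self._spans[doc])


def _universe_tsvs() -> tuple[str, str, str]:
    gene_lines = ["tax_id\tGeneID\tSymbol\tLocusTag\tSynonyms\tdbXrefs"]
    for tax, gid, sym, locus, syn, xref in GENE_ROWS:
        gene_lines.append(f"{tax}\t{gid}\t{sym}\t{locus}\t{syn}\t{xref}")
    tax_lines = ["tax_id\tname_txt\tname_class\trank"]
    for tax, name, cls, rank in TAXONOMY_ROWS:
        tax_lines.append(f"{tax}\t{name}\t{cls}\t{rank}")
    cell_lines = ["name\ttax_id"]
    for name, tax in CELL_LINE_ROWS:
        cell_lines.append(f"{name}\t{tax}")
    return ("\n".join(gene_lines) + "\n", "\n".join(tax_lines) + "\n",
            "\n".join(cell_lines) + "\n")


_CUE_CYCLE = ("forward", "backward", "previous", "majority")

#: countable species-mention surfaces contributed by the templates, with the
#: taxon they resolve to after inference (decoy species are filtered by the
#: pipeline and therefore not counted)
_SURFACE_TAX: dict[str, int] = {
    **{cue.lower(): tax for tax, cue in CUES.items()},
    "a549": 9606,
    "e. coli k12": 511145,
    "mg1655": 511145,
}


def _species_counts(sentences: list[_Sentence]) -> dict[int, int]:
    """Expected post-inference species profile of the assembled sentences."""
    counts: dict[int, int] = {}
    for s in sentences:
        text = s.text.lower()
        for surface, tax in _SURFACE_TAX.items():
            pos = 0
            while (pos := text.find(surface, pos)) != -1:
                before = text[pos - 1] if pos else " "
                after_idx = pos + len(surface)
                after = text[after_idx] if after_idx < len(text) else " "
                if not before.isalnum() and not after.isalnum():
                    counts[tax] = counts.get(tax, 0) + 1
                pos = after_idx
    return counts


def make_fixture_corpus(seed: int, n_docs: int = 20,
                        config: FixtureConfig | None = None) -> FixtureCorpus:
    """Generate a deterministic corpus of ``n_docs`` articles with gold truth."""
    config = config or FixtureConfig()
    rng = random.Random(seed)
    gene_tsv, tax_tsv, cell_tsv = _universe_tsvs()
    articles: dict[str, str] = {}
    plants: list[PlantRecord] = []

    for i in range(n_docs):
        doc_id = f"doc{i:04d}"
        sentences: list[_Sentence] = []
        dominant = rng.choice((9606, 10090))
        cue_type = _CUE_CYCLE[i % len(_CUE_CYCLE)]

        if config.variations:
            k = rng.randint(2, 4)
            for builder in rng.sample(VARIATION_BUILDERS, k):
                sentences.append(builder(rng))
        else:
            k = rng.randint(config.exact_min, config.exact_max)
            for _ in range(k):
                sentences.append(_exact(rng))

        if config.ambiguous:
            tax = dominant if cue_type == "majority" else rng.choice((9606, 10090))
            sentences.append(_ambiguous(rng, cue_type, tax))

        rng.shuffle(sentences)
        if config.ambiguous and cue_type == "majority":
            # the majority-cued plant is only recoverable if its taxon really
            # is the article's strict majority: top up with support sentences
            counts = _species_counts(sentences)
            rival = max((v for t, v in counts.items() if t != dominant),
                        default=0)
            needed = max(rival + 1 - counts.get(dominant, 0), 1)
            for _ in range(needed):
                sentences.append(_Sentence(
                    f"All subsequent experiments used {CUES[dominant]} samples."))
        if config.decoys:
            sentences.extend(_decoys(rng))

        offset = 0
        parts: list[str] = []
        for s in sentences:
            for (rs, re_, surface, gold, tax, taggable, kind, cue) in s.plants:
                plants.append(PlantRecord(doc_id, kind, surface,
                                          offset + rs, offset + re_,
                                          tuple(gold), tax, taggable, cue))
            parts.append(s.text)
            offset += len(s.text) + 1   # joined with a single space
        articles[doc_id] = " ".join(parts)

    return FixtureCorpus(seed=seed, articles=articles, plants=plants,
                         gene_info_tsv=gene_tsv, taxonomy_tsv=tax_tsv,
                         cell_lines_tsv=cell_tsv)


def profile_standin_article() -> tuple[str, dict[int, int]]:
    """Synthetic stand-in article with a fixed species-mention inventory.

    Emulates the species-mention census of a typical human cell-line study:
    one "293 cells", thirty-four a549 mentions (one guaranteed "A549 cells"
    plus 33 bare codes resolved by guaranteed inference), six "human", one
    "bovine", one "mice" and one "murine", one "rabbit", and two
    "Sendai virus" — so the expected profile is {9606: 41, 9913: 1,
    10090: 2, 9986: 1, 11191: 2}. Returns (article_text, expected_counts).
    """
    sentences = ["A549 cells were maintained under standard conditions."]
    sentences += [f"A549 cultures were examined at passage {i}."
                  for i in range(2, 35)]
    sentences.append("Transfection efficiency was verified in 293 cells.")
    sentences += ["Samples were obtained from human donors."] * 6
    sentences.append("Comparative lysates came from bovine tissue.")
    sentences.append("Parallel experiments used mice throughout.")
    sentences.append("Expression was confirmed in murine tissue.")
    sentences.append("Distribution was assessed in rabbit tissue.")
    sentences += ["Cells were infected with Sendai virus before analysis."] * 2
    expected = {9606: 41, 9913: 1, 10090: 2, 9986: 1, 11191: 2}
    return " ".join(sentences), expected
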
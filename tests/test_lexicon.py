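"""Gene dictionary loading, symbol normalization, and species lexicon building."""

import io
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genelink.lexicon import (SpeciesEntry, build_species_lexicon,
                              compile_species_pattern, extend_synonyms,
                              load_gene_info, normalize_symbol)

GENE_INFO_3ROWS = """\
tax_id\tGeneID\tSymbol\tLocusTag\tSynonyms\tdbXrefs
9606\t51554\tACKR4\t-\tCCRL1|CKRX\tHGNC:HGNC:1611
4932\t850557\tPBN1\tYCL057C-A\t-\tSGD:S000000563
9606\t7157\tTP53\t-\ttumor protein p53\t-
"""


class TestGeneInfo:
    def test_three_row_file_builds_expected_index(self):
        index = load_gene_info(io.StringIO(GENE_INFO_3ROWS))
        assert set(index.records) == {51554, 850557, 7157}
        assert index.records[51554].entities == {"ACKR4", "CCRL1", "CKRX"}
        assert index.by_tax_entity[(9606, "ccrl1")] == {51554}
        assert index.by_tax_entity[(9606, "ckrx")] == {51554}
        # words are the union of entity bags
        assert index.records[7157].words == {"tp53", "tumor", "protein", "p53"}
        assert index.df_word["p53"] == 1
        assert index.df_entity["tp53"] == 1

    def test_locus_tag_normalized_in_external_index(self):
        index = load_gene_info(io.StringIO(GENE_INFO_3ROWS))
        assert index.by_ext_id["ycl057ca"] == (850557, 4932)
        assert index.by_ext_id["s000000563"] == (850557, 4932)

    def test_empty_file_gives_empty_index(self):
        header = "tax_id\tGeneID\tSymbol\tLocusTag\tSynonyms\tdbXrefs\n"
        index = load_gene_info(io.StringIO(header))
        assert index.n_ids == 0
        assert not index.by_tax_entity and not index.by_ext_id

    def test_malformed_row_skipped_duplicate_gene_errors(self):
        bad = GENE_INFO_3ROWS + "9606\tnot_an_id\tX\t-\t-\t-\n"
        assert load_gene_info(io.StringIO(bad)).n_ids == 3
        dup = GENE_INFO_3ROWS + "9606\t7157\tTP53B\t-\t-\t-\n"
        with pytest.raises(ValueError, match="duplicate"):
            load_gene_info(io.StringIO(dup))


class TestNormalizeSymbol:
    @pytest.mark.parametrize("raw,expected", [
        ("YCL057C-A", "ycl057ca"),
        ("abc123", "abc123"),
        ("P 53._x", "p53x"),
        ("TLR-7", "tlr7"),
    ])
    def test_examples(self, raw, expected):
        assert normalize_symbol(raw) == expected

    @given(st.text(max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_idempotent(self, s):
        assert normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)


class TestExtendSynonyms:
    def test_genus_abbreviation_forms(self):
        syns = extend_synonyms("escherichia coli k-12")
        assert {"e.coli k-12", "e. coli k-12", "escherichia coli k-12"} == syns
        assert extend_synonyms("homo sapiens") == {
            "homo sapiens", "h.sapiens", "h. sapiens"}

    def test_single_word_unchanged(self):
        assert extend_synonyms("arabidopsis") == {"arabidopsis"}

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            extend_synonyms("  ")


def _entry(synonyms):
    return SpeciesEntry(tax_id=1, scientific_name=min(synonyms),
                        synonyms=set(synonyms), rank_type="species", genus="x")


class TestSpeciesPattern:
    K12_SYNONYMS = {"escherichia coli k-12", "escherichia coli k12",
                    "e.coli k-12", "e. coli k-12"}

    def test_matching_equivalent_to_reference_factored_form(self):
        """Both the generated and the factored reference pattern accept exactly
        the synonym set for the E. coli K-12 entry."""
        mine = re.compile(compile_species_pattern(_entry(self.K12_SYNONYMS)),
                          re.IGNORECASE)
        factored = re.compile(r"e(?:\. ?coli k\-12|scherichia coli k\-?12)",
                              re.IGNORECASE)
        positives = self.K12_SYNONYMS | {s.upper() for s in self.K12_SYNONYMS}
        negatives = ["e. coli", "escherichia coli", "e. coli k-123",
                     "scherichia coli k12", ""]
        for s in positives:
            assert mine.fullmatch(s) and factored.fullmatch(s)
        for s in negatives:
            assert not mine.fullmatch(s) and not factored.fullmatch(s)

    def test_single_synonym(self):
        pat = re.compile(compile_species_pattern(_entry({"zebrafish"})),
                         re.IGNORECASE)
        assert pat.fullmatch("Zebrafish")
        assert not pat.fullmatch("zebrafishx")

    @given(st.sets(st.text(alphabet="abc .-(", min_size=1, max_size=12),
                   min_size=1, max_size=8))
    @settings(max_examples=100, derandomize=True)
    def test_set_membership_oracle(self, synonyms):
        """Pattern accepts exactly the synonym set (mutated strings rejected)."""
        pat = re.compile(compile_species_pattern(_entry(synonyms)), re.IGNORECASE)
        for s in synonyms:
            assert pat.fullmatch(s)
            assert not pat.fullmatch(s + "q")
            assert not pat.fullmatch("q" + s)


class TestSpeciesLexicon:
    def test_geneless_taxon_removed(self, corpus, gene_index, lexicon):
        # tax 99999 is in the taxonomy table but owns no gene
        assert "plantus imaginarius" in corpus.taxonomy_tsv.lower()
        assert 99999 not in lexicon.entries
        assert all(gene_index.genes_per_tax.get(t, 0) >= 1
                   for t in lexicon.entries)

    def test_excluded_rank_absent(self, lexicon):
        assert 99988 not in lexicon.entries  # genus-rank row

    def test_genus_and_subtype_indexes(self, lexicon):
        assert 9606 in lexicon.genus_index["homo"]
        assert lexicon.subtype_index["mg1655"] == 511145
        assert lexicon.entries[83333].family_ambiguous
        assert lexicon.entries[562].family_ambiguous
        assert not lexicon.entries[9606].family_ambiguous

    def test_extended_abbreviations_indexed(self, lexicon):
        assert lexicon.name_index["e. coli k12"] == 83333
        assert lexicon.name_index["e.coli k-12"] == 83333

    def test_collision_resolved_by_priority(self, gene_index, corpus):
        import pandas as pd
        names = pd.read_csv(io.StringIO(corpus.taxonomy_tsv), sep="\t", dtype=str)
        # give a no-rank taxon the same name as a species-rank taxon
        clash = pd.DataFrame([{"tax_id": "83333", "name_txt": "cat",
                               "name_class": "synonym", "rank": "no rank"},
                              {"tax_id": "9685", "name_txt": "cat",
                               "name_class": "genbank common name",
                               "rank": "species"}])
        names = pd.concat([names, clash.iloc[[0]]], ignore_index=True)
        lex = build_species_lexicon(names, None, gene_index)
        assert lex.name_index["cat"] == 9685          # species beats no-rank
        assert "cat" not in lex.entries[83333].synonyms

    def test_deterministic_name_index(self, corpus, gene_index):
        a = corpus.species_lexicon(gene_index).name_index
        b = corpus.species_lexicon(gene_index).name_index
        assert a == b
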
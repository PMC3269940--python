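"""Mention post-processing rules, distillation, and identifier extraction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genelink.recognize import (DictionaryTagger, GeneMention, RawTag, distill,
                                expand_enumerations, extract_identifiers,
                                postprocess, split_conjunctions,
                                split_parentheses, strip_headwords, tag,
                                translate_number_type)
from genelink.textutils import to_bag_of_words


class TestRewriteRules:
    @pytest.mark.parametrize("text,expected", [
        ("III", "3"),
        ("factor IX", "factor 9"),
        ("alpha beta gamma", "a b g"),
        ("TLR7", "TLR7"),
        ("MIX", "MIX"),          # not a standalone numeral
    ])
    def test_number_type(self, text, expected):
        assert translate_number_type(text) == expected

    @pytest.mark.parametrize("text,expected", [
        ("GABARAP and light chain 3", ["GABARAP", "light chain 3"]),
        ("furin or proprotein convertase", ["furin", "proprotein convertase"]),
        ("SMAD4", ["SMAD4"]),
        ("SMADs 1, 5 and 8", ["SMADs 1, 5 and 8"]),   # enumeration, not a conjunction
    ])
    def test_conjunctions(self, text, expected):
        assert split_conjunctions(text) == expected

    @pytest.mark.parametrize("text,expected", [
        ("Robo 1/2", ["Robo 1", "Robo 2"]),
        ("SMADs 1, 5 and 8", ["SMAD 1", "SMAD 5", "SMAD 8"]),
        ("TLR7", ["TLR7"]),
    ])
    def test_enumerations(self, text, expected):
        assert expand_enumerations(text) == expected

    @pytest.mark.parametrize("text,expected", [
        ("fibroblast growth factor-2 (FGF-2)-interacting-factor",
         {"FGF-2", "fibroblast growth factor 2 interacting factor"}),
        ("gamma carboxyglutamic acid (Gla)",
         {"gamma carboxyglutamic acid", "Gla"}),
        ("BRCA1", {"BRCA1"}),
    ])
    def test_parentheses(self, text, expected):
        assert set(split_parentheses(text)) == expected

    def test_unbalanced_parentheses_ignored(self):
        assert split_parentheses("BRCA1 (truncated") == ["BRCA1 (truncated"]

    @pytest.mark.parametrize("text,expected", [
        ("MURF 3 protein", "MURF 3"),
        ("protein", ""),
        ("tumor protein p53", "tumor protein p53"),   # interior token kept
        ("gene MURF 3 genes", "MURF 3"),
    ])
    def test_strip_headwords(self, text, expected):
        assert strip_headwords(text) == expected

    @pytest.mark.parametrize("text", [
        "Robo 1/2", "SMADs 1, 5 and 8", "GABARAP and light chain 3",
        "fibroblast growth factor-2 (FGF-2)-interacting-factor",
        "MURF 3 protein", "factor IX", "PKC alpha", "TLR7",
    ])
    def test_pipeline_idempotent_on_own_output(self, text):
        once = postprocess(text)
        twice = [s for surface in once for s in postprocess(surface)]
        assert twice == once

    @given(st.text(alphabet=st.characters(codec="ascii"), max_size=40))
    @settings(max_examples=150, derandomize=True)
    def test_pipeline_idempotent_property(self, text):
        once = postprocess(text)
        assert [s for surface in once for s in postprocess(surface)] == once


class TestBagOfWords:
    @pytest.mark.parametrize("text,expected", [
        ("Hypoxia-inducible factor-1 alpha",
         ["hypoxia", "inducible", "factor", "1", "alpha"]),
        ("", []),
        ("FGF-2", ["fgf", "2"]),
    ])
    def test_examples(self, text, expected):
        assert to_bag_of_words(text) == expected

    def test_every_mention_bag_matches_surface(self):
        for surface in postprocess("SMADs 1, 5 and 8"):
            assert GeneMention(surface, RawTag(surface, 0, len(surface))).bag \
                == to_bag_of_words(surface)


class TestTagging:
    def test_dictionary_tagger_finds_planted_name(self, gene_index):
        text = "the CCRL1 receptor"
        tags = tag(text, DictionaryTagger(gene_index))
        assert tags == [RawTag("CCRL1", 4, 9)]

    def test_empty_text(self, gene_index):
        assert tag("", DictionaryTagger(gene_index)) == []

    def test_overlaps_resolved_to_longer_span(self):
        def overlapping(text):
            return [("CCRL", 0, 4), ("CCRL1", 0, 5)]
        assert tag("CCRL1", overlapping) == [RawTag("CCRL1", 0, 5)]

    def test_fixture_plants_recovered(self, corpus, gene_index):
        doc = sorted(corpus.articles)[0]
        planted = [(p.surface, p.start, p.end) for p in corpus.plants
                   if p.doc_id == doc and p.taggable]
        tags = tag(corpus.articles[doc], corpus.tagger())
        assert [(t.text, t.start, t.end) for t in tags] == sorted(
            planted, key=lambda p: p[1])


def _mention_at(text, surface):
    start = text.index(surface)
    t = RawTag(surface, start, start + len(surface))
    return GeneMention(surface, t)


class TestDistillation:
    def test_antibody_context_removed(self):
        text = "lysates probed with anti-p53 antibody overnight"
        kept = distill([_mention_at(text, "p53")], text)
        assert kept == []

    def test_figure_label_removed(self):
        text = "bands are quantified in figure S4 below"
        assert distill([_mention_at(text, "S4")], text) == []

    def test_clean_mention_kept_and_count_never_grows(self):
        text = "CCRL1 binds chemokines; anti-p53 antibody was used"
        mentions = [_mention_at(text, "CCRL1"), _mention_at(text, "p53")]
        kept = distill(mentions, text)
        assert [m.surface for m in kept] == ["CCRL1"]
        assert len(kept) <= len(mentions)

    def test_family_and_biomedical_filters(self):
        text = "the SMAD4 family regulates the TLR7 pathway"
        mentions = [_mention_at(text, "SMAD4"), _mention_at(text, "TLR7")]
        assert distill(mentions, text) == []


class TestIdentifierExtraction:
    def test_locus_tag_mapped(self, gene_index):
        out = extract_identifiers("Locus YCL057C-A was essential.", gene_index)
        assert [(m.surface, m.matched_gene) for m in out] == [
            ("YCL057C-A", (850557, 4932))]
        assert all(m.source == "identifier" for m in out)

    def test_two_identifiers_in_one_sentence(self, gene_index):
        out = extract_identifiers(
            "Strains carried YOR019W and YGL035C deletions.", gene_index)
        assert [(m.surface, m.matched_gene) for m in out] == [
            ("YOR019W", (855978, 4932)), ("YGL035C", (852846, 4932))]

    def test_no_mixed_token_no_output(self, gene_index):
        assert extract_identifiers("no identifiers appear here.", gene_index) == []

    def test_unindexed_identifier_ignored(self, gene_index):
        assert extract_identifiers("token ZZ9 plural Z alpha.", gene_index) == []
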
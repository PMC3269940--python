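"""Candidate generation, intersection filtering, and two-channel scoring."""

import io
import math
import random

import pytest

from genelink.assign import AssignedMention
from genelink.lexicon import load_gene_info
from genelink.rank import (CandidateId, generate_candidates,
                           intersection_filter, score_candidates)
from genelink.recognize import GeneMention, RawTag

TOY_GENE_INFO = """\
tax_id\tGeneID\tSymbol\tLocusTag\tSynonyms\tdbXrefs
9606\t101\tCCRL1\t-\tchemokine receptor like 1\t-
9606\t102\tTLR7\t-\t-\t-
9606\t103\tCB1\t-\tchemokine binder\t-
"""


@pytest.fixture(scope="module")
def toy_index():
    return load_gene_info(io.StringIO(TOY_GENE_INFO))


def _assigned(surface, tax=9606):
    m = GeneMention(surface, RawTag(surface, 0, len(surface)))
    return AssignedMention(m, tax, "forward", surface)


class TestCandidates:
    def test_exact_entity_match(self, toy_index):
        cids = generate_candidates([_assigned("CCRL1")], toy_index)
        by_id = {c.gene_id: c for c in cids}
        assert "ccrl1" in by_id[101].matched_entities

    def test_partial_word_match(self, toy_index):
        cids = generate_candidates([_assigned("chemokine receptor like 1")],
                                   toy_index)
        by_id = {c.gene_id: c for c in cids}
        assert {"chemokine", "receptor", "like"} <= by_id[101].matched_words
        assert by_id[103].matched_words == {"chemokine"}

    def test_candidates_restricted_to_assigned_taxon(self, toy_index):
        assert generate_candidates([_assigned("CCRL1", tax=10090)], toy_index) == []

    def test_no_word_overlap_no_candidate(self, toy_index):
        assert generate_candidates([_assigned("unrelated thing")], toy_index) == []

    def test_identifier_mention_contributes_directly(self, toy_index):
        m = GeneMention("XYZ1", RawTag("XYZ1", 0, 4), source="identifier",
                        matched_gene=(102, 9606))
        cids = generate_candidates([AssignedMention(m, 9606, "identifier", "XYZ1")],
                                   toy_index)
        assert [(c.gene_id, sorted(c.matched_entities)) for c in cids] == [
            (102, ["xyz1"])]


def _oracle_filter(cids):
    """Independent subset-removal oracle: literal pairwise definition."""
    out = []
    for c in cids:
        strict_superset_exists = False
        for other in cids:
            if other is c:
                continue
            if c.term_list != other.term_list and \
                    c.term_list.issubset(other.term_list):
                strict_superset_exists = True
        if not strict_superset_exists:
            out.append(c)
    return out


class TestIntersectionFilter:
    def test_strict_subset_removed(self):
        c1 = CandidateId(1, 9606, matched_words={"a", "b"})
        c2 = CandidateId(2, 9606, matched_words={"a", "b", "c"})
        assert intersection_filter([c1, c2]) == [c2]

    def test_disjoint_kept_and_equal_sets_survive(self):
        c1 = CandidateId(1, 9606, matched_words={"a"})
        c2 = CandidateId(2, 9606, matched_words={"b"})
        assert intersection_filter([c1, c2]) == [c1, c2]
        e1 = CandidateId(3, 9606, matched_words={"a", "b"})
        e2 = CandidateId(4, 9606, matched_words={"a", "b"})
        assert intersection_filter([e1, e2]) == [e1, e2]

    def test_random_instances_match_oracle(self):
        rng = random.Random(42)
        universe = "abcdefgh"
        for _ in range(200):
            n = rng.randint(1, 12)
            cids = [CandidateId(i, 9606,
                                matched_words=set(rng.sample(universe,
                                                             rng.randint(1, 6))))
                    for i in range(n)]
            got = intersection_filter(cids)
            assert [c.gene_id for c in got] == \
                [c.gene_id for c in _oracle_filter(cids)]

    def test_idempotent(self):
        rng = random.Random(1)
        cids = [CandidateId(i, 9606,
                            matched_words=set(rng.sample("abcde", rng.randint(1, 4))))
                for i in range(10)]
        once = intersection_filter(cids)
        assert intersection_filter(once) == once


class TestScoring:
    def test_hand_computed_two_channel_score(self, toy_index):
        """Two exact entities + word overlaps, checked against an arithmetic
        recomputation of the TF-IDF sums."""
        mentions = [_assigned("CCRL1"), _assigned("CCRL1"),
                    _assigned("chemokine receptor like 1")]
        cids = generate_candidates(mentions, toy_index)
        ranking = score_candidates(cids, mentions, toy_index, lambda_entity=0.7)
        n = 3
        ln3, ln32 = math.log(3), math.log(3 / 2)
        # gene 101: entities ccrl1 (tf 2) and the full name (tf 1), both df 1
        s_e_101 = 2 * ln3 + 1 * ln3
        # words: ccrl1 tf2 df1; chemokine tf1 df2; receptor/like/1 tf1 df1
        s_w_101 = 2 * ln3 + 1 * ln32 + 3 * ln3
        s_w_103 = 1 * ln32          # gene 103 shares only "chemokine"
        expected_103 = (0.3 * (s_w_103 / s_w_101)) / 1.0
        assert ranking.items[0] == (101, 1.0)
        assert ranking.items[1][0] == 103
        assert ranking.items[1][1] == pytest.approx(expected_103, rel=1e-12)

    def test_single_candidate_confidence_one(self, toy_index):
        mentions = [_assigned("TLR7")]
        cids = generate_candidates(mentions, toy_index)
        ranking = score_candidates(cids, mentions, toy_index)
        assert ranking.items == [(102, 1.0)]

    def test_extra_entity_wins_for_any_positive_lambda(self, toy_index):
        base = CandidateId(201, 9606, matched_words={"chemokine"})
        extra = CandidateId(202, 9606, matched_words={"chemokine"},
                            matched_entities={"ccrl1"})
        mentions = [_assigned("CCRL1"), _assigned("chemokine")]
        for lam in (0.1, 0.5, 0.7, 1.0):
            ranking = score_candidates([base, extra], mentions, toy_index,
                                       lambda_entity=lam)
            assert ranking.items[0][0] == 202

    def test_lambda_extremes_select_single_channel(self, toy_index):
        entity_only = CandidateId(301, 9606, matched_entities={"ccrl1"})
        word_only = CandidateId(302, 9606, matched_words={"chemokine"})
        mentions = [_assigned("CCRL1"), _assigned("chemokine")]
        pure_entity = score_candidates([entity_only, word_only], mentions,
                                       toy_index, lambda_entity=1.0)
        assert pure_entity.items == [(301, 1.0)]   # word evidence ignored
        pure_word = score_candidates([entity_only, word_only], mentions,
                                     toy_index, lambda_entity=0.0)
        assert pure_word.items == [(302, 1.0)]     # entity evidence ignored

    def test_ranking_invariant_to_candidate_order(self, toy_index):
        mentions = [_assigned("CCRL1"), _assigned("chemokine receptor like 1")]
        cids = generate_candidates(mentions, toy_index)
        forward = score_candidates(cids, mentions, toy_index)
        backward = score_candidates(list(reversed(cids)), mentions, toy_index)
        assert forward.items == backward.items

    def test_all_zero_scores_empty_ranking(self, toy_index):
        cid = CandidateId(400, 9606, matched_words={"zzz"})   # tf 0 everywhere
        ranking = score_candidates([cid], [], toy_index)
        assert ranking.items == []

    def test_monotone_in_added_terms(self, toy_index):
        """Adding a matched term with positive weight never lowers a score."""
        mentions = [_assigned("CCRL1"), _assigned("chemokine")]
        small = CandidateId(501, 9606, matched_words={"chemokine"})
        grown = CandidateId(501, 9606, matched_words={"chemokine"},
                            matched_entities={"ccrl1"})
        rival = CandidateId(502, 9606, matched_entities={"ccrl1"},
                            matched_words={"chemokine"})
        before = dict(score_candidates([small, rival], mentions, toy_index).items)
        after = dict(score_candidates([grown, rival], mentions, toy_index).items)
        assert after[501] >= before.get(501, 0.0)
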
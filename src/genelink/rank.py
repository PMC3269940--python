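"""Candidate generation and two-channel TF-IDF ranking of gene identifiers.

For every species-assigned mention, candidate gene ids of the same taxon are
collected through two channels: the exact channel (the normalized mention
surface equals a normalized dictionary entity) and the partial channel (at
least one word of the mention's bag occurs in the gene record's word set).
Candidates accumulate their matched entities and words article-wide; a
candidate whose matched-term list is a strict subset of another's is removed
(intersection filtering), and survivors are scored by

    S_E(c) = Σ_{e ∈ matched_entities} tf(e) · ln(N / df_entity(e))
    S_W(c) = Σ_{w ∈ matched_words}    tf(w) · ln(N / df_word(w))

where tf counts occurrences among the article's post-processed mention
surfaces (entity channel) or mention-bag words (word channel), N is the number
of gene records in the dictionary, and df the number of records containing the
term. Each channel is max-normalized within the article and combined as
λ·Ŝ_E + (1−λ)·Ŝ_W (λ = 0.7 by default: exact name matches are stronger
evidence than shared words). The final ranking is rescaled so the top
candidate's confidence is 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .assign import AssignedMention
from .lexicon import GeneIndex, normalize_symbol

__all__ = [
    "CandidateId", "Ranking", "generate_candidates", "intersection_filter",
    "score_candidates", "write_predictions", "read_predictions",
]


@dataclass
class CandidateId:
    gene_id: int
    tax_id: int
    matched_entities: set[str] = field(default_factory=set)
    matched_words: set[str] = field(default_factory=set)

    @property
    def term_list(self) -> frozenset[str]:
        return frozenset(self.matched_entities) | frozenset(self.matched_words)


@dataclass
class Ranking:
    doc_id: str
    items: list[tuple[int, float]] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[int]:
        return [g for g, _ in self.items]


def generate_candidates(
    assigned: list[AssignedMention], index: GeneIndex,
) -> list[CandidateId]:
    """Collect candidate gene ids for the article's assigned mentions.

    Exact and partial channels are both restricted to the mention's assigned
    taxon; identifier-source mentions contribute their matched gene directly.
    Candidates are merged per gene_id across mentions.
    """
    pool: dict[int, CandidateId] = {}

    def candidate(gene_id: int, tax_id: int) -> CandidateId:
        if gene_id not in pool:
            pool[gene_id] = CandidateId(gene_id, tax_id)
        return pool[gene_id]

    for a in assigned:
        norm = normalize_symbol(a.match_surface)
        if a.mention.source == "identifier" and a.mention.matched_gene:
            gene_id, tax_id = a.mention.matched_gene
            candidate(gene_id, tax_id).matched_entities.add(norm)
            continue
        for gene_id in index.by_tax_entity.get((a.tax_id, norm), ()):
            candidate(gene_id, a.tax_id).matched_entities.add(norm)
        for w in set(a.match_bag):
            for gene_id in index.by_tax_word.get((a.tax_id, w), ()):
                candidate(gene_id, a.tax_id).matched_words.add(w)
    return [pool[g] for g in sorted(pool)]


def intersection_filter(cids: list[CandidateId]) -> list[CandidateId]:
    """Remove candidates whose term list is a strict subset of another's.

    Equal term lists both survive; input order is preserved.
    """
    terms = [c.term_list for c in cids]
    keep = []
    for i, c in enumerate(cids):
        if not any(terms[i] < terms[j] for j in range(len(cids)) if j != i):
            keep.append(c)
    return keep


def score_candidates(
    cids: list[CandidateId],
    assigned: list[AssignedMention],
    index: GeneIndex,
    doc_id: str = "",
    lambda_entity: float = 0.7,
    use_idf: bool = True,
) -> Ranking:
    """Rank candidates by the max-normalized two-channel TF-IDF combination.

    ``use_idf=False`` degrades both channels to plain term-frequency sums (a
    flat vector-space scorer, kept for ablation of the inference network).
    Ties are broken by the raw entity-channel score, then by gene_id. An
    all-zero score set yields an empty ranking.
    """
    n = index.n_ids
    tf_entity: dict[str, int] = {}
    tf_word: dict[str, int] = {}
    for a in assigned:
        norm = normalize_symbol(a.match_surface)
        tf_entity[norm] = tf_entity.get(norm, 0) + 1
        for w in a.match_bag:
            tf_word[w] = tf_word.get(w, 0) + 1

    def idf(df: dict[str, int], term: str) -> float:
        if not use_idf:
            return 1.0
        return math.log(n / df.get(term, 1)) if n > 0 else 0.0

    s_entity = {c.gene_id: sum(tf_entity.get(e, 0) * idf(index.df_entity, e)
                               for e in c.matched_entities) for c in cids}
    s_word = {c.gene_id: sum(tf_word.get(w, 0) * idf(index.df_word, w)
                             for w in c.matched_words) for c in cids}
    max_e = max(s_entity.values(), default=0.0)
    max_w = max(s_word.values(), default=0.0)

    combined: list[tuple[int, float]] = []
    for c in cids:
        se = s_entity[c.gene_id] / max_e if max_e > 0 else 0.0
        sw = s_word[c.gene_id] / max_w if max_w > 0 else 0.0
        score = lambda_entity * se + (1.0 - lambda_entity) * sw
        if score > 0:
            combined.append((c.gene_id, score))
    if not combined:
        return Ranking(doc_id=doc_id)
    combined.sort(key=lambda gs: (-gs[1], -s_entity[gs[0]], gs[0]))
    top = combined[0][1]
    return Ranking(doc_id=doc_id,
                   items=[(g, s / top) for g, s in combined])


# --------------------------------------------------------------------------
# prediction I/O (doc_id, gene_id, rank, confidence)

def write_predictions(rankings: list[Ranking], path: str | Path) -> None:
    lines = ["doc_id\tgene_id\trank\tconfidence"]
    for r in rankings:
        for pos, (gene_id, score) in enumerate(r.items, start=1):
            lines.append(f"{r.doc_id}\t{gene_id}\t{pos}\t{score:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_predictions(path: str | Path) -> list[Ranking]:
    rankings: dict[str, Ranking] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        doc_id, gene_id, _rank, confidence = line.split("\t")
        rankings.setdefault(doc_id, Ranking(doc_id)).items.append(
            (int(gene_id), float(confidence)))
    return list(rankings.values())
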
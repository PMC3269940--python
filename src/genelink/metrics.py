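"""Evaluation: micro precision/recall/F-measure and threshold average precision.

TAP-k extends average precision with an error-bounded cutoff and a terminal
penalty. Per query, the ranked list is truncated at the position of the k-th
false positive (or at the list end if fewer errors occur); the score is

    ( Σ precision@rank over relevant hits up to the cutoff
      + precision@cutoff )  /  (|gold| + 1)

averaged over queries. The terminal precision term penalizes rankings that
pad their tail with errors; the +1 in the denominator is its weight. The
cutoff policy is pluggable: any callable mapping (relevance list, k) to a
cutoff length may replace the default k-th-error rule. Note that the terminal
term makes TAP-k non-monotone in k: a deeper cutoff with no further relevant
items dilutes the terminal precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

from .rank import Ranking

logger = logging.getLogger(__name__)

__all__ = ["GoldSet", "EvalReport", "load_gold", "prf", "tap_k", "evaluate",
           "kth_error_cutoff"]

GoldSet = Mapping[str, set[int]]


def load_gold(path: str | Path) -> dict[str, set[int]]:
    """Read gold annotations: one ``doc_id <TAB> gene_id`` pair per line."""
    gold: dict[str, set[int]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("doc_id"):
            continue
        doc_id, gene_id = line.split("\t")[:2]
        gold.setdefault(doc_id, set()).add(int(gene_id))
    return gold


@dataclass
class EvalReport:
    precision: float
    recall: float
    f_measure: float
    tap: dict[int, float] = field(default_factory=dict)
    per_doc: dict[str, dict] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            **{f"tap_{k}": v for k, v in sorted(self.tap.items())},
        }


def prf(preds: Mapping[str, set[int]], gold: GoldSet) -> tuple[float, float, float]:
    """Micro-averaged precision, recall and F over all documents.

    Predictions are treated as unranked sets; documents present in either
    mapping contribute their true/false positives and misses to the pooled
    counts.
    """
    tp = fp = fn = 0
    for doc in set(preds) | set(gold):
        p = set(preds.get(doc, set()))
        g = set(gold.get(doc, set()))
        tp += len(p & g)
        fp += len(p - g)
        fn += len(g - p)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f = (2 * precision * recall / (precision + recall)
         if (precision + recall) else 0.0)
    return precision, recall, f


def kth_error_cutoff(relevance: list[bool], k: int) -> int:
    """Default cutoff: length of the prefix ending at the k-th false positive.

    Returns the full list length when fewer than k errors occur.
    """
    errors = 0
    for i, rel in enumerate(relevance):
        if not rel:
            errors += 1
            if errors == k:
                return i + 1
    return len(relevance)


def tap_query(ranked_ids: list[int], gold_ids: set[int], k: int,
              cutoff_policy: Callable[[list[bool], int], int] = kth_error_cutoff,
              ) -> float:
    relevance = [g in gold_ids for g in ranked_ids]
    cut = cutoff_policy(relevance, k)
    hits = 0
    ap_sum = 0.0
    for i in range(cut):
        if relevance[i]:
            hits += 1
            ap_sum += hits / (i + 1)
    terminal = hits / cut if cut > 0 else 0.0
    return (ap_sum + terminal) / (len(gold_ids) + 1)


def tap_k(rankings: Iterable[Ranking], gold: GoldSet, k: int,
          cutoff_policy: Callable[[list[bool], int], int] = kth_error_cutoff,
          ) -> float:
    """Mean TAP over the gold documents.

    Gold documents missing from ``rankings`` score as empty rankings; a
    document with an empty gold set contributes only its terminal term
    (logged, since such queries are usually data problems).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_doc = {r.doc_id: r for r in rankings}
    scores = []
    for doc in sorted(gold):
        gold_ids = set(gold[doc])
        if not gold_ids:
            logger.info("doc %s has an empty gold set", doc)
        ranking = by_doc.get(doc, Ranking(doc))
        scores.append(tap_query(ranking.gene_ids, gold_ids, k, cutoff_policy))
    return sum(scores) / len(scores) if scores else 0.0


def evaluate(rankings: list[Ranking], gold: GoldSet,
             ks: tuple[int, ...] = (5, 10, 20)) -> EvalReport:
    preds = {r.doc_id: set(r.gene_ids) for r in rankings}
    precision, recall, f = prf(preds, gold)
    report = EvalReport(precision, recall, f)
    for k in ks:
        report.tap[k] = tap_k(rankings, gold, k)
    for doc in sorted(set(preds) | set(gold)):
        p = preds.get(doc, set())
        g = set(gold.get(doc, set()))
        report.per_doc[doc] = {
            "tp": len(p & g), "fp": len(p - g), "fn": len(g - p),
        }
    return report
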
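"""End-to-end orchestration: recognition → species → assignment → ranking.

`normalize_articles` is the library entry point: given article texts, a gene
dictionary, a species lexicon, a tagger, and a config, it produces one ranked
list of gene identifiers per article. `ablation_report` reruns the pipeline
with each component disabled in turn and tabulates the score deltas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .assign import AssignedMention, assign_species
from .config import COMPONENTS, PipelineConfig
from .lexicon import GeneIndex, SpeciesLexicon
from .metrics import GoldSet, evaluate
from .rank import Ranking, generate_candidates, intersection_filter, score_candidates
from .recognize import GeneMention, RawTag, distill, extract_identifiers, \
    postprocess_tags, tag
from .species import resolve_species
from .textutils import split_sentences

logger = logging.getLogger(__name__)

__all__ = ["DocResult", "normalize_article", "normalize_articles",
           "run_pipeline", "ablation_report"]


@dataclass
class DocResult:
    doc_id: str
    ranking: Ranking
    gene_mentions: list[GeneMention] = field(default_factory=list)
    assigned: list[AssignedMention] = field(default_factory=list)
    species_profile: dict[int, int] = field(default_factory=dict)
    species_resolution: dict[str, int] = field(default_factory=dict)


def normalize_article(
    doc_id: str,
    text: str,
    index: GeneIndex,
    lexicon: SpeciesLexicon,
    tagger,
    config: PipelineConfig | None = None,
) -> DocResult:
    config = config or PipelineConfig()
    sentences = split_sentences(text)

    # gene mention recognition
    raw_tags = tag(text, tagger)
    if config.enabled("post_processing"):
        mentions = postprocess_tags(raw_tags)
    else:
        mentions = [GeneMention(surface=t.text, origin=t) for t in raw_tags]
    if config.enabled("distillation"):
        mentions = distill(mentions, text)
    if config.enabled("identifier_extraction"):
        mentions.extend(extract_identifiers(text, index))

    # species extraction and inference
    species_mentions, profile = resolve_species(
        text, lexicon, sentences, config,
        infer=config.enabled("robust_inference"))
    n_direct = sum(1 for m in species_mentions if m.guaranteed)
    n_inferred = sum(1 for m in species_mentions
                     if m.resolved and not m.guaranteed)

    # assignment and ranking
    assigned = assign_species(mentions, species_mentions, profile, sentences,
                              text, config)
    cids = generate_candidates(assigned, index)
    if config.enabled("intersection_filtering"):
        cids = intersection_filter(cids)
    ranking = score_candidates(
        cids, assigned, index, doc_id=doc_id,
        lambda_entity=config.lambda_entity,
        use_idf=config.enabled("inference_network"))

    return DocResult(
        doc_id=doc_id, ranking=ranking, gene_mentions=mentions,
        assigned=assigned, species_profile=dict(profile.counts),
        species_resolution={"direct": n_direct, "inferred": n_inferred},
    )


def normalize_articles(
    articles: dict[str, str],
    index: GeneIndex,
    lexicon: SpeciesLexicon,
    tagger,
    config: PipelineConfig | None = None,
) -> dict[str, DocResult]:
    return {doc_id: normalize_article(doc_id, text, index, lexicon, tagger, config)
            for doc_id, text in sorted(articles.items())}


def run_pipeline(
    article_paths: list[str | Path],
    index: GeneIndex,
    lexicon: SpeciesLexicon,
    tagger,
    config: PipelineConfig | None = None,
) -> tuple[list[Ranking], int]:
    """File-based front end: read articles, normalize, return rankings.

    Unreadable articles are skipped with a log line; the second return value
    counts them (a nonzero count should surface as a nonzero exit status).
    """
    articles: dict[str, str] = {}
    failures = 0
    for path in article_paths:
        path = Path(path)
        try:
            articles[path.stem] = path.read_text(encoding="utf-8")
        except OSError as exc:
            logger.error("skipping unreadable article %s: %s", path, exc)
            failures += 1
    results = normalize_articles(articles, index, lexicon, tagger, config)
    return [r.ranking for r in results.values()], failures


def ablation_report(
    articles: dict[str, str],
    gold: GoldSet,
    index: GeneIndex,
    lexicon: SpeciesLexicon,
    tagger,
    config: PipelineConfig | None = None,
    ks: tuple[int, ...] = (5, 10, 20),
) -> pd.DataFrame:
    """Score the pipeline with each component removed in turn.

    Returns one row per configuration ("none" = full pipeline, then one row
    per disabled component) with TAP-k columns and their deltas against the
    full pipeline. Deltas are reported, not judged: their magnitude and even
    direction depend on the corpus composition.
    """
    config = config or PipelineConfig()

    def score(cfg: PipelineConfig) -> dict[str, float]:
        results = normalize_articles(articles, index, lexicon, tagger, cfg)
        report = evaluate([r.ranking for r in results.values()], gold, ks=ks)
        return {f"tap_{k}": report.tap[k] for k in ks}

    rows = []
    base = score(config)
    rows.append({"removed": "none", **base,
                 **{f"delta_tap_{k}": 0.0 for k in ks}})
    for component in COMPONENTS:
        scores = score(config.without(component))
        rows.append({"removed": component, **scores,
                     **{f"delta_tap_{k}": scores[f"tap_{k}"] - base[f"tap_{k}"]
                        for k in ks}})
    return pd.DataFrame(rows)
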
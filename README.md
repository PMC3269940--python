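# genelink — cross-species gene mention normalization

`genelink` maps gene and protein mentions in full-text biomedical articles to
species-specific gene database identifiers (Entrez-style integer ids). The
hard part of this task is not finding gene names but deciding *whose* gene a
name denotes: orthologs share names across species ("TP53" is a human, mouse,
or zebrafish gene depending on context), and full-text articles rarely state
the species next to the gene. `genelink` is written for text-mining
practitioners who need a transparent, rule-inspectable normalization pipeline
and a reproducible evaluation harness.

## The method

Normalization runs in three serial stages per article:

1. **Gene name recognition.** A pluggable tagger (any callable
   `text → (text, start, end)` triples; a dictionary longest-match tagger is
   built in) produces raw spans. A rewrite cascade tokenizes them —
   parenthetical abbreviations are isolated, conjunctions split
   ("GABARAP and light chain 3" → two mentions), enumerations expanded
   ("SMADs 1, 5 and 8" → "SMAD 1", "SMAD 5", "SMAD 8"), Roman numerals and
   Greek letters unified ("factor IX" → "factor 9", "alpha" → "a"), and
   head words ("protein", "gene") stripped. A distillation step removes
   mentions caught by four false-positive context patterns (family names,
   figure labels, antibody phrases, generic biomedical words), and a separate
   pass extracts database identifiers ("YCL057C-A" → normalized "ycl057ca")
   that generic taggers miss.

2. **Species assignment.** Species evidence is matched against a compiled
   lexicon (taxonomy names restricted to gene-bearing taxa, genus words,
   cell-line codes, strain designators, plus generated genus-initial
   abbreviations like "e. coli k-12"). Unguaranteed mentions are resolved by
   two inference strategies: a guaranteed partner in the article ("A549"
   counts only if "A549 cells" occurs) and same-sentence sub-type
   co-occurrence ("E. coli K12 (MG1655)" resolves to the MG1655 substrain
   taxon). Each gene mention then gets a tax_id through a six-indicator
   cascade: identifier → species prefix ("hZIP 2" → human) → immediately
   preceding species → nearest species before in sentence → nearest species
   after in sentence → article majority species.

3. **Species-specific ranking.** Candidate gene ids of the assigned taxon are
   collected through an exact channel (normalized mention equals a dictionary
   entity) and a partial channel (shared bag-of-words tokens). A candidate
   whose matched-term set is a strict subset of another's is removed
   (intersection filtering), and survivors are scored by a two-channel
   TF-IDF inference network

   S_E(c) = Σ_e tf(e)·ln(N/df_E(e)),  S_W(c) = Σ_w tf(w)·ln(N/df_W(w)),
   score(c) = λ·Ŝ_E + (1−λ)·Ŝ_W  (channels max-normalized, λ = 0.7),

   yielding one ranked, confidence-scored identifier list per article.

The evaluator reports micro precision/recall/F and TAP-k (threshold average
precision: average precision with a cutoff at the k-th false positive and a
terminal precision penalty).

A seeded fixture generator fabricates all inputs — gene dictionary, taxonomy
table, cell-line table, articles, gold annotations — by applying the inverse
of the rewrite rules, so every pipeline stage is testable against a known
plant log without downloading anything.

## Worked example

```bash
genelink make-fixtures --out demo --seed 5 --n-docs 3
genelink normalize --gene-info demo/gene_info.tsv --taxonomy demo/taxonomy.tsv \
    --cell-lines demo/cell_lines.tsv --plant-log demo/plants.json \
    --out demo/preds.tsv demo/articles/*.txt
genelink eval --predictions demo/preds.tsv --gold demo/gold.tsv --json
```

prints

```
{
 "precision": 1.0,
 "recall": 1.0,
 "f_measure": 1.0,
 "tap_5": 1.0,
 "tap_10": 1.0,
 "tap_20": 1.0
}
```

meaning all planted gene mentions (including enumerations, abbreviations,
identifier tokens, cell-line and substrain species cues) were recovered and
ranked without false positives. The predictions file lists per-article ranked
identifiers with confidences in (0, 1]:

```
doc_id  gene_id rank  confidence
doc0000 5045    1     1.000000
doc0000 32708   2     1.000000
doc0000 51284   3     0.817912
doc0000 855978  4     0.700000
```

Replacing `--plant-log` with nothing falls back to the built-in dictionary
tagger; on the same corpus that run scores recall 0.93 — rendered variations
like "SMADs 1, 5 and 8" are exactly what a plain dictionary tagger cannot see,
which is why the tagger is a pluggable contract.

`genelink --help` lists the other verbs (`build-lexicon`, `tag`) and the
ablation/config flags (`--disable <component>`, `--lambda`).

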
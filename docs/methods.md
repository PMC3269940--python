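# Methods

## Problem and model

Given a full-text article, the pipeline outputs a ranked list of gene
database identifiers (Entrez-style integers), one list per article. Three
error sources are handled by three serial stages: surface variation of gene
names (recognition + rewrite rules), cross-species ortholog ambiguity
(species assignment), and within-species name ambiguity (candidate ranking).
The stages communicate through character offsets on a shared sentence
segmentation, so every decision is traceable to a span.

## Gene name recognition

The tagger is a contract, not a component: any callable returning
`(text, start, end)` triples. Two implementations ship — a case-sensitive
longest-match dictionary tagger over the gene dictionary's entities, and a
plant-log tagger that replays a fixture corpus's recorded spans (a
perfect-recall stand-in used to test the downstream stages in isolation from
tagger quality). Overlapping spans are resolved longest-first.

Rewrite cascade order: parentheses → conjunctions → enumerations → number
translation → head-word stripping. Parentheticals go first so an isolated
abbreviation never confuses the conjunction logic; head words are stripped
last so "MURF 3 protein" survives enumeration intact. The conjunction rule
skips mentions that parse as a number enumeration ("SMADs 1, 5 and 8"), whose
"and" joins list items rather than names. The cascade is idempotent on its
own output (property-tested).

Number translation recognizes Roman numerals only uppercase and only I–XX,
as standalone tokens, so words like "MIX" or "Vi" are untouched; Greek
letters map to the first Latin letter of their name for all 24 letters, a
uniform extension of the conventional alpha/beta/gamma → a/b/g triple.

Distillation applies four fixed context regexes (family, figure/table
attachment, antibody, generic biomedical words) case-insensitively to the
article; a mention whose span lies inside a pattern's name group is deleted.
Deletion is per occurrence — the same string elsewhere in the article is
unaffected. Identifier extraction scans each sentence with the two
mixed-digit/letter token patterns, re-scanning the captured sentence tail so
several identifiers per sentence are found; tokens are normalized (lowercase;
whitespace, hyphen, dot, underscore removed) before lookup against locus tags
and cross-reference ids.

Sentence segmentation is rule-based (split after `.?!` + whitespace) with a
guard for single-letter genus abbreviations ("E. coli") and designator tokens
("str.", "subsp."); no external segmenter is required.

## Species lexicon and assignment

The lexicon keeps taxonomy names of ranks species / no rank / subspecies /
variants, drops any taxon with zero genes in the dictionary (it cannot be a
normalization target), lowercases everything, and extends each multi-word
name with genus-initial abbreviations. Name collisions are resolved by rank
priority (species > no rank > subspecies > variants > genus), ties by the
smaller tax_id for determinism. Genus words (first token of multi-word
scientific names) and strain-level sub-type designators (final token of names
containing "str."/"substr."/"subsp."/"var."/"pv."/"bv."; ambiguous
designators dropped with a warning) are indexed separately. Synonym sets are
compiled into escaped, longest-first alternation patterns whose acceptance
set provably equals the synonym set (tested against a membership oracle).

A matched complete species name is *guaranteed* — with one exception: a name
whose designator-stripped scientific name is a word-prefix of another entry's
(e.g. "Escherichia coli" and "Escherichia coli K-12" under the MG1655
substrain) is family-ambiguous. Such mentions keep a provisional taxon but
remain re-resolvable, which is exactly what sub-type co-occurrence needs;
truly unambiguous full names are never changed by inference.

Unguaranteed evidence resolves by two strategies: (1) guaranteed inference —
a genus word resolves to a guaranteed same-genus species mention in the
article, a bare cell-line code to a guaranteed "`<code>` cell(s)" mention;
conflicting partners leave the mention unresolved, and unresolved mentions
are excluded from the frequency profile rather than spread over candidates;
(2) co-occurrence inference — a sub-type designator occurring later in the
same sentence re-resolves a genus or family-ambiguous species mention to its
unique taxon.

False-positive filtering removes (a) surfaces on the high-FP list
(3a, t7, cat, ass, j1 by default), (b) a species word opening an
experimental-technique phrase ("yeast two hybrid"), and (c) species mentions
within 5 tokens (same sentence) of antibody-context tokens (anti-, antibody,
antibodies, polyclonal, monoclonal, igg, serum) — reagent hosts, not studied
organisms. The window size is a package choice; the filter patterns
themselves are configuration.

Assignment tries six indicators in order, first applicable wins: identifier,
prefix, previous, forward, backward, majority. The prefix indicator fires
only for a lowercase map letter followed by an uppercase letter ("hZIP 2"),
and candidate matching then uses the surface with the prefix stripped —
otherwise the mention could never match its gene record. "Previous" demands
at most one intervening token and no sentence break; forward/backward are
same-sentence nearest-first, with the species respectively before and after
the gene (the direction is defined by the worked examples of the indicator
scheme, whose prose descriptions are contradictory). Majority ties break to
the smaller tax_id. Mentions with no indicator (no species evidence at all)
are dropped and logged.

## Candidate ranking

Candidates are pooled per article and restricted to each mention's assigned
taxon. The exact channel matches the normalized mention surface against
normalized dictionary entities; the partial channel matches bag-of-words
tokens. Intersection filtering removes any candidate whose matched-term set
is a strict subset of another's (equal sets both survive; order stable); it
is equivalent to the brute-force pairwise oracle and idempotent.

Scoring: each channel sums tf·idf over its matched terms, where tf counts
occurrences among the article's post-processed mention surfaces (entity
channel) or mention-bag words (word channel), and idf = ln(N/df) over the
whole gene dictionary (N = number of gene records; df ≥ 1 by construction, no
smoothing; a term present in every record scores 0). How the two channels
combine is a genuinely open design point — the scheme here max-normalizes
each channel within the article and takes the convex combination
λ·Ŝ_E + (1−λ)·Ŝ_W with λ = 0.7 by default, favoring exact-name evidence as
the stronger signal; λ is exposed in configuration, and λ = 1 / λ = 0 recover
pure entity / pure bag-of-words inference. Ties break by raw entity score,
then gene id. The final list is rescaled so the top confidence is 1; all-zero
evidence yields an empty ranking. tf counts mention occurrences, not raw text
occurrences, so distillation and post-processing directly shape the weights.

## Evaluation

Micro-averaged P/R/F treats predictions as unranked sets pooled over
documents. TAP-k truncates each ranked list at the position of the k-th
false positive (or the list end), sums precision at each relevant hit up to
the cutoff, adds one terminal term equal to the precision at the cutoff, and
divides by (gold size + 1); scores are averaged over gold documents, with
missing documents scored as empty rankings. The cutoff policy is a pluggable
callable. Note the metric is not monotone in k per query: for gold {g} and
ranking [g, x, x, …], k = 1 gives (1 + 1/2)/2 = 0.75 but k = 2 gives
(1 + 1/3)/2 ≈ 0.667, because the terminal precision dilutes with a deeper
cutoff once no further relevant items appear. Published TAP-k tables show the
same effect. TAP-k as cited in the literature uses a database-wide score
threshold calibrated to a median of k errors per query; the per-query
k-th-error cutoff implemented here is the self-contained, deterministic
variant and is the package default, documented as a deviation.

## Synthetic corpus

The fixture generator writes the four inputs plus articles and a plant log,
seeded and byte-reproducible. Articles are assembled from sentence templates
that render dictionary entries through the inverse of the rewrite rules
(enumerations, conjunctions, Greek/Roman forms, parenthetical abbreviations,
head words, identifier tokens, species prefixes, cell-line and substrain
cues) and from decoy sentences (antibody phrases, figure labels, family
names, technique phrases, high-FP species words) that a correct pipeline must
discard. One cross-species ambiguous plant per document cycles through the
four cue styles; for majority-cued plants the generator counts the document's
expected post-inference species mentions and adds exactly enough support
sentences to make the intended taxon a strict majority, so the declared
ground truth is always self-consistent. Default scale: 20 documents, 2–4
variation plants plus one ambiguous plant and 1–2 decoys each — small enough
that the whole suite runs in seconds, large enough to exercise every rule.

What the fixtures do **not** emulate: statistical tagger noise (the plant-log
tagger has perfect recall), intra-species ambiguity at realistic dictionary
scale (dozens of genes, not millions), OCR/encoding artifacts, and discourse
phenomena beyond the two inference strategies (no anaphora). Perfect fixture
scores therefore validate the machinery, not expected performance on real
corpora, where published systems of this family score far lower.

## Known limitations

- The word channel can surface weak candidates sharing a single frequent
  token; intersection filtering removes only strict subsets, so such
  candidates may appear at the bottom of rankings (they rank strictly below
  exact-evidence candidates on the fixture corpora).
- High-FP species terms are filtered unconditionally, trading rare true
  mentions of those species for precision.
- The dictionary tagger is exact-match and case-sensitive; realistic recall
  requires plugging in a statistical tagger behind the contract.
- Genus mentions with two different guaranteed partner species in one
  article are left unresolved rather than guessed.
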
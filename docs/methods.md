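# Methods

## Problem and scope

Fusion proteins (chimeric proteins arising from two parental genes joined
by chromosomal aberration or trans-splicing, e.g. BCR-ABL1) are written in
the literature in many surface dialects: separator variants (`BCR-ABL`,
`BCR/ABL`, `BCR:ABL`, en/em-dash renderings), case variants (`bcr-abl`,
`Bcr-Abl`), and historical aliases (`EWS/FLI-1` for EWS-FLI1, `TEL-AML1`
for ETV6-RUNX1). `fusemine` recognizes these mentions in abstracts,
normalizes them to a canonical `GENEA-GENEB` identifier, extracts
sentence-level statements linking a fusion to an interaction partner or a
disease through an action verb, and classifies documents with a
bag-of-words Naive Bayes model. The package is a self-contained
reimplementation of this dictionary-plus-rules tagging strategy with a
complete evaluation harness; it does not predict interactions from
protein structure, resolve breakpoints, or host a web service.

## Tagging model

**Tokenization.** Tokens are maximal alphanumeric runs; internal hyphens,
en/em dashes, slashes and colons joining alphanumeric runs stay inside a
single token, so `BCR-ABL-selective` and `bcr:abl` survive tokenization.
Punctuation tokens are discarded. Sentence boundaries are terminal
punctuation followed by whitespace and an uppercase letter or digit,
vetoed after a small abbreviation stop-list; sentence spans tile the
document body exactly.

**Stemming.** Porter2 (Snowball English), implemented in
`fusemine/_porter2.py` from the algorithm definition (regions R1/R2,
steps 0–5, exception tables). Tokens containing separator characters are
candidate fusion forms and are exempt (stem = case-folded surface). Note
that the genuine algorithm is not a strict fixed point on every output:
a stem that itself ends in a strippable suffix shrinks again on a second
pass (`kinase → kinas → kina`). This is inherent to the suffix rules;
the test suite freezes the known cases so behaviour cannot drift
silently.

**Token categories.** Every token receives exactly one of four
categories with precedence Literal > Function > Biological >
Miscellaneous: Literal for stopwords (packaged fixed list, for
determinism across environments); Function for action-verb variants (by
surface or stem) and evaluative adjectives; Biological for domain
adjectives, gene symbols, fusion aliases and gene-pair separator forms;
Miscellaneous otherwise. The precedence and the packaged adjective lists
are chosen so the canonical worked example (the imatinib sentence)
reproduces exactly; in that convention Biological tokens include domain
adjectives while bare nouns like "kinase" fall to Miscellaneous.
Disease terms deliberately do not enter the Biological category, again
following the worked example ("leukemia" is Miscellaneous).

**Fusion mention detection.** A separator-joined token is emitted as a
fusion mention by either of two routes: (a) its first two parts resolve
case-insensitively to gene symbols *and* a fusion keyword ("fusion",
"fusion protein", "gene fusion", "chimeric" ...) occurs within a
5-token window in the same sentence (window configurable); or (b) the
whole form is a known fusion alias, which requires no keyword. Trailing
non-gene parts (`BCR-ABL-selective`) are tolerated: the mention records
the full surface while gene extraction uses the first two parts. Purely
numeric pairs (year ranges `2013-2017`) and one-sided forms
(`SH2-containing`) never match. Normalization case-folds, maps every
separator to a hyphen, and resolves the whole form and its parts through
the alias tables; it is idempotent, and every case/separator variant of
a fusion maps to one identifier.

**Relation extraction.** Interactions are undirected same-sentence
co-occurrence tuples, not semantic roles: for each (fusion mention,
partner gene token) pair in a sentence that contains at least one
action-verb token, one tuple (fusion, partner, action lemma) is emitted.
The action lemma is the action token nearest to the token interval
spanned by the pair — tokens lying between the two entities win, ties go
to the earlier token — so "BCR-JAK2 induces STAT5 activation" yields
`induce`, not `activate`, and a single verb distributes over coordinated
fusion lists ("... bind NPM-ALK and ATIC-ALK" yields two tuples).
Partners never equal a component gene of any fusion in the sentence.
Disease links are the analogous (fusion, disease term, action) triples;
disease dictionary matches are greedy-longest ("chronic myeloid
leukemia" beats "leukemia") and map to MeSH identifiers by table lookup.
A fusion–disease co-occurrence with no action verb in the sentence is
not emitted, since every link carries an action lemma by contract.

## Lexicons

The supplementary dictionaries of the original resource are not public;
the packaged TSVs are recreations seeded from every token printed in the
source material: fusion keywords, the action-verb corpus with its
morphological expansions (`activate → activates, activated, activating,
activation, activator`), the fusion alias families (BCR-ABL, EWS-FLI1,
TMPRSS2-ERG incl. the variant spelling TMRPSS2-ERG, NPM-ALK, ATIC-ALK,
BCR-JAK2, ...), a ~70-symbol gene list sufficient for the worked
examples and the synthetic corpus, and common hematological/oncological
disease terms with MeSH ids. The TSV format (`canonical<TAB>v1|v2|...`)
is documented so users can swap in full HGNC tables via
`load_lexicon(paths)` or the CLI's `--lexicon key=path`. Variant lookup
is case-insensitive; a variant mapping to two canonicals within one kind
is a hard load-time error. `expand_morphology` applies the suffix family
{-s, -d/-ed, -ing, -ion/-ation, -or/-er} with e-drop; it overgenerates
(e.g. `bindion`), which is harmless for dictionary matching and keeps
the rule set simple.

## Features and classifier

Documents are sentence-split, entity-blanked (recognized gene / fusion /
disease / action spans replaced by GENE / FUSION / DISEASE / ACTION
placeholders so features generalize across specific entities), stemmed,
and decomposed into contiguous n-grams (default 1–2, up to 4 by
configuration). Each gram s in document a is weighted by the
frequency-score threshold

    T(s, a) = FS(s, a) · log10(τ / σ(s))

with FS the in-document gram frequency, τ the corpus size and σ(s) the
gram's document frequency — a TF-IDF-style weight under which a gram
present in every document scores exactly zero. The global vocabulary is
the top V grams (default V = 1000) ranked by max-over-documents T with
lexicographic tie-breaks, optionally filtered at a minimum score; each
document becomes a fixed-length vector of its own T values over that
vocabulary, rescaled to unit sum (all-zero rows stay zero). The
"similar-length vector" construction (fixed dimension + unit-sum
rescale) is a design choice: the source describes rescaling but not the
construction.

Classification is multinomial Naive Bayes with additive smoothing
(default α = 1) in log space; exact posterior ties resolve to the
negative class for determinism. Whether the original applied the
threshold per document or corpus-wide is unstated; here vocabulary
selection is corpus-wide with per-document values. An abstract
convex-optimization restatement of training printed alongside the
method is internally inconsistent (its symbols have no operational
definition) and is deliberately not implemented; training is the
standard NB fit.

## Evaluation harness

Precision TP/(TP+FP), recall TP/(TP+FN), F = 2PR/(P+R), accuracy;
zero-denominator cases are reported as *undefined* (None), never
coerced. The separate `token_agreement_score` reproduces the worked
example convention in which gold (n, y, n, a) vs predicted (n, n, n, a)
scores 0.75 — positional agreement over the {n, y, a} alphabet, which is
not derivable from the confusion-matrix formulas and is therefore kept
as its own operation. Cross-validation is stratified k-fold (default
k = 10) with a seeded partition; the 40/60 split and the literal
"ten sub-samples, five test / five train" protocol described alongside
it are both available (`split_40_60`, `split_halves`) since the source
describes both without reconciling them. ROC points sweep the decision
threshold over all distinct posteriors plus {0, 1}; AUC is the
trapezoid rule, equal to pairwise concordance.

## Synthetic corpus

The generator emulates exactly the surface phenomena the taggers are
sensitive to. Defaults: 200 documents, half positive; dialect mix
dominated by upper-case hyphen forms with slash/colon/en-dash and
lower/title-case minorities; P(interaction sentence) = 0.8 with
coordinated two-fusion statements at 0.25 among alias-type fusions;
P(disease sentence) = 0.4; distractors per document ~ Poisson(1.5)
drawn from hyphenated-adjective, year-range and chemical-name families;
alias-type vs random-gene-pair fusions at 0.5. Pair-type fusions are
always planted next to a fusion keyword (they are only detectable
through the keyword route); alias-type fusions may appear bare.
Templates are data (`data/templates.json`), so new distractor families
need no code change. All randomness flows from one named
`random.Random(seed)`; identical configurations are byte-identical on
disk.

What passing recovery tests show — and what they do not: the corpus
exercises dialect variation, keyword windows, coordination, distractor
rejection and label recovery, but its sentences are templated; real
abstracts add unseen gene symbols, nested entities, anaphora and
negation, none of which the generator produces. Recovery at 1.0 on the
synthetic conditions therefore validates the machinery, not real-world
recall, which in the original resource-scale setting was reported far
below 1.

## Numerical and degenerate-input choices

Empty corpora yield empty statistics (τ = 0) and empty matrices; empty
documents yield zero sentences. Overlapping entity spans resolve
outermost-wins (longest, then leftmost) in both blanking and HTML
highlighting, with inner spans dropped and logged. Character offsets are
0-based, half-open, in Unicode code points on the raw body; MEDLINE
Latin-1 inputs are transcoded to UTF-8 on read. Annotation JSON has a
stable schema and key order, so read→write→read is a byte fixed point.
Network export collapses duplicate evidence onto one edge carrying
sorted action lemmas and doc ids; node and edge order are sorted for
determinism.

## Problem sizes

The default study conditions (200 synthetic documents, vocabulary 1000,
10 folds) are the package's chosen defaults throughout the test suite
and the reproduction script; the full suite and the script each complete
in seconds on one CPU at these sizes.

## Known limitations

Abstract-only processing is the default (full text is plain-text
ingestion only). Whitespace-separated "GENE GENE fusion" forms are not
detected by default (high false-positive risk; config flag planned
territory, the keyword window is the supported control). No three-gene
fusions, breakpoint/exon resolution, anaphora, negation or speculation
handling. The packaged gene list is intentionally small; recall on real
text is bounded by the symbol table supplied.
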
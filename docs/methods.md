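# Methods

This note documents the models and procedures implemented in `vivominer`, the
parameters that matter, the synthetic data the package is validated on, and
the numerical and design choices a maintainer should know about.

## The analysis in one paragraph

Curated *in vivo* assay descriptions are short (10–30 word) sentences written
by a small set of database curators in a semi-standardized style. The pipeline
(i) normalizes each description and shallow-chunks it into base noun phrases,
(ii) extracts four entity classes — genetic strains, induced (experimental)
disease models, transgenic models, phenotypes — with dictionary and rule
methods, (iii) trains a word2vec model on the chunked token streams so that
words and multi-word phrases used in similar contexts acquire nearby vectors,
(iv) represents each assay as the unit-normalized mean of its token vectors
and trains random-forest classifiers that predict the ATC class of the
approved drugs tested in the assay, and (v) links approved drugs to animal
models in a bipartite co-occurrence network.

## Preprocessing and chunking

*Normalization.* Latin species binomials are canonicalized to "rat"/"mouse";
a 20-entry table expands administration-route and regimen acronyms
("sc" → "subcutaneous", "qd" → "daily"); "sc" and "qd" are ubiquitous in
curator text and the full table is standard pharmacology usage, documented in
the data file. Every replacement is recorded in an offset map so spans in
normalized coordinates project back onto the raw text (replaced segments snap
to segment boundaries).

*Tokenization.* Tokens keep internal `/`, `.`, `,`, `'` ("mg/kg", "5.16",
"ob/ob"); hyphens always split, so the trigger keyword in "carrageenan-induced"
is its own token — this is what lets the split-on-trigger rule fire.
Possessive `'s` is detached as its own token with the `POS` tag.

*Tagging.* The POS/NER tagger is a pluggable backend behind a deterministic
contract (per-token Penn-Treebank POS plus optional protein/cell-line flags).
The bundled `RuleTagger` — closed-class lexicon, number detection, verbal /
adjectival / adverbial suffix rules, a mid-sentence capitalization heuristic,
and a small protein/cell-line gazetteer — is the default backend; an external
biomedical tagger can be substituted without touching the rest of the
pipeline. Custom tags overlay the POS layer: 24 experimental-procedure
triggers (`IND`; "induced", "infected", "xenografted", "fed", "operated",
"treated"/"pretreated", "stimulated", plus documented extrapolations in the
same families — injection, challenge, surgery, grafting, diet,
sensitization), `IND_B` for triggers that legitimately begin a phrase,
transgenesis keywords (`TRANSG`/`EXPR`/`KNOCK`), species words (`SP`), and the
tagger's `PROT`/`CELL` flags, which custom tags never overwrite.

*Chunking.* Base noun phrases are maximal non-overlapping matches of
`NP: {<JJ|NN.*>*<PROT|CELL|NN.*>+}` over the effective tag sequence (custom
tag when present, else POS). Determiners and numbers can only enter a phrase
through a `PROT`/`CELL` flag ("Concanavalin **A**"), and trigger-tagged tokens
act as separators, so "concanavalin A induced hepatic cell necrosis" chunks
into the stimulus "concanavalin A" and the outcome "hepatic cell necrosis".
The matcher is a greedy leftmost-longest regex scan; the test suite proves it
equivalent to brute-force enumeration of the grammar on every tag sequence of
length ≤ 8 over a representative 4-symbol alphabet, with a hypothesis property
test extending to longer sequences.

## Entity recognition

*Strains.* Dictionaries are compiled from MGD/RGD-style listings (name, type,
synonyms, substrains). Substrain designations append laboratory codes after a
slash; a substrain folds onto its parent only when the prefix resolves to a
listed inbred basic strain, which protects hybrid names like `B6D2F1`.
Matching uses keys stripped to lower-case alphanumerics, indexed with and
without the species word, so "Sprague-Dawley rat", "sprague dawley" and
"SD rat" all resolve; unlisted substrains of known basic strains resolve
through parent parsing, and sex/age modifier words may interleave inside a
span ("C56BL/6J male mouse" → C57BL). A key claimed by two entries aborts the
dictionary build. The repo bundles a small synthetic mini-listing (24 strains)
for tests and the corpus generator; full-scale runs must supply real listings.

*Phenotypes.* Term labels and exact synonyms of OBO ontologies (symptom,
phenotype, trait, clinical-measurement, disease and behavior vocabularies) are
indexed by the same alphanumeric keys; terms under 3 characters and a small
blocklist of generic English words ("activity", "process", …) are excluded.
Narrow/broad/related synonyms are off by default (`synonym_scope="all"` widens)
because dictionary NER should favor precision. Matching is longest-match on
token boundaries; candidates headed by "level(s)"/"production" adjacent to a
protein-flagged token are suppressed — molecular biomarkers ("IL4 production")
are not phenotypes. The biomarker rule is inherently example-driven and
ships as a configurable suffix blocklist.

*Induced and transgenic models.* Eight extraction patterns operate on the
chunked sequence (symbols: noun phrase, foreign word, possessive, trigger
classes). The core trigger-suffix pattern `{<NP|FW|POS>*<IND>+}` captures
"Freund's complete adjuvant induced" and "Staphylococcus aureus infected"; the
diet / infection / surgical / xenograft patterns are the same machinery pinned
to keyword families; a head-noun rule captures assay-name phrases of ≥ 2
tokens ending in test/assay/model/task/maze/paradigm ("glucose tolerance
test"); a leading-trigger rule handles phrase-initial triggers ("fasted rat");
and the transgenic pattern fires on `TRANSG`/`EXPR`/`KNOCK` ("APOA1
transgenic"). The suffix pattern requires at least one noun-phrase element so
a bare verb ("effect was induced slowly") is not a model mention; overlaps
within a class resolve leftmost-longest. Model names are not synonym-
normalized at extraction time; consolidation happens in the network step.

*Evaluation.* Precision/recall/F1 per class and micro-averaged, under exact
(identical class and character span) and partial (same class, any character
overlap, each gold mention creditable once) matching. Partial matching is this
package's definition of the "relaxed" criterion. Inter-annotator agreement is
the same computation applied to two annotation sets; there is no separate code
path. Gold annotations are read from BRAT standoff `.txt`/`.ann` pairs.

## Embeddings

`Word2VecEmbedder` implements CBOW and skip-gram with negative sampling in
numpy: dynamic context windows sampled uniformly in [1, window], 5 negatives
from the unigram distribution raised to 3/4, linear learning-rate decay from
0.025 to 1e-4, single-threaded and bit-reproducible from the seed. Defaults
follow the corpus-scale settings — 250 dimensions, window 5, minimum token
frequency 30, CBOW, 5 epochs (architecture and epoch count are free
parameters; CBOW with 5 epochs is the common tool default and is this
package's default). **For the desk-scale synthetic corpora (~100 documents, ~90-token
vocabularies) the package uses 50 dimensions, min_count 5, 30 epochs and
skip-gram** (`vivominer.workflow.SMALL_CORPUS_EMBED`): skip-gram's per-word
updates handle small corpora and rare tokens better than CBOW's context
averaging, which underfits at this scale. Both architectures must and do pass
the planted-synonym recovery test.

Assay vectors are the L2-normalized mean of in-vocabulary token vectors; an
all-out-of-vocabulary token list yields a flagged zero vector (the degenerate
contract) and such assays are excluded from classification. Similarity
heatmap matrices are raw cosines with row-wise Z-scoring; rows and columns are
clustered with average linkage on Euclidean distances of the Z-scored matrix.
Whether the column dendrogram should see raw or Z-scored values is ambiguous,
so both are computed (`col_linkage`, `col_linkage_raw`). 2-D maps reduce to 20
principal components first (or the matrix rank if lower), then t-SNE with
default perplexity 30, capped at (n−1)/3 for small inputs; the seed and
effective parameters are recorded in the output metadata. Exact cosine values are
not reproducible across corpus versions and training runs (stochastic
training); similarity tables are therefore validated as rank-order properties.

## Classification

Assays are labeled through approved drugs (development phase 4): the level-2
prefixes (first 3 characters) of their ATC codes map to problem classes and an
assay is kept only when exactly one class results. For binary problems the
catch-all class never claims an assay that also maps to an explicit class —
"involves any cidal drug" semantics — while multiclass problems use strict
unambiguity (a drug set spanning N03 and A10 is excluded as ambiguous).
The cidal code set beyond the four printed prefixes is an editable config
defaulting to {L01, J01, J02, J04, J05, P01, P02, P03}; indomethacin's
multi-code membership (C01/M01/M02/S01) is handled by the class→code-set map
itself, not by drug-specific rules.

Cross-validation is 10-fold under two protocols: random assay split, and
random document split in which all assays curated from one publication share a
fold. Same-document assays are frequently near-duplicates differing only in
dose or timing, so the assay split leaks and overestimates accuracy; the
document split is the honest generalization estimate, and the synthetic
corpus reproduces this leakage direction by construction. The classifier is a
200-tree random forest with balanced class weights (100 trees in desk-scale
runs; accuracy is insensitive to this within the reported precision). Both
pooled-prediction accuracy and mean-over-folds accuracy are reported, since
either convention is defensible. The out-of-bag estimate comes from a single
fit on the full labeled set (the convention chosen here; it is labeled as
such in the report). Embeddings are trained once on the full corpus before
cross-validation — the canonical protocol for this analysis; note this
shares unlabeled text (not labels) across folds.

Per-class phrase enrichment uses the one-sided Fisher exact test on the 2×2
presence/absence table, computed through the vectorized hypergeometric
survival function; an empty table has p = 1 by convention. Ranking is
ascending p, ties broken by in-class frequency then lexicographically. The
test suite proves equality with exact integer-binomial tail enumeration on all
316,251 tables with grand total ≤ 50 and anchors both routes to
`scipy.stats.fisher_exact` on a subsample.

## Drug–animal-model network

For assays testing approved drugs, each drug is connected to every animal
model (strain, induced, transgenic) mentioned in ≥ `min_assays` = 5 of its
assays, weighted by the distinct-assay count (distinct assays, not
assay–compound pairs, consistent with "tested in at least five assays").
General-purpose strains — outbred stocks screened indiscriminately across
indications (Wistar, Sprague Dawley, Swiss, ICR/CD-1, NMRI, CF-1, Long Evans,
Holtzman) — are excluded via an editable list so only disease-linked models
remain; synonymous experimental-model names are consolidated via an editable
merge map ("maximum electric shock" → "maximal electroshock", "hotplate" →
"hot plate"). Isolated nodes are dropped; bipartiteness is asserted
structurally on every build. Raising the threshold is monotone (never adds
nodes or edges).

## Synthetic data: what it emulates and what it does not

The generator emits curator-style sentences from a small set of templates
("<effect> of <stimulus>-induced <phenotype> in <strain> <species> at <dose>
mg/kg, <route> after <time> hrs" and variants), with gold entity spans for
every inserted entity. Study-condition defaults: 120 documents, 3–8 assays per
document (same-document assays share class, template and entities, differing
in dose/timing — the near-duplicate structure that motivates document
splits); five therapeutic-area classes with 5 drugs, 5 stimuli, 5 phenotypes
and realistic strain tables each, seeded from entity names a pharmacologist
would recognize; noise rates of 0.3 for route acronyms, 0.2 for nonstandard
strain surfaces ("ob-ob mouse" with gold normalization "ob/ob"), 0.3 for
planted phenotype-synonym swaps; 4% transgenic documents, reflecting the
rarity of transgenic-model assays in curated corpora. Dose/time numerals are
log-uniform in plausible ranges and never inside gold spans.
`class_vocab_overlap` interpolates between fully class-specific vocabularies
(0, linearly separable) and one shared vocabulary (1, class signal only in the
drug identity, hence chance-level text classification) — the two calibration
end-points of the classifier tests.

What the generator does **not** emulate: the long-tail vocabulary and
morphological variety of real curator text, misspellings, multi-sentence
descriptions, assays with multiple models, and annotation disagreement.
Passing the closure tests therefore demonstrates internal consistency of the
pipeline (extraction exactly inverts generation at zero noise; classifiers
recover planted separability and collapse to chance under planted nulls), not
the F-scores achievable on real curated corpora — those are covered by the
supplementary-dependent benchmark tests, which require the original datasets.

## Problem sizes and numerical choices

Desk-scale runs (test suite and `scripts/acceptance.py`) use corpora of 120
documents (≈ 650–700 assays), 50-dimensional embeddings, 100-tree forests, and
three seeds for stochastic claims; these sizes give stable results while
keeping a full run in minutes on one CPU. Degenerate inputs have explicit
contracts: empty assay lists give all-zero statistics; all-OOV assay vectors
are flagged and excluded; single-class classification inputs and
fewer-documents-than-folds splits raise; folds whose training part lacks a
class are skipped with a warning and recorded in the report. Ties are broken
deterministically everywhere (lexicographic in frequency rankings and
enrichment tables; stable sorts in similarity rankings), and every stochastic
component (generator, embedding training, fold shuffling, forests, t-SNE)
takes an explicit seed.

## Known limitations

- The bundled rule tagger is intentionally simple; precision of the rule-based
  model extraction on real corpora depends on the tagging backend, and the
  extraction patterns are tuned to the curator-sentence register — they would
  need re-evaluation on text from other sources.
- Except for strains, entity names are not synonym-normalized at extraction
  time; downstream frequency tables can split counts across surface variants
  (the network step's merge map is the manual remedy).
- Drug–model edges encode co-occurrence, not efficacy: an approved drug tested
  in a model may have been inactive in it.
- The embedding-before-split protocol shares unlabeled text across CV folds; a
  strict per-fold retraining mode would be the leakage-free alternative and is
  deliberately not the default, to keep the canonical protocol
  (`strict_classification_accuracy` provides it).
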
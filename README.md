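# vivominer

Text mining of curator-written *in vivo* bioassay descriptions.

Public preclinical screening resources summarize each whole-animal drug
efficacy experiment in one short curated sentence, e.g.

> *Inhibition of carrageenan-induced paw oedema in Sprague-Dawley rat at
> 5.16 mg/kg, sc after 3 hrs*

Despite being free text, these summaries are semi-standardized and information
dense: they name the genetic strain, the experimental stimulus that induces the
disease phenotype, the phenotypic readout, and the dosing details. `vivominer`
is a library (plus a thin CLI) for turning a corpus of such descriptions into
structured, analyzable data. It is aimed at cheminformaticians and
translational-research groups working with ChEMBL-style *in vivo* assay tables.

## What it does

1. **Preprocessing** (`vivominer.preprocess`) — species-name canonicalization
   and expansion of administration acronyms (*sc* → *subcutaneous*, *qd* →
   *daily*) with an offset map for annotation round-tripping; deterministic
   POS tagging behind a pluggable backend contract; shallow chunking with the
   base-noun-phrase grammar `NP: {<JJ|NN.*>*<PROT|CELL|NN.*>+}`, split at
   experimental-procedure trigger keywords so stimulus and outcome become
   separate phrases.
2. **Lexicons** (`vivominer.lexicon`) — mouse/rat strain dictionaries compiled
   from MGD/RGD-style listings with substrain→parent folding
   (`AKR/NCr` → `AKR`) and punctuation-insensitive alphanumeric match keys
   (`ob-ob mouse` ≡ `ob/ob mouse`); phenotype dictionaries from OBO ontologies
   (labels + exact synonyms, obsolete terms dropped).
3. **Entity recognition** (`vivominer.ner`) — dictionary matching for strains
   and phenotypes, rule patterns over the chunked sentence for induced and
   transgenic disease models (`{<NP|FW|POS>*<IND>+}` captures *"Freund's
   complete adjuvant induced"*); exact/partial precision–recall–F1 evaluation
   against gold BRAT standoff annotations.
4. **Semantic space** (`vivominer.embed`) — word2vec embeddings (CBOW or
   skip-gram with negative sampling, numpy implementation; defaults d = 250,
   window = 5, min_count = 30) trained on the chunked token streams; cosine
   similarity and analogy queries (`a − b + c`); unit-norm mean assay vectors;
   row-Z-scored cosine heatmap matrices with average-linkage/Euclidean
   dendrograms; PCA-to-20 followed by t-SNE for 2-D maps.
5. **Classification** (`vivominer.classify`) — assays labeled by the ATC
   level-2 codes of the approved drugs they test (four built-in problems:
   cidal vs non-cidal, nervous-system binary, five-class therapeutic areas,
   nervous-system subclasses); 10-fold cross-validated random forests
   (200 trees, balanced class weights) under both random **assay** splits and
   leakage-free **document** splits; one-sided Fisher exact phrase enrichment
   per class.
6. **Network** (`vivominer.network`) — the bipartite drug–animal-model graph:
   an edge connects a drug and a model mentioned together in ≥ 5 assays;
   general-purpose outbred stocks excluded; GraphML/GML/TSV export.
7. **Synthetic corpora** (`vivominer.synth`) — a generator that emulates the
   curator-sentence format with gold entity spans, near-duplicate
   same-document assays, drug/ATC labels, plantable synonym pairs and a
   tunable class-vocabulary overlap, so the whole pipeline is testable without
   any downloads.

## Worked example

```python
from vivominer.lexicon import PhenotypeDictionary, compile_strain_dictionary, load_strain_listing
from vivominer.ner import NERPipeline

pipeline = NERPipeline(
    strain_dictionaries=[compile_strain_dictionary(load_strain_listing())],
    phenotype_dictionary=PhenotypeDictionary.from_terms(["paw oedema", "arthritis"]),
)
text = ("Inhibition of carrageenan-induced paw oedema in Sprague-Dawley rat "
        "at 5.16 mg/kg, sc after 3 hrs")
for m in pipeline.mentions(text):
    print(m.entity_class, repr(m.surface), "->", repr(m.normalized))
print(pipeline.embedding_tokens(text, species="rat"))
```

prints

```
experimental_model 'carrageenan-induced' -> 'carrageenan induced'
phenotype 'paw oedema' -> 'paw oedema'
genetic_strain 'Sprague-Dawley rat' -> 'Sprague Dawley'
['inhibition', 'carrageenan_induced', 'paw_oedema', 'sprague_dawley_rat', 'mg/kg', 'subcutaneous', 'hrs']
```

The rule pattern recognized the induced disease model and split it from the
phenotype; the strain dictionary normalized the hyphenated surface form via
its alphanumeric key; the embedding token stream carries one underscore-joined
token per concept — these streams are what `vivominer.embed.Word2VecEmbedder`
(a scikit-learn style transformer: `fit` on token lists, `transform` to unit
assay vectors) trains on, and what the random-forest classifiers consume.

An end-to-end run on a generated corpus:

```bash
vivominer simulate --seed 7 --out workdir/        # tables + gold BRAT + ledger
vivominer ner --assays workdir/assays.tsv --out workdir/mentions.tsv ...
vivominer network --mentions workdir/mentions.tsv --assays workdir/assays.tsv \
    --compounds workdir/compounds.tsv --links workdir/links.tsv --out workdir/net.graphml
```

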
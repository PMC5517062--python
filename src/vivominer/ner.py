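"""Named entity recognition for assay descriptions.

Four entity classes are recognized:

* ``genetic_strain`` — dictionary matching against the compiled mouse/rat
  strain dictionaries; longest match on alphanumeric keys, tolerating
  interleaved sex/age modifiers ("C56BL/6J male mouse" resolves to C57BL);
* ``phenotype`` — dictionary matching against the ontology-derived phenotype
  dictionary (longest non-overlapping match on token boundaries);
* ``experimental_model`` — rule patterns over the chunked sentence, e.g. the
  trigger-suffix pattern ``{<NP|FW|POS>*<IND>+}`` that captures "Freund's
  complete adjuvant induced" or "Staphylococcus aureus infected", plus
  head-noun assay phrases ("glucose tolerance test");
* ``transgenic_model`` — the analogous patterns over TRANSG/EXPR/KNOCK
  triggers ("APOA1 transgenic").

Evaluation against gold BRAT standoff annotations reports precision/recall/F1
per class under exact (identical class and span) and partial (same class, any
character overlap) matching — the same machinery doubles as the strict/relaxed
inter-annotator agreement computation when fed two human annotation sets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .lexicon import (
    PhenotypeDictionary,
    StrainDictionary,
    match_key,
    parse_substrain_parent,
)
from .preprocess import (
    DEFAULT_KEYWORD_CONFIG,
    NounPhrase,
    TaggedSentence,
    TaggerBackend,
    apply_custom_tags,
    extract_noun_phrases,
    normalize_description,
    tag_tokens,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ENTITY_CLASSES",
    "EntityMention",
    "AnnotatedDescription",
    "NERMetrics",
    "ExtractionPattern",
    "DEFAULT_PATTERNS",
    "MODIFIER_WORDS",
    "match_dictionary_entities",
    "extract_rule_entities",
    "NERPipeline",
    "annotate_corpus",
    "read_brat",
    "write_brat",
    "evaluate_ner",
    "mention_frequencies",
]

ENTITY_CLASSES = ("genetic_strain", "experimental_model", "transgenic_model", "phenotype")

#: sex/age modifier words tolerated inside strain mention spans
MODIFIER_WORDS = frozenset({"male", "female", "adult", "young", "aged"})


@dataclass(frozen=True)
class EntityMention:
    assay_id: str
    entity_class: str
    surface: str
    normalized: str
    char_start: int
    char_end: int

    def overlaps(self, other: "EntityMention") -> bool:
        return self.char_start < other.char_end and other.char_start < self.char_end


@dataclass
class AnnotatedDescription:
    doc_id: str
    text: str
    mentions: list[EntityMention] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Dictionary-based matching
# ---------------------------------------------------------------------------


def match_dictionary_entities(
    sentence: TaggedSentence,
    dictionary: StrainDictionary | PhenotypeDictionary,
    entity_class: str,
    assay_id: str = "",
    max_span: int = 6,
    biomarker_suffixes: frozenset[str] = frozenset({"level", "levels", "production"}),
) -> list[EntityMention]:
    """Longest-match, non-overlapping dictionary mentions.

    For strain dictionaries the candidate span may interleave sex/age modifier
    words which do not contribute to the match key. Phenotype candidates whose
    head word is a biomarker suffix ("levels", "production") directly preceded
    by a protein-flagged token are suppressed (molecular readouts such as
    "IL4 production" are not phenotypes).
    """
    is_strain = isinstance(dictionary, StrainDictionary)
    toks = sentence.tokens
    mentions: list[EntityMention] = []
    i = 0
    while i < len(toks):
        if is_strain and toks[i].text.lower() in MODIFIER_WORDS:
            i += 1
            continue
        best_end = None
        best_value = None
        # two running keys: as-written, and with an unlisted substrain's first
        # token replaced by its parsed parent ("C56BL/6J male mouse" must still
        # extend through "mouse")
        key = ""
        alt_key = None
        if is_strain and "/" in toks[i].text:
            parent = parse_substrain_parent(
                toks[i].text, getattr(dictionary, "key_index", {}).keys()
            )
            if parent != toks[i].text:
                alt_key = match_key(parent)
        j = i
        n_content = 0
        while j < len(toks) and n_content < max_span:
            t = toks[j]
            if is_strain and t.text.lower() in MODIFIER_WORDS and j > i:
                j += 1
                continue
            part = match_key(t.text)
            key += part
            if alt_key is not None and n_content > 0:
                alt_key += part
            n_content += 1
            hit = _dict_lookup(dictionary, key, t.text if n_content == 1 else None)
            if hit is None and alt_key is not None:
                hit = _dict_lookup(dictionary, alt_key, None)
            if hit is not None:
                best_end, best_value = j + 1, hit
            j += 1
        if best_end is not None:
            span_first = toks[i]
            if not (
                entity_class == "phenotype"
                and toks[best_end - 1].text.lower() in biomarker_suffixes
                and (
                    span_first.custom == "PROT"
                    or (i > 0 and toks[i - 1].custom == "PROT")
                )
            ):
                span_toks = toks[i:best_end]
                mentions.append(
                    EntityMention(
                        assay_id=assay_id,
                        entity_class=entity_class,
                        surface=sentence.text[span_toks[0].char_start: span_toks[-1].char_end],
                        normalized=best_value,
                        char_start=span_toks[0].char_start,
                        char_end=span_toks[-1].char_end,
                    )
                )
            i = best_end
        else:
            i += 1
    return mentions


def _dict_lookup(dictionary, key: str, single_token_text: str | None):
    if isinstance(dictionary, StrainDictionary):
        entry = dictionary.key_index.get(key)
        if entry is None and single_token_text and "/" in single_token_text:
            entry = dictionary.lookup(single_token_text)
        return entry.preferred_name if entry is not None else None
    return dictionary.key_index.get(key)


# ---------------------------------------------------------------------------
# Rule-based extraction (experimental / transgenic models)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtractionPattern:
    """One extraction rule over the chunked token sequence.

    ``regex`` runs over a symbol string with one char per chunk element:
    N = noun phrase, F = foreign word, S = possessive ending, I = IND trigger,
    B = IND_B trigger, T/E/K = TRANSG/EXPR/KNOCK triggers, X = anything else.
    ``trigger_words`` optionally restricts which trigger keyword may anchor the
    match (this is how the diet/infection/surgical/xenograft specializations of
    the trigger-suffix rule are expressed).
    """

    name: str
    regex: str
    entity_class: str
    trigger_words: frozenset[str] | None = None

    def compiled(self) -> re.Pattern:
        return re.compile(self.regex)


#: The eight extraction patterns. The trigger-suffix pattern is the printed
#: one; the specializations pin it to specific procedure families, and the
#: head-noun rule is applied inside noun phrases (see extract_rule_entities).
DEFAULT_PATTERNS: tuple[ExtractionPattern, ...] = (
    ExtractionPattern("diet", r"[NFS]+I+", "experimental_model", frozenset({"fed"})),
    ExtractionPattern("infection", r"[NFS]+I+", "experimental_model", frozenset({"infected"})),
    ExtractionPattern("surgical", r"[NFS]*I+", "experimental_model", frozenset({"operated", "ligated"})),
    ExtractionPattern(
        "xenograft", r"[NFS]+I+", "experimental_model",
        frozenset({"xenografted", "implanted", "inoculated"}),
    ),
    ExtractionPattern("trigger_suffix", r"[NFS]+I+", "experimental_model"),
    ExtractionPattern("leading_trigger", r"B+[NF]*", "experimental_model"),
    ExtractionPattern("transgenic", r"[NFS]*[TEK]+", "transgenic_model"),
    # head_noun is structural (an NP ending in an assay head noun); kept in the
    # set so it is configurable alongside the others
    ExtractionPattern("head_noun", r"", "experimental_model",
                      frozenset({"test", "assay", "model", "task", "maze", "paradigm"})),
)

_TRIGGER_SYMBOLS = {"IND": "I", "IND_B": "B", "TRANSG": "T", "EXPR": "E", "KNOCK": "K"}


def _chunk_elements(
    sentence: TaggedSentence, phrases: Sequence[NounPhrase]
) -> list[tuple[str, int, int, str]]:
    """(symbol, tok_start, tok_end, trigger_word) elements of the chunked sentence."""
    starts = {id(p.tokens[0]): p for p in phrases}
    elements: list[tuple[str, int, int, str]] = []
    i = 0
    toks = sentence.tokens
    while i < len(toks):
        p = starts.get(id(toks[i]))
        if p is not None:
            elements.append(("N", i, i + len(p.tokens), ""))
            i += len(p.tokens)
            continue
        t = toks[i]
        sym = _TRIGGER_SYMBOLS.get(t.custom or "", None)
        if sym is None:
            if t.pos == "FW":
                sym = "F"
            elif t.pos == "POS":
                sym = "S"
            else:
                sym = "X"
        elements.append((sym, i, i + 1, t.text.lower() if sym in "IBTEK" else ""))
        i += 1
    return elements


def extract_rule_entities(
    sentence: TaggedSentence,
    phrases: Sequence[NounPhrase] | None = None,
    patterns: Sequence[ExtractionPattern] = DEFAULT_PATTERNS,
    assay_id: str = "",
) -> list[EntityMention]:
    """Pattern matches over the chunked sentence.

    Patterns are tried in order; matches are resolved leftmost-longest and
    non-overlapping per entity class. Pure-trigger matches (no noun-phrase
    material) are kept only for surgical/leading-trigger/transgenic rules,
    where the bare keyword is informative.
    """
    if phrases is None:
        phrases = extract_noun_phrases(sentence)
    elements = _chunk_elements(sentence, phrases)
    symbols = "".join(e[0] for e in elements)
    toks = sentence.tokens

    candidates: list[tuple[int, int, ExtractionPattern]] = []  # element spans
    for pat in patterns:
        if pat.name == "head_noun":
            continue
        rx = pat.compiled()
        for m in rx.finditer(symbols):
            if m.start() == m.end():
                continue
            if pat.trigger_words is not None:
                trig = {
                    elements[k][3]
                    for k in range(m.start(), m.end())
                    if elements[k][0] in "IBTEK"
                }
                if not trig & pat.trigger_words:
                    continue
            candidates.append((m.start(), m.end(), pat))

    # head-noun assay phrases: NPs of >=2 tokens whose last token is a head noun
    head_pat = next((p for p in patterns if p.name == "head_noun"), None)
    if head_pat is not None:
        for k, (sym, ts, te, _) in enumerate(elements):
            if sym == "N" and te - ts >= 2 and toks[te - 1].text.lower() in (head_pat.trigger_words or ()):
                candidates.append((k, k + 1, head_pat))

    # leftmost-longest, non-overlapping within each entity class
    mentions: list[EntityMention] = []
    for cls in ("experimental_model", "transgenic_model"):
        spans = sorted(
            ((s, e, p) for s, e, p in candidates if p.entity_class == cls),
            key=lambda c: (c[0], -(c[1] - c[0])),
        )
        taken_until = -1
        for s, e, pat in spans:
            if s <= taken_until:
                continue
            ts, te = elements[s][1], elements[e - 1][2]
            surface = sentence.text[toks[ts].char_start: toks[te - 1].char_end]
            mentions.append(
                EntityMention(
                    assay_id=assay_id,
                    entity_class=cls,
                    surface=surface,
                    normalized=" ".join(t.text for t in toks[ts:te]).lower(),
                    char_start=toks[ts].char_start,
                    char_end=toks[te - 1].char_end,
                )
            )
            taken_until = e - 1
    return mentions


# ---------------------------------------------------------------------------
# Corpus annotation pipeline
# ---------------------------------------------------------------------------


class NERPipeline:
    """Description -> mentions, wiring normalization, tagging, chunking and the
    dictionary/rule extractors together."""

    def __init__(
        self,
        strain_dictionaries: Sequence[StrainDictionary] = (),
        phenotype_dictionary: PhenotypeDictionary | None = None,
        tagger: TaggerBackend | None = None,
        keyword_config: dict[str, frozenset[str]] | None = None,
        patterns: Sequence[ExtractionPattern] = DEFAULT_PATTERNS,
        acronym_map: dict[str, str] | None = None,
    ):
        self.strain_dictionaries = list(strain_dictionaries)
        self.phenotype_dictionary = phenotype_dictionary
        self.tagger = tagger
        self.keyword_config = keyword_config or DEFAULT_KEYWORD_CONFIG
        self.patterns = tuple(patterns)
        self.acronym_map = acronym_map

    def process(self, description: str, assay_id: str = ""):
        """Returns (normalized_text, offset_map, sentence, phrases, mentions)."""
        normalized, offmap = normalize_description(description, self.acronym_map)
        sentence = tag_tokens(normalized, self.tagger, assay_id)
        apply_custom_tags(sentence, self.keyword_config)
        phrases = extract_noun_phrases(sentence)
        mentions: list[EntityMention] = []
        for d in self.strain_dictionaries:
            mentions.extend(
                match_dictionary_entities(sentence, d, "genetic_strain", assay_id)
            )
        if self.phenotype_dictionary is not None:
            mentions.extend(
                match_dictionary_entities(
                    sentence, self.phenotype_dictionary, "phenotype", assay_id
                )
            )
        mentions.extend(
            extract_rule_entities(sentence, phrases, self.patterns, assay_id)
        )
        mentions.sort(key=lambda m: (m.char_start, m.char_end, m.entity_class))
        return normalized, offmap, sentence, phrases, mentions

    def mentions(self, description: str, assay_id: str = "") -> list[EntityMention]:
        return self.process(description, assay_id)[4]

    def embedding_tokens(
        self,
        description: str,
        assay_id: str = "",
        species: str = "",
        stopwords: frozenset[str] | None = None,
    ) -> list[str]:
        """Token stream for embedding training: noun phrases joined, strain
        mentions replaced by "<preferred name> <species>", model mentions by
        their normalized form, numbers/stopwords removed."""
        from .preprocess import tokens_for_embedding

        _, _, sentence, phrases, mentions = self.process(description, assay_id)
        replacements = []
        for m in mentions:
            if m.entity_class == "genetic_strain":
                name = f"{m.normalized} {species}".strip()
                replacements.append((m.char_start, m.char_end, name))
            elif m.entity_class in ("experimental_model", "transgenic_model"):
                replacements.append((m.char_start, m.char_end, m.normalized))
        # drop replacements contained in an earlier, longer one
        replacements.sort(key=lambda r: (r[0], -(r[1] - r[0])))
        pruned: list[tuple[int, int, str]] = []
        for r in replacements:
            if not any(r[0] >= p[0] and r[1] <= p[1] for p in pruned):
                pruned.append(r)
        return tokens_for_embedding(sentence, phrases, pruned, stopwords)


MENTION_COLUMNS = ["assay_id", "class", "surface", "normalized", "start", "end"]


def annotate_corpus(assays, pipeline: NERPipeline) -> pd.DataFrame:
    """Run the pipeline over a corpus; one row per mention.

    Individual description failures are logged and skipped, never fatal.
    """
    rows = []
    for assay in assays:
        try:
            for m in pipeline.mentions(assay.description, assay.assay_id):
                rows.append((m.assay_id, m.entity_class, m.surface, m.normalized,
                             m.char_start, m.char_end))
        except Exception:  # noqa: BLE001 - per-description isolation
            logger.exception("NER failed for assay %s", assay.assay_id)
    return pd.DataFrame(rows, columns=MENTION_COLUMNS)


def annotation_summary(mentions: pd.DataFrame) -> dict:
    model_classes = ["genetic_strain", "experimental_model", "transgenic_model"]
    models = mentions[mentions["class"].isin(model_classes)]
    return {
        "n_mentions": int(len(mentions)),
        "n_distinct_model_names": int(models["normalized"].nunique()),
        "n_assays_with_model_mention": int(models["assay_id"].nunique()),
        "n_distinct_phenotypes": int(
            mentions.loc[mentions["class"] == "phenotype", "normalized"].nunique()
        ),
    }


# ---------------------------------------------------------------------------
# BRAT standoff IO
# ---------------------------------------------------------------------------


def write_brat(annotated: Iterable[AnnotatedDescription], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc in annotated:
        (out / f"{doc.doc_id}.txt").write_text(doc.text)
        lines = [
            f"T{i + 1}\t{m.entity_class} {m.char_start} {m.char_end}\t"
            f"{doc.text[m.char_start:m.char_end]}"
            for i, m in enumerate(doc.mentions)
        ]
        (out / f"{doc.doc_id}.ann").write_text("\n".join(lines) + ("\n" if lines else ""))


def read_brat(directory: str | Path) -> list[AnnotatedDescription]:
    """Read .txt/.ann BRAT standoff pairs from a directory."""
    directory = Path(directory)
    docs = []
    for txt in sorted(directory.glob("*.txt")):
        text = txt.read_text()
        doc = AnnotatedDescription(txt.stem, text)
        ann = txt.with_suffix(".ann")
        if ann.exists():
            for line in ann.read_text().splitlines():
                if not line.startswith("T"):
                    continue
                _, spec, surface = line.split("\t", 2)
                cls, start, end = spec.rsplit(" ", 2)
                start, end = int(start), int(end)
                if end > len(text) or start < 0 or start >= end:
                    raise ValueError(f"invalid span in {ann.name}: {line!r}")
                doc.mentions.append(
                    EntityMention(txt.stem, cls, surface, surface, start, end)
                )
        docs.append(doc)
    return docs


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    n_gold: int
    n_predicted: int


@dataclass
class NERMetrics:
    mode: str
    per_class: dict[str, ClassMetrics]
    micro: ClassMetrics


def _prf(tp: int, n_pred: int, n_gold: int) -> ClassMetrics:
    p = tp / n_pred if n_pred else 0.0
    r = tp / n_gold if n_gold else 0.0
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    return ClassMetrics(p, r, f, n_gold, n_pred)


def evaluate_ner(
    predicted: dict[str, list[EntityMention]] | pd.DataFrame,
    gold: Sequence[AnnotatedDescription],
    mode: str = "exact",
) -> NERMetrics:
    """Precision/recall/F1 per entity class and micro-averaged.

    ``exact``: a prediction is a true positive iff some gold mention has the
    identical (class, span). ``partial``: same class and any character
    overlap; each gold mention can satisfy at most one prediction. Spans must
    be in the same coordinate frame as the gold description text.
    """
    if mode not in ("exact", "partial"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(predicted, pd.DataFrame):
        by_doc: dict[str, list[EntityMention]] = {}
        for row in predicted.itertuples(index=False):
            by_doc.setdefault(str(row.assay_id), []).append(
                EntityMention(str(row.assay_id), row[1], row.surface,
                              row.normalized, int(row.start), int(row.end))
            )
        predicted = by_doc

    classes = sorted(
        {m.entity_class for doc in gold for m in doc.mentions}
        | {m.entity_class for ms in predicted.values() for m in ms}
    )
    tp = {c: 0 for c in classes}
    n_pred = {c: 0 for c in classes}
    n_gold = {c: 0 for c in classes}
    for doc in gold:
        preds = sorted(predicted.get(doc.doc_id, []), key=lambda m: (m.char_start, m.char_end))
        for m in preds:
            if m.char_end > len(doc.text):
                raise ValueError(
                    f"prediction span {m.char_start}:{m.char_end} outside text of {doc.doc_id}"
                )
        golds = doc.mentions
        for c in classes:
            g = [m for m in golds if m.entity_class == c]
            p = [m for m in preds if m.entity_class == c]
            n_gold[c] += len(g)
            n_pred[c] += len(p)
            if mode == "exact":
                gset = {(m.char_start, m.char_end) for m in g}
                tp[c] += sum((m.char_start, m.char_end) in gset for m in p)
            else:
                unmatched = list(g)
                for m in p:
                    hit = next((x for x in unmatched if m.overlaps(x)), None)
                    if hit is not None:
                        unmatched.remove(hit)
                        tp[c] += 1
    per_class = {c: _prf(tp[c], n_pred[c], n_gold[c]) for c in classes}
    micro = _prf(sum(tp.values()), sum(n_pred.values()), sum(n_gold.values()))
    return NERMetrics(mode, per_class, micro)


def mention_frequencies(
    mentions: pd.DataFrame, entity_class: str | None = None, top_k: int | None = None
) -> list[tuple[str, int]]:
    """Ranked (normalized name, distinct-assay count), descending count with
    lexicographic tie-break."""
    df = mentions if entity_class is None else mentions[mentions["class"] == entity_class]
    counts = df.groupby("normalized")["assay_id"].nunique()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k] if top_k is not None else ranked
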
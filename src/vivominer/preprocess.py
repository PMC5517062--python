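"""Normalization, tagging and shallow chunking of assay descriptions.

Curator-written bioassay summaries ("Inhibition of carrageenan-induced paw
oedema in Sprague-Dawley rat at 5.16 mg/kg, sc after 3 hrs") are short,
semi-standardized sentences. This module turns a raw description into

1. a *normalized* text (species names canonicalized to "rat"/"mouse",
   administration-route/regimen acronyms expanded) plus an offset map that
   projects normalized character spans back onto the raw text;
2. a :class:`TaggedSentence` of tokens carrying Penn-Treebank-style POS tags
   and custom tags (``IND``/``IND_B`` experimental-procedure triggers,
   ``TRANSG``/``EXPR``/``KNOCK`` transgenesis keywords, ``SP`` species words,
   ``PROT``/``CELL`` protein and cell-line flags);
3. base noun phrases chunked by the grammar ``NP: {<JJ|NN.*>*<PROT|CELL|NN.*>+}``
   — determiners and numbers are excluded unless they are part of a
   protein/cell-line name, and phrases are split at trigger tokens so that an
   experimental stimulus and its phenotypic outcome become separate phrases;
4. the token stream used for embedding training: noun phrases joined with
   underscores, strain mentions replaced by preferred names, numbers and
   stopwords removed, everything lower-cased.

The POS tagger is a pluggable backend behind :class:`TaggerBackend`; the
bundled :class:`RuleTagger` (lexicon + suffix rules + a small protein/cell-line
gazetteer) is deterministic and dependency-free.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Protocol, Sequence

__all__ = [
    "TaggedToken",
    "TaggedSentence",
    "NounPhrase",
    "OffsetMap",
    "tokenize",
    "load_acronym_map",
    "load_stopwords",
    "normalize_description",
    "RuleTagger",
    "tag_tokens",
    "DEFAULT_KEYWORD_CONFIG",
    "apply_custom_tags",
    "extract_noun_phrases",
    "tokens_for_embedding",
]

CUSTOM_TAGS = ("IND", "IND_B", "TRANSG", "EXPR", "KNOCK", "SP", "PROT", "CELL")


@dataclass
class TaggedToken:
    text: str
    pos: str
    custom: str | None = None
    char_start: int = 0
    char_end: int = 0

    @property
    def effective_tag(self) -> str:
        """Custom tag when present, else the POS tag (the chunker's view)."""
        return self.custom or self.pos


@dataclass
class TaggedSentence:
    tokens: list[TaggedToken] = field(default_factory=list)
    source_assay_id: str = ""
    text: str = ""

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self):
        return len(self.tokens)


@dataclass
class NounPhrase:
    tokens: list[TaggedToken]
    char_start: int
    char_end: int

    @property
    def surface(self) -> str:
        return " ".join(t.text for t in self.tokens)


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

# Word characters plus internal '/', '.', ',' and "'" (so "mg/kg", "5.16",
# "55,212" and "Freund's" survive); hyphens always separate tokens so that
# trigger keywords in hyphenated stimuli ("carrageenan-induced") are their own
# tokens and the split-on-trigger chunking rule can fire.
_TOKEN_RE = re.compile(r"[A-Za-z0-9](?:[A-Za-z0-9/.,']*[A-Za-z0-9])?")
_NUMBER_RE = re.compile(r"[0-9]+(?:[.,][0-9]+)*")
_POSSESSIVE_RE = re.compile(r"(?:'s|'S)$")


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Split text into (token, char_start, char_end) triples.

    Possessive endings are detached as their own ``'s`` token, mirroring how
    Treebank-style taggers emit a separate POS-tagged possessive.
    """
    out: list[tuple[str, int, int]] = []
    for m in _TOKEN_RE.finditer(text):
        tok, s, e = m.group(), m.start(), m.end()
        pm = _POSSESSIVE_RE.search(tok)
        if pm and len(tok) > 2:
            cut = s + pm.start()
            out.append((tok[: pm.start()], s, cut))
            out.append((tok[pm.start():], cut, e))
        else:
            out.append((tok, s, e))
    return out


def is_number(token: str) -> bool:
    return bool(_NUMBER_RE.fullmatch(token))


# ---------------------------------------------------------------------------
# Normalization (species names + acronym expansion) with offset map
# ---------------------------------------------------------------------------

SPECIES_MAP = {
    "rattus norvegicus": "rat",
    "mus musculus": "mouse",
}


def load_acronym_map() -> dict[str, str]:
    """The bundled 20-entry administration acronym table."""
    out: dict[str, str] = {}
    text = resources.files("vivominer.data").joinpath("acronyms.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        acro, expansion = line.split("\t")[:2]
        out[acro.strip().lower()] = expansion.strip()
    return out


def load_stopwords() -> frozenset[str]:
    text = resources.files("vivominer.data").joinpath("stopwords.txt").read_text()
    return frozenset(
        w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#")
    )


class OffsetMap:
    """Maps character spans in the normalized text back to the raw text.

    Built from an ordered list of (raw_start, raw_end, norm_start, norm_end)
    replacement segments; positions outside any segment shift rigidly.
    """

    def __init__(self, segments: list[tuple[int, int, int, int]], raw_len: int, norm_len: int):
        self.segments = segments
        self.raw_len = raw_len
        self.norm_len = norm_len

    def _to_raw_pos(self, pos: int, *, end: bool) -> int:
        delta = 0
        for rs, re_, ns, ne in self.segments:
            if pos < ns:
                break
            if pos >= ne:
                delta = re_ - ne
                continue
            # inside a replaced segment: snap to the segment boundary
            return rs if not end or pos == ns else re_
        return pos + delta

    def to_raw(self, start: int, end: int) -> tuple[int, int]:
        """Project a normalized half-open span onto raw-text coordinates."""
        return self._to_raw_pos(start, end=False), self._to_raw_pos(end, end=True)

    @property
    def identity(self) -> bool:
        return not self.segments


def normalize_description(
    text: str, acronym_map: dict[str, str] | None = None
) -> tuple[str, OffsetMap]:
    """Canonicalize species names and expand whole-token acronyms.

    Returns the normalized text and an :class:`OffsetMap` for round-tripping
    annotation spans. Unknown tokens pass through unchanged.
    """
    if acronym_map is None:
        acronym_map = load_acronym_map()
    # collect non-overlapping replacements on the raw text, left to right
    repls: list[tuple[int, int, str]] = []
    for phrase, canon in SPECIES_MAP.items():
        pat = re.compile(r"\b" + re.escape(phrase).replace(r"\ ", r"\s+") + r"\b", re.I)
        for m in pat.finditer(text):
            repls.append((m.start(), m.end(), canon))
    if acronym_map:
        acro_pat = re.compile(
            r"(?<![A-Za-z0-9])(" + "|".join(re.escape(a) for a in sorted(acronym_map, key=len, reverse=True)) + r")(?![A-Za-z0-9])",
            re.I,
        )
        for m in acro_pat.finditer(text):
            repls.append((m.start(), m.end(), acronym_map[m.group(1).lower()]))
    repls.sort()
    # drop overlaps (first wins)
    pruned: list[tuple[int, int, str]] = []
    last_end = -1
    for s, e, rep in repls:
        if s >= last_end:
            pruned.append((s, e, rep))
            last_end = e

    parts: list[str] = []
    segments: list[tuple[int, int, int, int]] = []
    cursor = 0
    norm_cursor = 0
    for s, e, rep in pruned:
        if rep == text[s:e]:
            continue
        parts.append(text[cursor:s])
        norm_cursor += s - cursor
        parts.append(rep)
        segments.append((s, e, norm_cursor, norm_cursor + len(rep)))
        norm_cursor += len(rep)
        cursor = e
    parts.append(text[cursor:])
    normalized = "".join(parts)
    return normalized, OffsetMap(segments, len(text), len(normalized))


# ---------------------------------------------------------------------------
# POS tagging: pluggable backend + bundled deterministic fallback
# ---------------------------------------------------------------------------


class TaggerBackend(Protocol):
    """Contract for POS/NER tagging backends.

    A backend must be deterministic and return, for a pre-tokenized sentence,
    one (pos, bio_flag) pair per token, where ``bio_flag`` is ``None`` or one
    of ``PROT``/``CELL`` (protein / cell-line entity membership).
    """

    def tag(self, tokens: Sequence[str]) -> list[tuple[str, str | None]]: ...


_PREPOSITIONS = {
    "in", "of", "at", "on", "for", "with", "by", "to", "after", "before",
    "during", "per", "versus", "vs", "than", "as", "from", "into", "under",
    "over", "against", "via", "without", "between", "upon", "through",
}
_DETERMINERS = {"a", "an", "the", "this", "that", "these", "those", "its", "their", "each", "any", "some", "no"}
_CONJUNCTIONS = {"and", "or", "but", "nor"}
_VERBS = {
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "assessed": "VBN", "measured": "VBN", "evaluated": "VBN",
    "compared": "VBN", "determined": "VBN", "expressed": "VBN", "dosed": "VBN",
    "administered": "VBN", "given": "VBN", "tested": "VBN", "using": "VBG",
}
_ADJECTIVES = {
    "high", "low", "acute", "chronic", "complete", "male", "female", "adult",
    "young", "maximal", "maximum", "anti-inflammatory", "antidiabetic",
    "anticonvulsant", "analgesic", "antitumor", "oral", "subcutaneous",
    "intravenous", "intraperitoneal", "intramuscular", "peroral", "daily",
    "intragastric", "intracerebroventricular", "intradermal", "intracisternal",
    "diabetic", "hypertensive", "obese", "fatty", "spontaneous", "clonic",
    "tonic", "systolic", "diastolic", "arterial", "inflammatory",
}
_JJ_SUFFIXES = ("ous", "ive", "ble", "ary", "ical", "inal", "atic", "etic", "emic")
_ADVERB_SUFFIX = "ly"


def _load_bio_lexicon() -> dict[tuple[str, ...], str]:
    lex: dict[tuple[str, ...], str] = {}
    text = resources.files("vivominer.data").joinpath("bio_entities.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        surface, tag = line.split("\t")[:2]
        # hyphens never survive tokenization: index the hyphen-split form
        key = tuple(t for part in surface.strip().lower().split() for t in part.split("-"))
        lex[key] = tag.strip()
    return lex


class RuleTagger:
    """Bundled deterministic lexicon + suffix POS tagger with a small
    protein/cell-line gazetteer standing in for biological NER flags.

    Tags are Penn-Treebank style. Heuristics, in order: closed-class lexicon;
    numbers -> CD; possessive ``'s`` -> POS; verbal/adjectival/adverbial
    suffixes; capitalized mid-sentence tokens -> NNP; default NN (plural -s ->
    NNS). Sentence-initial capitalization is ignored so "Inhibition" is a
    plain noun.
    """

    def __init__(self, bio_lexicon: dict[tuple[str, ...], str] | None = None):
        self.bio_lexicon = _load_bio_lexicon() if bio_lexicon is None else bio_lexicon
        self._max_bio_len = max((len(k) for k in self.bio_lexicon), default=1)

    def tag(self, tokens: Sequence[str]) -> list[tuple[str, str | None]]:
        pos = [self._pos_one(tok, i) for i, tok in enumerate(tokens)]
        bio: list[str | None] = [None] * len(tokens)
        low = [t.lower() for t in tokens]
        i = 0
        while i < len(tokens):
            matched = 0
            tag = None
            for n in range(min(self._max_bio_len, len(tokens) - i), 0, -1):
                key = tuple(low[i: i + n])
                if key in self.bio_lexicon:
                    matched, tag = n, self.bio_lexicon[key]
                    break
            if matched:
                for j in range(i, i + matched):
                    bio[j] = tag
                i += matched
            else:
                i += 1
        return list(zip(pos, bio))

    def _pos_one(self, token: str, index: int) -> str:
        low = token.lower()
        if is_number(token):
            return "CD"
        if low == "'s":
            return "POS"
        if low in _PREPOSITIONS:
            return "IN"
        if low in _DETERMINERS:
            return "DT"
        if low in _CONJUNCTIONS:
            return "CC"
        if low in _VERBS:
            return _VERBS[low]
        if low in _ADJECTIVES:
            return "JJ"
        if index > 0 and token[:1].isupper():
            return "NNP"
        if low.endswith(_ADVERB_SUFFIX) and len(low) > 4:
            return "RB"
        if low.endswith("ed") and len(low) > 4:
            return "VBN"
        if low.endswith("ing") and len(low) > 5:
            return "VBG"
        if any(low.endswith(s) for s in _JJ_SUFFIXES) and len(low) > 4:
            return "JJ"
        if low.endswith("s") and not low.endswith("ss") and len(low) > 3:
            return "NNS"
        return "NN"


_DEFAULT_TAGGER: RuleTagger | None = None


def _default_tagger() -> RuleTagger:
    global _DEFAULT_TAGGER
    if _DEFAULT_TAGGER is None:
        _DEFAULT_TAGGER = RuleTagger()
    return _DEFAULT_TAGGER


def tag_tokens(
    text: str,
    tagger: TaggerBackend | None = None,
    source_assay_id: str = "",
) -> TaggedSentence:
    """Tokenize a normalized description and POS-tag it.

    ``PROT``/``CELL`` custom tags are set from the backend's biological NER
    output. Empty input yields an empty sentence.
    """
    tagger = tagger or _default_tagger()
    toks = tokenize(text)
    if not toks:
        return TaggedSentence([], source_assay_id, text)
    tags = tagger.tag([t for t, _, _ in toks])
    tokens = [
        TaggedToken(tok, pos, bio, s, e)
        for (tok, s, e), (pos, bio) in zip(toks, tags)
    ]
    return TaggedSentence(tokens, source_assay_id, text)


# ---------------------------------------------------------------------------
# Custom tags
# ---------------------------------------------------------------------------

# Trigger keywords for experimental procedures (IND / IND_B) and genetic
# modification (TRANSG / EXPR / KNOCK). The printed examples are: induced,
# infected, xenografted, fed, operated, (pre)treated, stimulated (IND family;
# 24 keywords in total) and transgenic, overexpressing, knockout (TRANSG
# family). The remaining entries are documented extrapolations covering the
# same procedure families (injection, challenge, surgery, grafting, diet,
# sensitization); edit via the ``keyword_config`` argument.
DEFAULT_KEYWORD_CONFIG: dict[str, frozenset[str]] = {
    "IND": frozenset({
        "induced", "infected", "xenografted", "fed", "operated", "treated",
        "pretreated", "stimulated", "challenged", "injected", "administered",
        "exposed", "sensitized", "immunized", "implanted", "inoculated",
        "ligated", "loaded", "lesioned", "deprived", "evoked", "primed",
        "bearing", "depleted",
    }),
    # triggers that legitimately begin a phrase ("fasted rat")
    "IND_B": frozenset({"fasted"}),
    "TRANSG": frozenset({"transgenic"}),
    "EXPR": frozenset({"overexpressing", "expressing"}),
    "KNOCK": frozenset({"knockout", "knockdown", "knock-out", "deficient", "null"}),
    "SP": frozenset({"rat", "rats", "mouse", "mice"}),
}


def apply_custom_tags(
    sentence: TaggedSentence,
    keyword_config: dict[str, frozenset[str]] | None = None,
) -> TaggedSentence:
    """Overlay IND/IND_B/TRANSG/EXPR/KNOCK/SP tags onto a tagged sentence.

    Matching is case-insensitive on token text; PROT/CELL flags set by the
    tagger are never overwritten. The sentence is modified in place and
    returned.
    """
    config = keyword_config or DEFAULT_KEYWORD_CONFIG
    lookup = {kw: tag for tag, kws in config.items() for kw in kws}
    for tok in sentence.tokens:
        if tok.custom in ("PROT", "CELL"):
            continue
        tag = lookup.get(tok.text.lower())
        if tag:
            tok.custom = tag
    return sentence


# ---------------------------------------------------------------------------
# Chunking grammar
# ---------------------------------------------------------------------------


def _chunk_symbol(tok: TaggedToken) -> str:
    """One-char symbol of a token for the NP grammar regex.

    J = adjective, N = noun (NN/NNS/NNP/...), P = PROT/CELL, X = everything
    else. Custom tags take precedence, so trigger/species/number tokens are
    never absorbed into a noun phrase (this is what splits "concanavalin A
    induced hepatic cell necrosis" into stimulus and outcome phrases).
    """
    tag = tok.effective_tag
    if tag in ("PROT", "CELL"):
        return "P"
    if tag in CUSTOM_TAGS:
        return "X"
    if tag == "JJ":
        return "J"
    if tag.startswith("NN"):
        return "N"
    return "X"


# NP: {<JJ|NN.*>*<PROT|CELL|NN.*>+} as a regex over chunk symbols;
# re's greedy leftmost-longest scan reproduces chunk-parser semantics.
_NP_PATTERN = re.compile(r"[JN]*[NP]+")


def extract_noun_phrases(sentence: TaggedSentence) -> list[NounPhrase]:
    """Maximal non-overlapping base noun phrases under the chunking grammar."""
    symbols = "".join(_chunk_symbol(t) for t in sentence.tokens)
    phrases = []
    for m in _NP_PATTERN.finditer(symbols):
        toks = sentence.tokens[m.start(): m.end()]
        phrases.append(NounPhrase(toks, toks[0].char_start, toks[-1].char_end))
    return phrases


# ---------------------------------------------------------------------------
# Tagged-text interchange format
# ---------------------------------------------------------------------------


def write_tagged(sentences: Iterable[TaggedSentence], path) -> None:
    """One token per line: text, POS, custom tag ('-' if none), offsets;
    blank line between sentences, '# <assay_id>' sentence headers."""
    from pathlib import Path

    lines: list[str] = []
    for sent in sentences:
        lines.append(f"# {sent.source_assay_id}")
        for t in sent.tokens:
            lines.append(f"{t.text}\t{t.pos}\t{t.custom or '-'}\t{t.char_start}\t{t.char_end}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_tagged(path) -> list[TaggedSentence]:
    from pathlib import Path

    sentences: list[TaggedSentence] = []
    current: TaggedSentence | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("# "):
            current = TaggedSentence([], line[2:])
            sentences.append(current)
        elif line.strip() and current is not None:
            text, pos, custom, s, e = line.split("\t")
            current.tokens.append(
                TaggedToken(text, pos, None if custom == "-" else custom, int(s), int(e))
            )
    for sent in sentences:
        # reconstruct the text skeleton from token offsets
        buf = list(" " * (sent.tokens[-1].char_end if sent.tokens else 0))
        for t in sent.tokens:
            buf[t.char_start: t.char_end] = t.text
        sent.text = "".join(buf)
    return sentences


# ---------------------------------------------------------------------------
# Embedding token stream
# ---------------------------------------------------------------------------


def _join(words: Iterable[str]) -> str:
    return "_".join(w.lower() for w in words)


def tokens_for_embedding(
    sentence: TaggedSentence,
    phrases: Sequence[NounPhrase] | None = None,
    mention_replacements: Sequence[tuple[int, int, str]] | None = None,
    stopwords: frozenset[str] | None = None,
) -> list[str]:
    """Token stream for embedding training.

    Multi-word noun phrases become single underscore-joined tokens; spans in
    ``mention_replacements`` (char_start, char_end, replacement) — typically
    normalized strain or model mentions — are emitted as a single token;
    numbers and stopwords are removed; everything is lower-cased.
    """
    if phrases is None:
        phrases = extract_noun_phrases(sentence)
    if stopwords is None:
        stopwords = load_stopwords()
    repl = sorted(mention_replacements or [])

    out: list[str] = []
    i = 0
    toks = sentence.tokens
    phrase_at = {id(p.tokens[0]): p for p in phrases}
    while i < len(toks):
        tok = toks[i]
        consumed = False
        for rs, re_, replacement in repl:
            if tok.char_start >= rs and tok.char_start < re_:
                if not out or out[-1] != _join(replacement.split()):
                    out.append(_join(replacement.split()))
                while i < len(toks) and toks[i].char_start < re_:
                    i += 1
                consumed = True
                break
        if consumed:
            continue
        p = phrase_at.get(id(tok))
        if p is not None:
            words = [t.text for t in p.tokens if not is_number(t.text)]
            if words:
                joined = _join(words)
                if joined not in stopwords:
                    out.append(joined)
            i += len(p.tokens)
            continue
        low = tok.text.lower()
        if not is_number(low) and low not in stopwords:
            out.append(low)
        i += 1
    return out
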
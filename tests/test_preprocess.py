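"""Normalization, tagging, chunking grammar and embedding token streams."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from vivominer.preprocess import (
    NounPhrase,
    RuleTagger,
    TaggedSentence,
    TaggedToken,
    apply_custom_tags,
    extract_noun_phrases,
    load_acronym_map,
    load_stopwords,
    normalize_description,
    tag_tokens,
    tokenize,
    tokens_for_embedding,
)


# -- normalization -----------------------------------------------------------


def test_species_and_route_acronym_normalization():
    text = "Inhibition of oedema in Rattus norvegicus at 5 mg/kg, sc"
    norm, _ = normalize_description(text)
    assert norm == "Inhibition of oedema in rat at 5 mg/kg, subcutaneous"


def test_regimen_acronym_expansion():
    norm, _ = normalize_description("qd dosing in Mus musculus")
    assert norm == "daily dosing in mouse"


def test_no_op_normalization_has_identity_offset_map():
    text = "Inhibition of paw oedema in rat"
    norm, offmap = normalize_description(text)
    assert norm == text and offmap.identity
    assert offmap.to_raw(14, 24) == (14, 24)


def test_offset_map_round_trips_spans():
    text = "Effect in Rattus norvegicus at 5 mg/kg, sc after qd dosing"
    norm, offmap = normalize_description(text)
    # span over "subcutaneous" maps back onto the raw "sc"
    start = norm.index("subcutaneous")
    rs, re_ = offmap.to_raw(start, start + len("subcutaneous"))
    assert text[rs:re_] == "sc"
    # span before any replacement is untouched
    assert offmap.to_raw(0, 6) == (0, 6)
    # span over "rat" maps onto the raw species name
    rstart = norm.index("rat")
    rs, re_ = offmap.to_raw(rstart, rstart + 3)
    assert text[rs:re_] == "Rattus norvegicus"


def test_acronym_table_has_twenty_entries_with_printed_examples():
    table = load_acronym_map()
    assert len(table) == 20
    assert table["sc"] == "subcutaneous" and table["qd"] == "daily"


# -- tokenizer ---------------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        ("carrageenan-induced paw oedema", ["carrageenan", "induced", "paw", "oedema"]),
        ("at 5.16 mg/kg, sc", ["at", "5.16", "mg/kg", "sc"]),
        ("Freund's complete adjuvant", ["Freund", "'s", "complete", "adjuvant"]),
        ("ob/ob mouse", ["ob/ob", "mouse"]),
        ("", []),
    ],
)
def test_tokenizer(text, expected):
    assert [t for t, _, _ in tokenize(text)] == expected


def test_token_offsets_are_increasing_and_consistent():
    text = "Inhibition of carrageenan-induced paw oedema in Sprague-Dawley rat"
    toks = tokenize(text)
    last = -1
    for tok, s, e in toks:
        assert s < e and s > last
        assert text[s:e] == tok
        last = s


# -- tagger ------------------------------------------------------------------


def test_rule_tagger_basic_pos():
    sent = tag_tokens("Inhibition of oedema")
    assert [t.pos for t in sent.tokens] == ["NN", "IN", "NN"]


def test_protein_tokens_flagged_from_gazetteer():
    sent = tag_tokens("Concanavalin A induced hepatic cell necrosis")
    assert sent.tokens[0].custom == "PROT" and sent.tokens[1].custom == "PROT"


def test_empty_string_gives_empty_sentence():
    sent = tag_tokens("")
    assert len(sent) == 0


def test_tagger_deterministic():
    text = "Reduction of blood glucose level in ZDF rat at 10 mg/kg"
    a = [(t.text, t.pos, t.custom) for t in tag_tokens(text)]
    b = [(t.text, t.pos, t.custom) for t in tag_tokens(text)]
    assert a == b


# -- custom tags -------------------------------------------------------------


def test_trigger_and_species_tags():
    sent = apply_custom_tags(tag_tokens("streptozotocin induced diabetes in rat"))
    by_text = {t.text: t.custom for t in sent}
    assert by_text["induced"] == "IND" and by_text["rat"] == "SP"


def test_transgenic_tags():
    sent = apply_custom_tags(tag_tokens("APOA1 transgenic mouse overexpressing leptin"))
    by_text = {t.text: t.custom for t in sent}
    assert by_text["transgenic"] == "TRANSG"
    assert by_text["overexpressing"] == "EXPR"
    assert by_text["mouse"] == "SP"
    assert by_text["leptin"] == "PROT"  # PROT never overwritten


def test_sentence_without_keywords_unchanged():
    sent = tag_tokens("Reduction of arterial pressure")
    before = [(t.text, t.pos, t.custom) for t in sent]
    apply_custom_tags(sent)
    assert [(t.text, t.pos, t.custom) for t in sent] == before


# -- chunking grammar --------------------------------------------------------


def _phrases(text):
    sent = apply_custom_tags(tag_tokens(text))
    return [p.surface for p in extract_noun_phrases(sent)]


def test_split_on_induced_separates_stimulus_and_outcome():
    assert _phrases("concanavalin A induced hepatic cell necrosis") == [
        "concanavalin A",
        "hepatic cell necrosis",
    ]


def test_base_np_extracted_from_long_phrase():
    got = _phrases("a perorally dosed Freund's complete adjuvant induced rat inflammatory pain model")
    assert "inflammatory pain model" in got
    assert "Freund" in got and "complete adjuvant" in got
    # determiner and species word never inside a phrase
    assert all("a " != p[:2] and " rat" not in p for p in got)


def test_all_function_words_give_no_phrases():
    sent = tag_tokens("of in at after")
    assert extract_noun_phrases(sent) == []


def _oracle_chunks(symbols: str) -> list[tuple[int, int]]:
    """Brute-force leftmost-longest enumeration of the NP grammar.

    A span matches iff it splits into a (possibly empty) prefix of {J, N} and a
    non-empty suffix of {N, P}; scan left to right taking the longest match.
    """

    def matches(seq: str) -> bool:
        return any(
            all(s in "JN" for s in seq[:m]) and seq[m:] and all(s in "NP" for s in seq[m:])
            for m in range(len(seq))
        )

    out = []
    i = 0
    while i < len(symbols):
        best = None
        for j in range(len(symbols), i, -1):
            if matches(symbols[i:j]):
                best = j
                break
        if best is None:
            i += 1
        else:
            out.append((i, best))
            i = best
    return out


SYMBOL_TO_TAG = {"J": "JJ", "N": "NN", "P": "PROT", "X": "IN"}


def _sentence_from_symbols(symbols: str) -> TaggedSentence:
    toks = []
    pos = 0
    for i, s in enumerate(symbols):
        tag = SYMBOL_TO_TAG[s]
        custom = "PROT" if s == "P" else None
        toks.append(TaggedToken(f"w{i}", tag if s != "P" else "NN", custom, pos, pos + 2))
        pos += 3
    return TaggedSentence(toks, text=" ".join(f"w{i}" for i in range(len(symbols))))


@pytest.mark.parametrize("length", range(1, 9))
def test_grammar_matches_bruteforce_oracle_exhaustively(length):
    """On every tag sequence of length <= 8 over {JJ, NN, IN, PROT}, the chunker
    equals exhaustive leftmost-longest enumeration of the grammar."""
    from itertools import product

    for combo in product("JNPX", repeat=length):
        symbols = "".join(combo)
        sent = _sentence_from_symbols(symbols)
        got = [(sent.tokens.index(p.tokens[0]), sent.tokens.index(p.tokens[-1]) + 1)
               for p in extract_noun_phrases(sent)]
        assert got == _oracle_chunks(symbols), symbols


@settings(max_examples=300, deadline=None)
@given(st.text(alphabet="JNPX", min_size=9, max_size=16))
def test_grammar_matches_oracle_on_longer_sequences(symbols):
    sent = _sentence_from_symbols(symbols)
    got = [(sent.tokens.index(p.tokens[0]), sent.tokens.index(p.tokens[-1]) + 1)
           for p in extract_noun_phrases(sent)]
    assert got == _oracle_chunks(symbols)


# -- embedding token stream --------------------------------------------------


def test_multiword_phrase_joined_with_underscore():
    sent = apply_custom_tags(tag_tokens("Reduction of arterial pressure"))
    toks = tokens_for_embedding(sent)
    assert "arterial_pressure" in toks


def test_strain_replacement_and_number_stopword_removal():
    text = "Inhibition of oedema in C57BL/6J male mouse at 5 mg/kg"
    sent = apply_custom_tags(tag_tokens(text))
    start = text.index("C57BL/6J")
    end = text.index("mouse") + len("mouse")
    toks = tokens_for_embedding(sent, mention_replacements=[(start, end, "C57BL mouse")])
    assert "c57bl_mouse" in toks
    assert "5" not in toks and "of" not in toks and "at" not in toks


def test_all_removed_gives_empty_stream():
    sent = apply_custom_tags(tag_tokens("the 5 mg"))
    # "mg" survives tokenization but "the" and "5" must go
    toks = tokens_for_embedding(sent)
    assert "the" not in toks and "5" not in toks


def test_token_stream_deterministic():
    text = "Inhibition of carrageenan-induced paw oedema in rat"
    sent1 = apply_custom_tags(tag_tokens(text))
    sent2 = apply_custom_tags(tag_tokens(text))
    assert tokens_for_embedding(sent1) == tokens_for_embedding(sent2)
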
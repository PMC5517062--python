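"""Entity recognition: dictionary matching, rule patterns, evaluation, BRAT IO."""

import numpy as np
import pytest

from vivominer.lexicon import PhenotypeDictionary, compile_strain_dictionary, load_strain_listing
from vivominer.ner import (
    AnnotatedDescription,
    EntityMention,
    NERPipeline,
    annotate_corpus,
    evaluate_ner,
    extract_rule_entities,
    match_dictionary_entities,
    mention_frequencies,
    read_brat,
    write_brat,
)
from vivominer.preprocess import apply_custom_tags, tag_tokens

from conftest import make_pipeline


@pytest.fixture(scope="module")
def strain_dict():
    return compile_strain_dictionary(load_strain_listing())


def _sent(text):
    return apply_custom_tags(tag_tokens(text))


# -- dictionary matching -----------------------------------------------------


def test_substrain_with_sex_modifier_normalizes_to_parent(strain_dict):
    text = "Survival of C56BL/6J male mouse"
    ments = match_dictionary_entities(_sent(text), strain_dict, "genetic_strain")
    assert len(ments) == 1
    m = ments[0]
    assert m.normalized == "C57BL"
    assert text[m.char_start:m.char_end] == "C56BL/6J male mouse"


def test_alphanumeric_key_tolerates_punctuation(strain_dict):
    ments = match_dictionary_entities(_sent("oedema in Sprague-Dawley rat"), strain_dict, "genetic_strain")
    assert [m.normalized for m in ments] == ["Sprague Dawley"]
    ments2 = match_dictionary_entities(_sent("weight of ob-ob mouse"), strain_dict, "genetic_strain")
    assert [m.normalized for m in ments2] == ["ob/ob"]


def test_no_dictionary_terms_gives_empty(strain_dict):
    assert match_dictionary_entities(_sent("Inhibition of oedema"), strain_dict, "genetic_strain") == []


def test_longest_match_wins(strain_dict):
    # "Zucker diabetic fatty" must resolve to ZDF, not stop at "Zucker"
    ments = match_dictionary_entities(_sent("in Zucker diabetic fatty rat"), strain_dict, "genetic_strain")
    assert [m.normalized for m in ments] == ["ZDF"]


def test_biomarker_suffix_suppression():
    pheno = PhenotypeDictionary.from_terms(["IL4 production", "paw oedema"])
    ments = match_dictionary_entities(_sent("change in IL4 production"), pheno, "phenotype")
    assert ments == []  # IL4 carries PROT, head word is a biomarker suffix
    ments2 = match_dictionary_entities(_sent("change in paw oedema"), pheno, "phenotype")
    assert [m.normalized for m in ments2] == ["paw oedema"]


# -- rule patterns -----------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected_surface,expected_class",
    [
        ("Freund's complete adjuvant induced arthritis", "Freund's complete adjuvant induced", "experimental_model"),
        ("performance in glucose tolerance test", "glucose tolerance test", "experimental_model"),
        ("APOA1 transgenic mouse", "APOA1 transgenic", "transgenic_model"),
        ("mortality of Staphylococcus aureus infected mouse", "Staphylococcus aureus infected", "experimental_model"),
        ("weight of high-fat diet fed rat", "high-fat diet fed", "experimental_model"),
    ],
)
def test_extraction_patterns_on_canonical_phrases(text, expected_surface, expected_class):
    ments = extract_rule_entities(_sent(text))
    assert (expected_surface, expected_class) in {(m.surface, m.entity_class) for m in ments}


def test_trigger_needs_noun_material_on_suffix_pattern():
    # a bare trigger with no preceding phrase is not an induced-model mention
    ments = extract_rule_entities(_sent("effect was induced slowly"))
    surfaces = [m.surface for m in ments if m.entity_class == "experimental_model"]
    assert "induced" not in surfaces


def test_rule_mentions_do_not_overlap_within_class(noisy_corpus, noisy_pipeline):
    for assay in noisy_corpus.assays[:100]:
        ments = noisy_pipeline.mentions(assay.description, assay.assay_id)
        for cls in {"experimental_model", "transgenic_model", "genetic_strain", "phenotype"}:
            spans = sorted(
                (m.char_start, m.char_end) for m in ments if m.entity_class == cls
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2, (assay.description, cls, spans)


# -- pipeline on the canonical example ---------------------------------------


def test_pipeline_on_canonical_description(strain_dict):
    pipe = NERPipeline(
        strain_dictionaries=[strain_dict],
        phenotype_dictionary=PhenotypeDictionary.from_terms(["paw oedema"]),
    )
    ments = pipe.mentions(
        "Inhibition of carrageenan-induced paw oedema in Sprague-Dawley rat at 5.16 mg/kg, sc after 3 hrs"
    )
    got = {(m.entity_class, m.normalized) for m in ments}
    assert ("experimental_model", "carrageenan induced") in got
    assert ("phenotype", "paw oedema") in got
    assert ("genetic_strain", "Sprague Dawley") in got


def test_annotate_corpus_empty_is_empty_table():
    df = annotate_corpus([], NERPipeline())
    assert df.empty and list(df.columns) == ["assay_id", "class", "surface", "normalized", "start", "end"]


def test_zero_noise_corpus_has_full_recall(zero_noise_corpus):
    pipe = make_pipeline(zero_noise_corpus)
    mentions = annotate_corpus(zero_noise_corpus.assays, pipe)
    metrics = evaluate_ner(mentions, zero_noise_corpus.gold, "exact")
    for cls, m in metrics.per_class.items():
        assert m.recall == 1.0, cls


# -- evaluation --------------------------------------------------------------


def _gold(text, spans):
    return AnnotatedDescription(
        "d1", text, [EntityMention("d1", c, text[s:e], text[s:e], s, e) for c, s, e in spans]
    )


def test_perfect_prediction_scores_one():
    doc = _gold("paw oedema in SHR rat", [("phenotype", 0, 10), ("genetic_strain", 14, 21)])
    metrics = evaluate_ner({"d1": doc.mentions}, [doc], "exact")
    assert metrics.micro.f1 == 1.0
    assert all(m.f1 == 1.0 for m in metrics.per_class.values())


def test_off_by_one_span_counts_under_partial_only():
    doc = _gold("paw oedema in rat", [("phenotype", 0, 10)])
    pred = [EntityMention("d1", "phenotype", "aw oedema", "aw oedema", 1, 10)]
    exact = evaluate_ner({"d1": pred}, [doc], "exact")
    partial = evaluate_ner({"d1": pred}, [doc], "partial")
    assert exact.micro.f1 == 0.0
    assert partial.micro.f1 == 1.0


def test_hand_counted_precision_recall():
    """2 gold, 1 correct + 1 spurious prediction: P = R = F1 = 0.5."""
    doc = _gold("paw oedema in SHR rat", [("phenotype", 0, 10), ("phenotype", 14, 21)])
    pred = [
        EntityMention("d1", "phenotype", "paw oedema", "paw oedema", 0, 10),
        EntityMention("d1", "phenotype", "in", "in", 11, 13),
    ]
    m = evaluate_ner({"d1": pred}, [doc], "exact").per_class["phenotype"]
    assert (m.precision, m.recall, m.f1) == (0.5, 0.5, 0.5)


def test_span_outside_text_is_fatal():
    doc = _gold("short", [])
    pred = [EntityMention("d1", "phenotype", "x", "x", 2, 99)]
    with pytest.raises(ValueError, match="d1"):
        evaluate_ner({"d1": pred}, [doc], "exact")


def test_exact_f1_never_exceeds_partial_f1_randomized():
    """Definitional monotonicity over randomized prediction/gold pairs."""
    rng = np.random.default_rng(42)
    classes = ["genetic_strain", "experimental_model", "phenotype"]
    for _ in range(200):
        text = "x" * 60
        def random_mentions(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 50))
                e = s + int(rng.integers(1, 10))
                out.append(EntityMention("d1", classes[rng.integers(0, 3)], "x", "x", s, e))
            return out
        doc = AnnotatedDescription("d1", text, random_mentions(int(rng.integers(0, 6))))
        pred = random_mentions(int(rng.integers(0, 6)))
        exact = evaluate_ner({"d1": pred}, [doc], "exact")
        partial = evaluate_ner({"d1": pred}, [doc], "partial")
        assert exact.micro.f1 <= partial.micro.f1 + 1e-12
        for cls in exact.per_class:
            assert exact.per_class[cls].f1 <= partial.per_class[cls].f1 + 1e-12


def test_interannotator_agreement_uses_same_machinery():
    """Two annotation sets compared with exact/partial give strict/relaxed IAA."""
    doc_a = _gold("paw oedema in SHR rat", [("phenotype", 0, 10)])
    doc_b = _gold("paw oedema in SHR rat", [("phenotype", 0, 9)])
    strict = evaluate_ner({"d1": doc_b.mentions}, [doc_a], "exact")
    relaxed = evaluate_ner({"d1": doc_b.mentions}, [doc_a], "partial")
    assert strict.micro.f1 == 0.0 and relaxed.micro.f1 == 1.0


# -- BRAT --------------------------------------------------------------------


def test_brat_round_trip(tmp_path, zero_noise_corpus):
    write_brat(zero_noise_corpus.gold[:20], tmp_path)
    docs = read_brat(tmp_path)
    assert len(docs) == 20
    orig = {d.doc_id: d for d in zero_noise_corpus.gold[:20]}
    for doc in docs:
        ref = orig[doc.doc_id]
        assert doc.text == ref.text
        assert {(m.entity_class, m.char_start, m.char_end) for m in doc.mentions} == {
            (m.entity_class, m.char_start, m.char_end) for m in ref.mentions
        }
        for m in doc.mentions:
            assert doc.text[m.char_start:m.char_end] == m.surface


# -- frequencies -------------------------------------------------------------


def test_mention_frequencies_counts_distinct_assays():
    import pandas as pd

    df = pd.DataFrame(
        [
            ("A1", "genetic_strain", "SHR", "SHR", 0, 3),
            ("A1", "genetic_strain", "SHR", "SHR", 10, 13),  # same assay, counted once
            ("A2", "genetic_strain", "SHR", "SHR", 0, 3),
            ("A3", "genetic_strain", "SHR", "SHR", 0, 3),
            ("A4", "genetic_strain", "Wistar", "Wistar", 0, 6),
        ],
        columns=["assay_id", "class", "surface", "normalized", "start", "end"],
    )
    assert mention_frequencies(df, "genetic_strain") == [("SHR", 3), ("Wistar", 1)]


def test_frequencies_match_generator_ledger(zero_noise_corpus):
    pipe = make_pipeline(zero_noise_corpus)
    mentions = annotate_corpus(zero_noise_corpus.assays, pipe)
    got = dict(mention_frequencies(mentions, "genetic_strain"))
    planted = {
        name: len(assays)
        for name, assays in zero_noise_corpus.ledger["strain_assay_counts"].items()
    }
    assert got == planted
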
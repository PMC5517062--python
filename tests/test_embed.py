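"""Embedding training, queries, semantic matrix and 2-D projection."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage

from vivominer.embed import (
    OOVError,
    Word2VecEmbedder,
    project_assays_2d,
    similarity_matrix,
)


def _cooccurrence_corpus(n=500, seed=0):
    """A and B always share contexts; C never appears with them."""
    rng = np.random.default_rng(seed)
    ctx1 = ["alpha", "beta", "gamma"]
    ctx2 = ["delta", "epsilon", "zeta"]
    corpus = []
    for _ in range(n):
        if rng.random() < 0.5:
            word = "tokA" if rng.random() < 0.5 else "tokB"
            corpus.append(list(rng.permutation(ctx1)) + [word])
        else:
            corpus.append(list(rng.permutation(ctx2)) + ["tokC"])
    return corpus


@pytest.fixture(scope="module")
def cooc_model():
    return Word2VecEmbedder(vector_size=30, min_count=5, epochs=10, seed=1).fit(
        _cooccurrence_corpus()
    )


def test_shared_context_tokens_are_closer(cooc_model):
    for seed in (2, 3, 4):
        m = Word2VecEmbedder(vector_size=30, min_count=5, epochs=10, seed=seed).fit(
            _cooccurrence_corpus(seed=seed)
        )
        assert m.cosine("tokA", "tokB") > m.cosine("tokA", "tokC")


def test_min_count_threshold_excludes_rare_tokens():
    corpus = [["common", "rare"]] * 29 + [["common", "filler"]] * 31
    m = Word2VecEmbedder(vector_size=10, min_count=30, epochs=1, seed=0).fit(corpus)
    assert "common" in m and "filler" in m and "rare" not in m


def test_empty_vocabulary_is_an_error():
    with pytest.raises(ValueError, match="empty vocabulary"):
        Word2VecEmbedder(min_count=30).fit([["a", "b"], ["c"]])


def test_self_cosine_is_one_and_query_excluded(cooc_model):
    for tok in cooc_model.vocabulary_:
        assert cooc_model.cosine(tok, tok) == pytest.approx(1.0, abs=1e-6)
    results = cooc_model.nearest_terms("tokA", k=len(cooc_model.vocabulary_))
    assert "tokA" not in [t for t, _ in results]
    sims = [s for _, s in results]
    assert sims == sorted(sims, reverse=True)


def test_oov_query_raises_named_error(cooc_model):
    with pytest.raises(OOVError, match="nonexistent"):
        cooc_model.nearest_terms("nonexistent")
    with pytest.raises(OOVError):
        cooc_model.analogy_query("tokA", "missing", "tokC")


def test_analogy_with_a_equal_b_reduces_to_nearest(cooc_model):
    got = cooc_model.analogy_query("tokA", "tokA", "tokC", k=3)
    expected = [t for t, _ in cooc_model.nearest_terms("tokC", k=5) if t != "tokA"][:3]
    assert [t for t, _ in got] == expected


def test_assay_vector_arithmetic_oracle(cooc_model):
    v1 = cooc_model.vector("tokA")
    v2 = cooc_model.vector("tokB")
    expected = (v1 + v2) / 2
    expected = expected / np.linalg.norm(expected)
    got, ok = cooc_model.assay_vector(["tokA", "tokB", "unseen-token"])
    assert ok
    np.testing.assert_allclose(got, expected, rtol=1e-5)
    assert np.linalg.norm(got) == pytest.approx(1.0, abs=1e-9)


def test_single_token_assay_vector_is_unit_token_vector(cooc_model):
    got, ok = cooc_model.assay_vector(["tokC"])
    v = cooc_model.vector("tokC")
    np.testing.assert_allclose(got, v / np.linalg.norm(v), rtol=1e-5)
    assert ok


def test_all_oov_gives_flagged_zero_vector(cooc_model):
    vec, ok = cooc_model.assay_vector(["nope", "nada"])
    assert not ok and not vec.any()


def test_training_reproducible_from_seed():
    corpus = _cooccurrence_corpus(n=200)
    m1 = Word2VecEmbedder(vector_size=20, min_count=5, epochs=3, seed=9).fit(corpus)
    m2 = Word2VecEmbedder(vector_size=20, min_count=5, epochs=3, seed=9).fit(corpus)
    np.testing.assert_array_equal(m1.vectors_, m2.vectors_)
    m3 = Word2VecEmbedder(vector_size=20, min_count=5, epochs=3, seed=10).fit(corpus)
    assert not np.array_equal(m1.vectors_, m3.vectors_)


def test_save_load_round_trip(tmp_path, cooc_model):
    p = tmp_path / "model.w2v.txt"
    cooc_model.save(p)
    loaded = Word2VecEmbedder.load(p)
    assert loaded.vocabulary_ == cooc_model.vocabulary_
    np.testing.assert_allclose(loaded.vectors_, cooc_model.vectors_, atol=1e-5)
    a = cooc_model.nearest_terms("tokA", 3)
    b = loaded.nearest_terms("tokA", 3)
    assert [t for t, _ in a] == [t for t, _ in b]


# -- semantic matrix ---------------------------------------------------------


def test_similarity_matrix_symmetric_unit_diagonal(cooc_model):
    terms = cooc_model.vocabulary_[:4]
    sm = similarity_matrix(cooc_model, terms, terms)
    np.testing.assert_allclose(sm.raw, sm.raw.T, atol=1e-6)
    np.testing.assert_allclose(np.diag(sm.raw), 1.0, atol=1e-6)
    assert sm.raw.min() >= -1 - 1e-9 and sm.raw.max() <= 1 + 1e-9


def test_zscored_rows_have_zero_mean_unit_variance(cooc_model):
    sm = similarity_matrix(cooc_model, cooc_model.vocabulary_[:3], cooc_model.vocabulary_)
    np.testing.assert_allclose(sm.zscored.mean(axis=1), 0.0, atol=1e-9)
    np.testing.assert_allclose(sm.zscored.std(axis=1), 1.0, atol=1e-9)


def test_linkage_equals_bruteforce_agglomeration(cooc_model):
    """3x3 case: the linkage tree equals exhaustive pairwise-merge agglomeration."""
    terms = cooc_model.vocabulary_[:3]
    sm = similarity_matrix(cooc_model, terms, cooc_model.vocabulary_[:5])
    z = sm.zscored
    # brute force: merge the closest pair, then the remaining pair; average
    # linkage distance between a singleton and a pair is the mean of the two
    # pointwise Euclidean distances
    d = {(i, j): np.linalg.norm(z[i] - z[j]) for i in range(3) for j in range(3) if i < j}
    (i0, j0), d0 = min(d.items(), key=lambda kv: kv[1])
    rest = ({0, 1, 2} - {i0, j0}).pop()
    d1 = (np.linalg.norm(z[rest] - z[i0]) + np.linalg.norm(z[rest] - z[j0])) / 2
    link = sm.row_linkage
    assert sorted(link[0, :2]) == sorted([i0, j0])
    assert link[0, 2] == pytest.approx(d0)
    assert link[1, 2] == pytest.approx(d1)
    # and agrees with scipy run independently on the same matrix
    np.testing.assert_allclose(link, linkage(z, method="average", metric="euclidean"))


def test_similarity_matrix_oov_error_lists_terms(cooc_model):
    with pytest.raises(OOVError, match="missing1"):
        similarity_matrix(cooc_model, ["tokA", "missing1"], ["tokB"])


# -- projection --------------------------------------------------------------


def test_rank2_matrix_is_lossless_through_pca():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(2, 30))
    X = rng.normal(size=(40, 2)) @ base  # rank 2
    coords, meta = project_assays_2d(X, seed=0)
    assert coords.shape == (40, 2)
    assert meta["pca_explained_variance_ratio_sum"] == pytest.approx(1.0, abs=1e-9)


def test_two_separated_clusters_stay_separated():
    from sklearn.metrics import silhouette_score

    rng = np.random.default_rng(1)
    a = rng.normal(0, 0.05, size=(30, 25)) + np.r_[np.ones(5), np.zeros(20)]
    b = rng.normal(0, 0.05, size=(30, 25)) - np.r_[np.ones(5), np.zeros(20)]
    X = np.vstack([a, b])
    labels = np.r_[np.zeros(30), np.ones(30)]
    coords, _ = project_assays_2d(X, seed=3)
    assert silhouette_score(coords, labels) > 0.5


def test_duplicated_rows_land_near_each_other():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 10))
    X = np.vstack([X, X[:1]])  # duplicate the first row
    coords, _ = project_assays_2d(X, seed=4, perplexity=5)
    dup = np.linalg.norm(coords[0] - coords[-1])
    others = np.linalg.norm(coords[1:-1] - coords[0], axis=1)
    assert dup <= others.min() + 1e-6


def test_fewer_than_three_vectors_rejected():
    with pytest.raises(ValueError):
        project_assays_2d(np.zeros((2, 5)), seed=0)


# -- planted structure on the synthetic corpus --------------------------------


def test_vocabulary_contains_joined_model_and_strain_tokens(trained_model):
    vocab = set(trained_model.vocabulary_)
    assert any(t.endswith("_induced") for t in vocab)
    assert any(t.endswith("_rat") or t.endswith("_mouse") for t in vocab)


def test_nearest_terms_of_a_disease_model_are_same_disease_area(trained_model):
    """Tokens sharing contexts (same class) dominate a model token's
    neighborhood — the Table-1-style rank property."""
    if "streptozotocin_induced" not in trained_model:
        pytest.skip("token below min_count at this seed")
    diabetes_vocab = {
        "alloxan_induced", "glucose_induced", "fructose_induced",
        "high_fat_diet_fed", "blood_glucose_level", "plasma_glucose_level",
        "hyperglycemia", "glucose_tolerance", "body_weight", "glycemia",
        "zdf_rat", "ob/ob_mouse", "db/db_mouse", "zucker_rat",
        "antihyperglycemic_activity", "reduction", "decrease",
    }
    top = [t for t, _ in trained_model.nearest_terms("streptozotocin_induced", 3)]
    assert any(t in diabetes_vocab for t in top), top
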
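"""End-to-end analysis workflows over a corpus.

Glue that wires the stages together in the canonical order: normalize and tag
the descriptions, extract entities, build embedding token streams, train the
embedding model, derive unit assay vectors, and run the downstream analyses
(NER evaluation, cross-validated ATC classification, drug-model network).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as classify_mod
from . import network as network_mod
from .corpus_io import corpus_stats
from .embed import Word2VecEmbedder
from .ner import NERPipeline, annotate_corpus, annotation_summary, evaluate_ner
from .preprocess import load_stopwords
from .synth import SyntheticConfig, SyntheticCorpus, generate_corpus

__all__ = ["CorpusArtifacts", "build_artifacts", "classification_accuracy"]

#: embedding settings for desk-scale synthetic corpora; skip-gram copes with
#: the small-corpus regime better than CBOW's context averaging
SMALL_CORPUS_EMBED = dict(vector_size=50, min_count=5, epochs=30, architecture="skipgram")


@dataclass
class CorpusArtifacts:
    corpus: SyntheticCorpus
    pipeline: NERPipeline
    mentions: pd.DataFrame
    streams: dict[str, list[str]]
    model: Word2VecEmbedder | None = None
    summary: dict = field(default_factory=dict)


def build_artifacts(
    config: SyntheticConfig,
    train_model: bool = True,
    embed_params: dict | None = None,
) -> CorpusArtifacts:
    """Generate a synthetic corpus and run the text pipeline over it."""
    corpus = generate_corpus(config)
    pipeline = NERPipeline(
        strain_dictionaries=[corpus.strain_dictionary()],
        phenotype_dictionary=corpus.phenotype_dictionary(),
    )
    mentions = annotate_corpus(corpus.assays, pipeline)
    stop = load_stopwords()
    streams = {
        a.assay_id: pipeline.embedding_tokens(a.description, a.assay_id, a.species, stop)
        for a in corpus.assays
    }
    model = None
    if train_model:
        params = dict(SMALL_CORPUS_EMBED)
        params.update(embed_params or {})
        model = Word2VecEmbedder(**params, seed=config.seed).fit(list(streams.values()))
    art = CorpusArtifacts(corpus, pipeline, mentions, streams, model)
    art.summary = annotation_summary(mentions)
    return art


def ner_scores(art: CorpusArtifacts, mode: str = "exact"):
    return evaluate_ner(art.mentions, art.corpus.gold, mode)


def classification_accuracy(
    art: CorpusArtifacts,
    problem: str = "top5_multiclass",
    split: str = "document",
    seed: int | None = None,
    n_trees: int = 100,
    permute_labels: bool = False,
) -> classify_mod.ClassificationReport:
    """Label the corpus, featurize with the trained embedder, cross-validate."""
    if art.model is None:
        raise ValueError("artifacts were built without an embedding model")
    seed = art.corpus.ledger["seed"] if seed is None else seed
    labeled, _ = classify_mod.assign_class_labels(
        art.corpus.assays, art.corpus.compounds, art.corpus.links,
        classify_mod.PROBLEMS[problem],
    )
    X = np.vstack([art.model.assay_vector(art.streams[a])[0] for a in labeled["assay_id"]])
    y = labeled["label"].to_numpy()
    if permute_labels:
        y = np.random.default_rng(seed).permutation(y)
    folds = classify_mod.make_folds(labeled, split, 10, seed=seed)
    return classify_mod.cross_validate_rf(
        X, y, folds, n_trees=n_trees, seed=seed, problem_name=problem, compute_oob=False
    )


def strict_classification_accuracy(
    art: CorpusArtifacts,
    problem: str = "top5_multiclass",
    split: str = "document",
    seed: int | None = None,
    n_trees: int = 100,
    embed_params: dict | None = None,
) -> float:
    """Leakage-free variant: the embedding model is retrained on each
    training fold's token streams only, so held-out text never influences the
    feature space. Stricter than the canonical protocol (which trains the
    embedding once on the full corpus); expect slightly lower accuracy.
    """
    from sklearn.ensemble import RandomForestClassifier

    seed = art.corpus.ledger["seed"] if seed is None else seed
    labeled, _ = classify_mod.assign_class_labels(
        art.corpus.assays, art.corpus.compounds, art.corpus.links,
        classify_mod.PROBLEMS[problem],
    )
    folds = classify_mod.make_folds(labeled, split, 10, seed=seed)
    params = dict(SMALL_CORPUS_EMBED)
    params.update(embed_params or {})
    ids = labeled["assay_id"].to_numpy()
    y = labeled["label"].to_numpy()
    correct = total = 0
    for f in range(folds.k):
        test = folds.fold == f
        if not test.any() or set(y[~test]) != set(y):
            continue
        model = Word2VecEmbedder(**params, seed=seed).fit(
            [art.streams[a] for a in ids[~test]]
        )
        X_train = np.vstack([model.assay_vector(art.streams[a])[0] for a in ids[~test]])
        X_test = np.vstack([model.assay_vector(art.streams[a])[0] for a in ids[test]])
        clf = RandomForestClassifier(
            n_estimators=n_trees, class_weight="balanced", random_state=seed, n_jobs=1
        ).fit(X_train, y[~test])
        pred = clf.predict(X_test)
        correct += int((pred == y[test]).sum())
        total += int(test.sum())
    return correct / total if total else 0.0


def network_sizes(art: CorpusArtifacts, min_assays: int = 5) -> tuple[int, int]:
    G = network_mod.build_network(
        art.mentions, art.corpus.assays, art.corpus.compounds, art.corpus.links,
        min_assays=min_assays,
    )
    return G.number_of_nodes(), G.number_of_edges()


def corpus_summary(art: CorpusArtifacts) -> dict:
    stats = corpus_stats(art.corpus.assays, art.corpus.compounds, art.corpus.links)
    out = stats.to_dict()
    out.update(art.summary)
    return out
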
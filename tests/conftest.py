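"""Shared fixtures: synthetic corpora and trained embedding models.

Expensive artifacts (corpus generation, embedding training) are session-scoped
so the suite builds them once.
"""

from __future__ import annotations

import pytest

from vivominer import embed, ner, synth
from vivominer.preprocess import load_stopwords

#: embedding settings for desk-scale synthetic corpora (skip-gram handles the
#: small-corpus regime; the 250-dim/min-count-30 defaults assume corpus scale)
SMALL_EMBED = dict(vector_size=50, min_count=5, epochs=30, architecture="skipgram")


def make_pipeline(corpus: synth.SyntheticCorpus) -> ner.NERPipeline:
    return ner.NERPipeline(
        strain_dictionaries=[corpus.strain_dictionary()],
        phenotype_dictionary=corpus.phenotype_dictionary(),
    )


def token_streams(corpus: synth.SyntheticCorpus, pipeline: ner.NERPipeline) -> dict[str, list[str]]:
    stop = load_stopwords()
    return {
        a.assay_id: pipeline.embedding_tokens(a.description, a.assay_id, a.species, stop)
        for a in corpus.assays
    }


@pytest.fixture(scope="session")
def zero_noise_corpus() -> synth.SyntheticCorpus:
    return synth.generate_corpus(
        synth.SyntheticConfig(
            seed=101, n_documents=60, acronym_rate=0.0,
            strain_synonym_rate=0.0, synonym_plant_rate=0.0,
        )
    )


@pytest.fixture(scope="session")
def noisy_corpus() -> synth.SyntheticCorpus:
    return synth.generate_corpus(synth.SyntheticConfig(seed=202, n_documents=120))


@pytest.fixture(scope="session")
def noisy_pipeline(noisy_corpus) -> ner.NERPipeline:
    return make_pipeline(noisy_corpus)


@pytest.fixture(scope="session")
def noisy_streams(noisy_corpus, noisy_pipeline) -> dict[str, list[str]]:
    return token_streams(noisy_corpus, noisy_pipeline)


@pytest.fixture(scope="session")
def trained_model(noisy_streams) -> embed.Word2VecEmbedder:
    return embed.Word2VecEmbedder(**SMALL_EMBED, seed=7).fit(list(noisy_streams.values()))
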
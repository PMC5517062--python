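"""Word embeddings for the assay-description corpus.

A compact word2vec trainer (CBOW or skip-gram with negative sampling,
implemented in numpy) learns dense vectors from the preprocessed token streams
— words, underscore-joined noun phrases, and normalized strain/model tokens.
Defaults follow the corpus-appropriate settings: window 5, minimum token
frequency 30, 250 dimensions. Cosine similarity between vectors approximates
semantic relatedness, vector arithmetic answers analogy queries
("a − b + c ≈ ?"), and an assay is represented by the unit-normalized mean of
its in-vocabulary token vectors.

:class:`Word2VecEmbedder` is a scikit-learn style transformer: ``fit`` trains
on a corpus of token lists, ``transform`` maps token lists to unit assay
vectors, so it composes directly with sklearn pipelines and model selection.

Training notes: the context window is sampled uniformly in [1, window] per
position (the standard trick that weights nearby words more); negatives are
drawn from the unigram distribution raised to 3/4; the learning rate decays
linearly. Training is single-threaded and fully reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "OOVError",
    "Word2VecEmbedder",
    "train_embeddings",
    "nearest_terms",
    "analogy_query",
    "assay_vector",
    "SemanticMatrix",
    "similarity_matrix",
    "project_assays_2d",
]


class OOVError(KeyError):
    """A query token is not in the embedding vocabulary."""

    def __init__(self, tokens):
        self.tokens = list(tokens)
        super().__init__(f"token(s) not in vocabulary: {', '.join(self.tokens)}")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class Word2VecEmbedder(BaseEstimator, TransformerMixin):
    """CBOW / skip-gram word embeddings with negative sampling.

    Parameters
    ----------
    vector_size : embedding dimensionality (default 250).
    window : maximum distance between the current and predicted word.
    min_count : minimum corpus frequency for a token to enter the vocabulary.
    architecture : "cbow" (default) or "skipgram".
    epochs : passes over the corpus.
    negative : negative samples per positive example.
    alpha, min_alpha : initial and final learning rate (linear decay).
    ns_exponent : exponent flattening the unigram noise distribution.
    seed : RNG seed; training is single-threaded and reproducible.

    Fitted attributes: ``vocabulary_`` (token list), ``vectors_`` (input
    vectors, shape (V, d)), ``index_`` (token -> row), ``counts_``.
    """

    def __init__(
        self,
        vector_size: int = 250,
        window: int = 5,
        min_count: int = 30,
        architecture: str = "cbow",
        epochs: int = 5,
        negative: int = 5,
        alpha: float = 0.025,
        min_alpha: float = 1e-4,
        ns_exponent: float = 0.75,
        seed: int = 0,
    ):
        self.vector_size = vector_size
        self.window = window
        self.min_count = min_count
        self.architecture = architecture
        self.epochs = epochs
        self.negative = negative
        self.alpha = alpha
        self.min_alpha = min_alpha
        self.ns_exponent = ns_exponent
        self.seed = seed

    # -- estimator API ------------------------------------------------------

    def fit(self, X: Sequence[Sequence[str]], y=None):
        if self.architecture not in ("cbow", "skipgram"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        counts: dict[str, int] = {}
        for sent in X:
            for tok in sent:
                counts[tok] = counts.get(tok, 0) + 1
        vocab = sorted(t for t, c in counts.items() if c >= self.min_count)
        if not vocab:
            raise ValueError(
                f"empty vocabulary: no token reaches min_count={self.min_count}"
            )
        self.vocabulary_ = vocab
        self.index_ = {t: i for i, t in enumerate(vocab)}
        self.counts_ = np.array([counts[t] for t in vocab], dtype=np.int64)

        rng = np.random.default_rng(self.seed)
        V, d = len(vocab), self.vector_size
        w_in = (rng.random((V, d), dtype=np.float64) - 0.5) / d
        w_out = np.zeros((V, d), dtype=np.float64)

        noise = self.counts_.astype(np.float64) ** self.ns_exponent
        noise_cdf = np.cumsum(noise / noise.sum())

        sents = [
            np.array([self.index_[t] for t in sent if t in self.index_], dtype=np.int64)
            for sent in X
        ]
        sents = [s for s in sents if len(s) >= 2]
        total = self.epochs * sum(len(s) for s in sents)
        step = 0
        k = self.negative
        for _ in range(self.epochs):
            for s in sents:
                L = len(s)
                reduced = rng.integers(1, self.window + 1, size=L)
                # one negative-sample block per sentence pass
                for pos in range(L):
                    lr = max(
                        self.min_alpha,
                        self.alpha * (1 - step / max(total, 1)),
                    )
                    step += 1
                    b = reduced[pos]
                    lo, hi = max(0, pos - b), min(L, pos + b + 1)
                    ctx = np.concatenate([s[lo:pos], s[pos + 1: hi]])
                    if len(ctx) == 0:
                        continue
                    center = s[pos]
                    negs = np.searchsorted(noise_cdf, rng.random(k))
                    if self.architecture == "cbow":
                        h = w_in[ctx].mean(axis=0)
                        targets = np.concatenate(([center], negs))
                        labels = np.zeros(k + 1)
                        labels[0] = 1.0
                        scores = _sigmoid(w_out[targets] @ h)
                        g = (labels - scores) * lr
                        grad_h = g @ w_out[targets]
                        w_out[targets] += np.outer(g, h)
                        w_in[ctx] += grad_h / len(ctx)
                    else:  # skip-gram: predict each context word from center
                        v = w_in[center]
                        grad_v = np.zeros(d)
                        for c in ctx:
                            targets = np.concatenate(([c], negs))
                            labels = np.zeros(k + 1)
                            labels[0] = 1.0
                            scores = _sigmoid(w_out[targets] @ v)
                            g = (labels - scores) * lr
                            grad_v += g @ w_out[targets]
                            w_out[targets] += np.outer(g, v)
                        w_in[center] += grad_v
        self.vectors_ = w_in.astype(np.float32)
        norms = np.linalg.norm(self.vectors_, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self._unit = self.vectors_ / norms
        self.training_meta_ = {
            "seed": self.seed, "architecture": self.architecture,
            "vector_size": self.vector_size, "window": self.window,
            "min_count": self.min_count, "epochs": self.epochs,
        }
        return self

    def transform(self, X: Sequence[Sequence[str]]) -> np.ndarray:
        """Unit assay vectors; an all-OOV token list maps to the zero vector."""
        return np.vstack([self.assay_vector(sent)[0] for sent in X])

    # -- queries ------------------------------------------------------------

    def __contains__(self, token: str) -> bool:
        return token in getattr(self, "index_", {})

    def vector(self, token: str) -> np.ndarray:
        if token not in self:
            raise OOVError([token])
        return self.vectors_[self.index_[token]]

    def cosine(self, a: str, b: str) -> float:
        missing = [t for t in (a, b) if t not in self]
        if missing:
            raise OOVError(missing)
        return float(self._unit[self.index_[a]] @ self._unit[self.index_[b]])

    def nearest_terms(self, query: str, k: int = 10) -> list[tuple[str, float]]:
        """k most similar vocabulary tokens, descending cosine, query excluded."""
        if query not in self:
            raise OOVError([query])
        qi = self.index_[query]
        sims = self._unit @ self._unit[qi]
        order = np.argsort(-sims, kind="stable")
        out = [
            (self.vocabulary_[i], float(sims[i])) for i in order if i != qi
        ]
        return out[:k]

    def analogy_query(self, a: str, b: str, c: str, k: int = 10) -> list[tuple[str, float]]:
        """Tokens ranked by cosine to vec(a) − vec(b) + vec(c); a, b, c excluded.

        Reads as "a is to b what ? is to c".
        """
        missing = [t for t in (a, b, c) if t not in self]
        if missing:
            raise OOVError(missing)
        target = (
            self._unit[self.index_[a]]
            - self._unit[self.index_[b]]
            + self._unit[self.index_[c]]
        )
        nrm = np.linalg.norm(target)
        if nrm > 0:
            target = target / nrm
        sims = self._unit @ target
        exclude = {self.index_[t] for t in (a, b, c)}
        order = np.argsort(-sims, kind="stable")
        out = [
            (self.vocabulary_[i], float(sims[i])) for i in order if i not in exclude
        ]
        return out[:k]

    def assay_vector(self, tokens: Sequence[str]) -> tuple[np.ndarray, bool]:
        """Unit-normalized mean of in-vocabulary token vectors.

        Returns (vector, in_vocabulary_flag); all-OOV input yields the zero
        vector flagged False — the degenerate contract.
        """
        idx = [self.index_[t] for t in tokens if t in self.index_]
        if not idx:
            return np.zeros(self.vector_size, dtype=np.float32), False
        v = self.vectors_[idx].mean(axis=0)
        n = np.linalg.norm(v)
        if n == 0:
            return np.zeros(self.vector_size, dtype=np.float32), False
        return (v / n).astype(np.float32), True

    # -- serialization (plain-text word2vec format) -------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"{len(self.vocabulary_)} {self.vector_size}\n")
            for tok, row in zip(self.vocabulary_, self.vectors_):
                fh.write(tok + " " + " ".join(f"{x:.6g}" for x in row) + "\n")
        meta = dict(self.training_meta_)
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "Word2VecEmbedder":
        path = Path(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        with path.open() as fh:
            n, d = map(int, fh.readline().split())
            vocab, rows = [], []
            for _ in range(n):
                parts = fh.readline().rstrip("\n").split(" ")
                vocab.append(parts[0])
                rows.append(np.array(parts[1:], dtype=np.float32))
        model = cls(
            vector_size=d,
            window=meta.get("window", 5),
            min_count=meta.get("min_count", 30),
            architecture=meta.get("architecture", "cbow"),
            epochs=meta.get("epochs", 5),
            seed=meta.get("seed", 0),
        )
        model.vocabulary_ = vocab
        model.index_ = {t: i for i, t in enumerate(vocab)}
        model.vectors_ = np.vstack(rows)
        model.counts_ = np.zeros(n, dtype=np.int64)
        norms = np.linalg.norm(model.vectors_, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        model._unit = model.vectors_ / norms
        model.training_meta_ = meta
        return model


# -- thin functional wrappers ------------------------------------------------


def train_embeddings(token_corpus, params: dict | None = None, seed: int = 0) -> Word2VecEmbedder:
    return Word2VecEmbedder(**(params or {}), seed=seed).fit(token_corpus)


def nearest_terms(model: Word2VecEmbedder, query: str, k: int = 10):
    return model.nearest_terms(query, k)


def analogy_query(model: Word2VecEmbedder, a: str, b: str, c: str, k: int = 10):
    return model.analogy_query(a, b, c, k)


def assay_vector(model: Word2VecEmbedder, tokens: Sequence[str]):
    return model.assay_vector(tokens)


# ---------------------------------------------------------------------------
# Clustered similarity matrix and 2-D projection
# ---------------------------------------------------------------------------


@dataclass
class SemanticMatrix:
    row_labels: list[str]
    col_labels: list[str]
    raw: np.ndarray            # cosine similarities, in [-1, 1]
    zscored: np.ndarray        # row-wise Z-scores of `raw`
    row_linkage: np.ndarray    # average linkage, Euclidean, on zscored rows
    col_linkage: np.ndarray    # same, on zscored columns
    col_linkage_raw: np.ndarray  # column dendrogram on the raw matrix


def similarity_matrix(
    model: Word2VecEmbedder, row_terms: Sequence[str], col_terms: Sequence[str]
) -> SemanticMatrix:
    """Pairwise cosine matrix with row-Z-scoring and hierarchical clustering.

    Rows and columns are clustered with average linkage on Euclidean distances
    of the Z-scored matrix; since it is ambiguous whether the column dendrogram
    should see raw or Z-scored values, both are computed.
    """
    missing = [t for t in [*row_terms, *col_terms] if t not in model]
    if missing:
        raise OOVError(sorted(set(missing)))
    R = np.vstack([model._unit[model.index_[t]] for t in row_terms]).astype(np.float64)
    R /= np.linalg.norm(R, axis=1, keepdims=True)
    C = np.vstack([model._unit[model.index_[t]] for t in col_terms]).astype(np.float64)
    C /= np.linalg.norm(C, axis=1, keepdims=True)
    raw = R @ C.T
    sd = raw.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (raw - raw.mean(axis=1, keepdims=True)) / sd
    row_link = linkage(z, method="average", metric="euclidean") if len(row_terms) > 1 else np.empty((0, 4))
    col_link = linkage(z.T, method="average", metric="euclidean") if len(col_terms) > 1 else np.empty((0, 4))
    col_link_raw = linkage(raw.T, method="average", metric="euclidean") if len(col_terms) > 1 else np.empty((0, 4))
    return SemanticMatrix(list(row_terms), list(col_terms), raw, z, row_link, col_link, col_link_raw)


def project_assays_2d(
    vectors: np.ndarray,
    seed: int = 0,
    n_components: int = 20,
    perplexity: float = 30.0,
) -> tuple[np.ndarray, dict]:
    """PCA to 20 dimensions (or the matrix rank if lower), then t-SNE to 2-D.

    Returns (coordinates, metadata with the seed and effective parameters).
    """
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE

    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("at least 3 vectors are required for 2-D projection")
    n_comp = int(min(n_components, X.shape[0], X.shape[1]))
    pca = PCA(n_components=n_comp, random_state=seed)
    reduced = pca.fit_transform(X)
    eff_perplexity = float(min(perplexity, max(2.0, (X.shape[0] - 1) / 3)))
    tsne = TSNE(
        n_components=2, random_state=seed, perplexity=eff_perplexity, init="pca"
    )
    coords = tsne.fit_transform(reduced)
    meta = {
        "seed": seed,
        "pca_components": n_comp,
        "perplexity": eff_perplexity,
        "pca_explained_variance_ratio_sum": float(pca.explained_variance_ratio_.sum()),
    }
    return coords, meta
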
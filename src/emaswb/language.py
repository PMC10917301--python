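"""Language features: LDA topic usage and document embeddings.

Documents are the free-text "current feelings" answers, pooled per
person-day (within-person analyses) or per person (between-person
analyses).  Two feature families are produced:

* **Topic usage** -- an LDA topic model is fit on 1-gram counts after
  removing the most frequent corpus words (the study protocol removes the
  top 75 and fits 200 topics for 750 iterations; smaller profiles are used
  for quick runs).  A document's usage vector is its normalized topic
  distribution; person-level usage is the token-weighted mean of the
  person's documents.
* **Embeddings** -- a pluggable encoder maps each document to a fixed-width
  vector (1536 features, mirroring a concatenation of the last two hidden
  layers of a RoBERTa-base encoder).  The tested path uses the
  deterministic synthetic encoder from :mod:`emaswb.synthetic_data`; a
  transformer adapter can be registered where the `transformers` stack is
  installed, and raises a :class:`CapabilityError` otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import DEFAULT_VOCABULARY, VocabularySpec, synthetic_encoder

__all__ = [
    "tokenize",
    "Corpus",
    "build_corpus",
    "top_stop_words",
    "TopicModel",
    "fit_lda",
    "person_topic_usage",
    "CapabilityError",
    "encode",
    "person_mean_embeddings",
]

_TOKEN_RE = re.compile(r"[a-z0-9']+")


def tokenize(text: str) -> list[str]:
    """Lowercased, punctuation-stripped unigram tokens."""
    if not isinstance(text, str):
        return []
    return _TOKEN_RE.findall(text.lower())


@dataclass
class Corpus:
    """Aligned document ids, token lists and metadata."""

    ids: list
    docs: list[list[str]]
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.docs):
            raise ValueError("ids and docs are misaligned")

    def __len__(self) -> int:
        return len(self.docs)


def build_corpus(days: pd.DataFrame, level: str = "day") -> Corpus:
    """Corpus from day records: one document per person-day or per person.

    Empty documents are dropped (a 200-character minimum applies upstream
    in the protocol this emulates).
    """
    if level == "day":
        ids = list(zip(days["participant_id"], days["wave"], days["day_index"]))
        texts = days["text"].tolist()
        meta = days[["participant_id", "wave", "day_index"]].copy()
    elif level == "person":
        grouped = days.groupby("participant_id")["text"].apply(
            lambda s: " ".join(t for t in s if isinstance(t, str)))
        ids = grouped.index.tolist()
        texts = grouped.tolist()
        meta = pd.DataFrame({"participant_id": ids})
    else:
        raise ValueError("level must be 'day' or 'person'")
    docs = [tokenize(t) for t in texts]
    keep = [i for i, d in enumerate(docs) if d]
    return Corpus(ids=[ids[i] for i in keep], docs=[docs[i] for i in keep],
                  meta=meta.iloc[keep].reset_index(drop=True))


def top_stop_words(docs: list[list[str]], n: int = 75) -> list[str]:
    """The ``n`` highest-frequency corpus words; frequency ties broken
    lexicographically."""
    counts: dict[str, int] = {}
    for doc in docs:
        for tok in doc:
            counts[tok] = counts.get(tok, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [w for w, _ in ranked[:n]]


@dataclass
class TopicModel:
    """Fitted LDA: word-topic weights and per-document topic usage."""

    vocab: list[str]
    topic_word: np.ndarray    # (k, V), rows sum to 1
    doc_topic: np.ndarray     # (D, k), rows sum to 1
    doc_ids: list
    doc_lengths: np.ndarray   # retained-token counts per document
    stop_words: list[str]
    k: int
    iterations: int
    seed: int

    def top_words(self, topic: int, m: int = 6) -> list[tuple[str, float]]:
        """Ranked (word, weight) list for one topic; ties lexicographic."""
        w = self.topic_word[topic]
        order = sorted(range(len(self.vocab)), key=lambda j: (-w[j], self.vocab[j]))
        return [(self.vocab[j], float(w[j])) for j in order[:m]]


def _count_matrix(docs: list[list[str]], vocab: list[str]) -> np.ndarray:
    index = {w: j for j, w in enumerate(vocab)}
    X = np.zeros((len(docs), len(vocab)), dtype=np.int64)
    for i, doc in enumerate(docs):
        for tok in doc:
            j = index.get(tok)
            if j is not None:
                X[i, j] += 1
    return X


def fit_lda(corpus: Corpus, k: int = 200, stop_top: int = 75,
            iters: int = 750, seed: int = 0) -> TopicModel:
    """Fit an LDA topic model on 1-gram counts.

    The ``stop_top`` most frequent corpus words are removed before
    fitting.  Inference is batch variational EM with symmetric priors
    (``alpha = 50/k``, ``eta = 0.01``); deterministic given ``seed``.
    Documents left empty after stop-word removal are dropped.
    """
    from sklearn.decomposition import LatentDirichletAllocation

    if k < 2:
        raise ValueError("k must be >= 2")
    stop = set(top_stop_words(corpus.docs, stop_top)) if stop_top else set()
    vocab = sorted({t for doc in corpus.docs for t in doc} - stop)
    if len(vocab) < k:
        raise ValueError(
            f"k={k} exceeds the post-stop-list vocabulary size {len(vocab)}")
    X = _count_matrix(corpus.docs, vocab)
    lengths = X.sum(axis=1)
    keep = lengths > 0
    X = X[keep]
    ids = [corpus.ids[i] for i in np.flatnonzero(keep)]

    lda = LatentDirichletAllocation(
        n_components=k, max_iter=iters, random_state=seed,
        doc_topic_prior=min(50.0 / k, 1.0), topic_word_prior=0.01,
        learning_method="batch", evaluate_every=-1)
    usage = lda.fit_transform(X)
    usage = usage / usage.sum(axis=1, keepdims=True)
    topic_word = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return TopicModel(vocab=vocab, topic_word=topic_word, doc_topic=usage,
                      doc_ids=ids, doc_lengths=lengths[keep],
                      stop_words=sorted(stop), k=k, iterations=iters, seed=seed)


def person_topic_usage(model: TopicModel, person_ids) -> pd.DataFrame:
    """Person-level topic usage: token-weighted mean of document usages.

    ``person_ids`` maps each of the model's documents to a person; rows of
    the result sum to 1.  Persons with no documents simply do not appear.
    """
    pid = np.asarray(person_ids)
    if pid.shape[0] != model.doc_topic.shape[0]:
        raise ValueError("person_ids misaligned with the model's documents")
    w = model.doc_lengths.astype(float)
    df = pd.DataFrame(model.doc_topic * w[:, None])
    df["_w"] = w
    df["_p"] = pid
    agg = df.groupby("_p").sum()
    usage = agg.drop(columns="_w").to_numpy() / agg["_w"].to_numpy()[:, None]
    out = pd.DataFrame(usage, index=agg.index,
                       columns=[f"topic_{j}" for j in range(model.k)])
    out.index.name = "participant_id"
    return out


class CapabilityError(RuntimeError):
    """An optional encoder backend is not available in this environment."""


def encode(corpus: Corpus, encoder: str = "synthetic", dim: int = 1536,
           seed: int = 0, vocab: VocabularySpec = DEFAULT_VOCABULARY
           ) -> pd.DataFrame:
    """One embedding row per document (index = document id).

    ``encoder='synthetic'`` uses the deterministic planted-signal encoder;
    ``encoder='transformer'`` requires the optional transformers stack and
    raises :class:`CapabilityError` when absent -- never a silent fallback.
    """
    if encoder == "synthetic":
        rows = [synthetic_encoder(doc, dim=dim, seed=seed, vocab=vocab)
                for doc in corpus.docs]
    elif encoder == "transformer":
        try:
            import transformers  # noqa: F401
        except ImportError as exc:
            raise CapabilityError(
                "the transformer encoder requires the 'transformers' package; "
                "install it or use encoder='synthetic'") from exc
        raise CapabilityError(
            "transformer adapter registered but no weights are shipped; "
            "supply an encoder callable via encode_with")
    else:
        raise ValueError(f"unknown encoder {encoder!r}")
    X = np.vstack(rows)
    return pd.DataFrame(X, index=pd.Index(corpus.ids, name="doc_id", tupleize_cols=False))


def person_mean_embeddings(emb: pd.DataFrame, person_ids) -> pd.DataFrame:
    """Mean embedding over each person's documents."""
    pid = np.asarray(person_ids)
    if pid.shape[0] != emb.shape[0]:
        raise ValueError("person_ids misaligned with embeddings")
    out = emb.groupby(pid).mean()
    out.index.name = "participant_id"
    return out
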
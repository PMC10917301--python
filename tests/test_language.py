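import numpy as np
import pandas as pd
import pytest

from emaswb import language as lang
from emaswb.synthetic_data import (
    DEFAULT_VOCABULARY,
    VocabularySpec,
    generate_text,
    synthetic_encoder,
    topic_mixture,
)


class TestTokenize:
    @pytest.mark.parametrize("text,expected", [
        ("I feel SAD, sad.", ["i", "feel", "sad", "sad"]),
        ("", []),
        ("don't stop!", ["don't", "stop"]),
    ])
    def test_examples(self, text, expected):
        assert lang.tokenize(text) == expected

    def test_counts_match_reference_oracle(self):
        import re

        rng = np.random.default_rng(0)
        words = ["Happy", "sad!", "WORK,", "ok."]
        for _ in range(100):
            doc = " ".join(rng.choice(words, size=rng.integers(0, 20)))
            oracle = [w for w in re.sub(r"[^\w'\s]", " ", doc.lower()).split()
                      if w]
            assert lang.tokenize(doc) == oracle


class TestGenerateText:
    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            VocabularySpec(topics={}, loadings={})

    def test_zero_loadings_give_uniform_mixture(self):
        w = topic_mixture({}, DEFAULT_VOCABULARY)
        np.testing.assert_allclose(w, 1.0 / len(w))

    def test_negative_day_makes_sad_topic_modal(self):
        # analytic check on the softmax weights themselves
        state = {"swb_day": -3.0, "trait_swb": -1.0}
        w = topic_mixture(state, DEFAULT_VOCABULARY)
        names = DEFAULT_VOCABULARY.topic_names
        assert names[int(np.argmax(w))] == "sad_anxious"

    def test_document_length_and_vocabulary(self):
        rng = np.random.default_rng(1)
        toks = generate_text({"swb_day": 1.0}, DEFAULT_VOCABULARY, rng)
        assert len(toks) == DEFAULT_VOCABULARY.tokens_per_doc >= 30
        allowed = set(DEFAULT_VOCABULARY.filler_words)
        for ws in DEFAULT_VOCABULARY.topics.values():
            allowed |= set(ws)
        assert set(toks) <= allowed


class TestSyntheticEncoder:
    def test_deterministic(self):
        toks = ["friends", "dinner", "fun"]
        a = synthetic_encoder(toks, dim=64, seed=5)
        b = synthetic_encoder(toks, dim=64, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_pure_topic_documents_nearly_parallel(self):
        words = DEFAULT_VOCABULARY.topics["sad_anxious"]
        a = synthetic_encoder(list(words[:6]) * 5, dim=256, seed=0,
                              noise_sd=1e-6)
        b = synthetic_encoder(list(words[6:]) * 5, dim=256, seed=0,
                              noise_sd=1e-6)
        cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos > 0.99

    def test_empty_document_is_noise_around_zero(self):
        v = synthetic_encoder([], dim=128, seed=1, noise_sd=0.05)
        assert np.linalg.norm(v) < 0.05 * np.sqrt(128) * 2


class TestCorpus:
    def test_person_level_concatenates_documents(self, day_records):
        day = lang.build_corpus(day_records, "day")
        person = lang.build_corpus(day_records, "person")
        assert len(person) == day.meta.participant_id.nunique()
        total_day = sum(len(d) for d in day.docs)
        total_person = sum(len(d) for d in person.docs)
        assert total_day == total_person

    def test_no_empty_documents(self, day_records):
        corpus = lang.build_corpus(day_records, "day")
        assert all(len(d) > 0 for d in corpus.docs)


class TestStopWords:
    def test_highest_frequency_and_ties_lexicographic(self):
        docs = [["b", "b", "a", "a", "c"], ["d", "b"]]
        assert lang.top_stop_words(docs, 2) == ["b", "a"]
        # tie between a and b at the cut: lexicographic
        docs = [["a", "b"], ["b", "a"], ["c"]]
        assert lang.top_stop_words(docs, 1) == ["a"]


def _planted_corpus(n_docs=1500, seed=0, k_true=5):
    """Documents drawn from one planted topic each (no fillers)."""
    names = list(DEFAULT_VOCABULARY.topics)[:k_true]
    vocab = VocabularySpec(
        topics={n: DEFAULT_VOCABULARY.topics[n] for n in names},
        loadings={n: {} for n in names}, filler_words=(), filler_rate=0.0,
        tokens_per_doc=30, doc_topic_noise=0.0, person_style_noise=0.0)
    rng = np.random.default_rng(seed)
    docs, labels = [], []
    for i in range(n_docs):
        topic = names[i % k_true]
        words = vocab.topics[topic]
        p = 1.0 / np.arange(1, len(words) + 1)
        p /= p.sum()
        docs.append(list(rng.choice(words, size=30, p=p)))
        labels.append(topic)
    corpus = lang.Corpus(ids=list(range(n_docs)), docs=docs)
    return corpus, labels, vocab, names


class TestLda:
    def test_usage_rows_sum_to_one(self, day_records):
        corpus = lang.build_corpus(day_records.head(300), "day")
        model = lang.fit_lda(corpus, k=5, stop_top=10, iters=30, seed=0)
        np.testing.assert_allclose(model.doc_topic.sum(axis=1), 1.0,
                                   atol=1e-9)
        np.testing.assert_allclose(model.topic_word.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_k_exceeding_vocabulary_rejected(self):
        corpus = lang.Corpus(ids=[0, 1], docs=[["a", "b"], ["b", "c"]])
        with pytest.raises(ValueError):
            lang.fit_lda(corpus, k=10, stop_top=0, iters=5)

    def test_deterministic_given_seed(self):
        corpus, _, _, _ = _planted_corpus(n_docs=200)
        m1 = lang.fit_lda(corpus, k=3, stop_top=0, iters=20, seed=7)
        m2 = lang.fit_lda(corpus, k=3, stop_top=0, iters=20, seed=7)
        np.testing.assert_array_equal(m1.doc_topic, m2.doc_topic)

    def test_single_topic_corpus_recovered(self):
        # a one-topic corpus is fully explained: either one component
        # dominates, or (symmetric variational solutions) every component
        # reproduces the planted word distribution
        rng = np.random.default_rng(2)
        words = DEFAULT_VOCABULARY.topics["work_routine"]
        docs = [list(rng.choice(words, size=25)) for _ in range(300)]
        corpus = lang.Corpus(ids=list(range(300)), docs=docs)
        model = lang.fit_lda(corpus, k=2, stop_top=0, iters=100, seed=0)
        share = model.doc_topic.mean(axis=0)
        true = np.zeros(len(model.vocab))
        uniq, counts = np.unique(np.concatenate(docs), return_counts=True)
        for w, c in zip(uniq, counts):
            true[model.vocab.index(w)] = c
        true = true / true.sum()
        mixture = share @ model.topic_word
        mix_cos = mixture @ true / (np.linalg.norm(mixture)
                                    * np.linalg.norm(true))
        assert share.max() > 0.9 or mix_cos > 0.99

    def test_planted_topic_recovery_hungarian_cosine(self):
        from scipy.optimize import linear_sum_assignment

        corpus, _, vocab, names = _planted_corpus(n_docs=2000, seed=3)
        model = lang.fit_lda(corpus, k=5, stop_top=0, iters=200, seed=0)
        # true topic-word distributions on the model's vocabulary
        true = np.zeros((5, len(model.vocab)))
        for i, name in enumerate(names):
            words = vocab.topics[name]
            p = 1.0 / np.arange(1, len(words) + 1)
            p /= p.sum()
            for w, pw in zip(words, p):
                if w in model.vocab:
                    true[i, model.vocab.index(w)] = pw
        est = model.topic_word
        cos = (true / np.linalg.norm(true, axis=1, keepdims=True)) @ \
            (est / np.linalg.norm(est, axis=1, keepdims=True)).T
        ri, ci = linear_sum_assignment(-cos)
        assert cos[ri, ci].min() > 0.8


class TestPersonUsage:
    def test_single_document_person_equals_document_usage(self):
        corpus, _, _, _ = _planted_corpus(n_docs=40)
        model = lang.fit_lda(corpus, k=3, stop_top=0, iters=20, seed=0)
        pids = [f"p{i:03d}" for i in range(len(model.doc_ids))]
        usage = lang.person_topic_usage(model, pids)
        np.testing.assert_allclose(usage.loc[pids].to_numpy(),
                                   model.doc_topic, atol=1e-12)

    def test_two_equal_length_documents_average(self):
        corpus, _, _, _ = _planted_corpus(n_docs=40)
        model = lang.fit_lda(corpus, k=3, stop_top=0, iters=20, seed=0)
        pid = [f"p{i // 2}" for i in range(len(model.doc_ids))]
        usage = lang.person_topic_usage(model, pid)
        expect = (model.doc_topic[0] + model.doc_topic[1]) / 2
        np.testing.assert_allclose(usage.loc["p0"].to_numpy(), expect,
                                   atol=1e-12)

    def test_rows_are_stochastic(self, day_records):
        corpus = lang.build_corpus(day_records.head(400), "day")
        model = lang.fit_lda(corpus, k=4, stop_top=5, iters=25, seed=1)
        pid = [i[0] for i in model.doc_ids]
        usage = lang.person_topic_usage(model, pid)
        np.testing.assert_allclose(usage.sum(axis=1), 1.0, atol=1e-9)


class TestEncode:
    def test_encode_deterministic(self, day_records):
        corpus = lang.build_corpus(day_records.head(50), "day")
        a = lang.encode(corpus, dim=32, seed=9)
        b = lang.encode(corpus, dim=32, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_person_mean_of_identical_documents(self):
        corpus = lang.Corpus(ids=[0, 1], docs=[["sad", "down"]] * 2)
        emb = lang.encode(corpus, dim=16, seed=0)
        pm = lang.person_mean_embeddings(emb, ["p", "p"])
        np.testing.assert_allclose(pm.iloc[0].to_numpy(),
                                   emb.iloc[0].to_numpy(), atol=1e-12)

    def test_featurewise_within_centering_zeroes_person_means(self):
        from emaswb.stats import within_center

        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((40, 4)))
        df["participant_id"] = np.repeat(list("abcd"), 10)
        cent = within_center(df, [0, 1, 2, 3])
        means = cent.groupby("participant_id")[[0, 1, 2, 3]].mean()
        assert np.abs(means.to_numpy()).max() < 1e-12

    def test_transformer_adapter_capability_error(self, day_records):
        corpus = lang.build_corpus(day_records.head(5), "day")
        with pytest.raises((lang.CapabilityError,)):
            lang.encode(corpus, encoder="transformer")
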
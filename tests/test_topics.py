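"""Document-term matrix, TF-IDF pruning, Gibbs LDA and topic analytics."""

import math
import warnings

import numpy as np
import pytest

from emotopic.errors import ParameterError
from emotopic.lexicons import HappinessLexicon
from emotopic import topics as tp
from tests.conftest import make_corpus


def _results_from_phi_theta(phi, theta, vocab=None):
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    K, V = phi.shape
    vocab = tuple(vocab) if vocab else tuple(f"w{i}" for i in range(V))
    return tp.TopicModelResults(
        K=K,
        alpha=50.0 / K,
        beta=0.1,
        seed=0,
        vocab=vocab,
        doc_ids=tuple(f"d{i}" for i in range(theta.shape[0])),
        topic_word=phi,
        doc_topic=theta,
        assignments=np.zeros(1, dtype=np.int64),
        loglik_samples=np.zeros(1),
        loglik_trace=np.zeros(1),
    )


class TestBuildDtm:
    def test_hand_tally(self):
        dtm = tp.build_dtm([["a", "b"], ["b", "b"]])
        assert dtm.vocab == ("a", "b")
        assert dtm.counts.toarray().tolist() == [[1, 1], [0, 2]]

    def test_min_count_threshold(self):
        dtm = tp.build_dtm([["a", "b"], ["b", "b"]], min_count=2)
        assert dtm.vocab == ("b",)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ParameterError):
            tp.build_dtm([])

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(17)
        vocab = [f"w{i}" for i in range(12)]
        docs = [
            list(rng.choice(vocab, size=rng.integers(0, 15))) for _ in range(25)
        ]
        dtm = tp.build_dtm(docs)
        dense = dtm.counts.toarray()
        for d, doc in enumerate(docs):
            for j, word in enumerate(dtm.vocab):
                assert dense[d, j] == doc.count(word)
        assert list(dtm.vocab) == sorted(set(dtm.vocab))
        assert not (dense.sum(axis=0) == 0).any()


class TestTfidfFilter:
    def test_ubiquitous_term_removed(self):
        # a term in every document has idf 0, score 0 <= 0.1
        dtm = tp.build_dtm([["every", "x"], ["every", "y"], ["every", "z"]])
        filtered = tp.tfidf_filter(dtm, 0.1)
        assert "every" not in filtered.vocab

    def test_hand_computed_scores(self):
        docs = [["a", "a", "b"], ["b", "c"]]
        dtm = tp.build_dtm(docs)
        scores = dict(zip(dtm.vocab, tp.tfidf_scores(dtm)))
        assert scores["a"] == pytest.approx((2 / 3) * math.log2(2))
        assert scores["b"] == pytest.approx(
            np.mean([1 / 3, 1 / 2]) * math.log2(1)
        )
        assert scores["c"] == pytest.approx((1 / 2) * math.log2(2))

    def test_threshold_infinite_empties_vocabulary(self):
        dtm = tp.build_dtm([["a", "b"], ["c"]])
        with pytest.raises(ParameterError, match="vocabulary"):
            tp.tfidf_filter(dtm, math.inf)

    def test_negative_threshold_rejected(self):
        dtm = tp.build_dtm([["a"]])
        with pytest.raises(ParameterError):
            tp.tfidf_filter(dtm, -0.5)

    def test_keeps_above_drops_at_or_below_exhaustively(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            vocab = [f"w{i}" for i in range(8)]
            docs = [
                list(rng.choice(vocab, size=rng.integers(1, 10)))
                for _ in range(6)
            ]
            dtm = tp.build_dtm(docs)
            scores = dict(zip(dtm.vocab, tp.tfidf_scores(dtm)))
            threshold = float(np.median(list(scores.values())))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    filtered = tp.tfidf_filter(dtm, threshold)
                except ParameterError:
                    continue  # fully emptied vocabulary
            kept = set(filtered.vocab)
            for word, s in scores.items():
                assert (word in kept) == (s > threshold)

    def test_emptied_documents_dropped_and_recorded(self):
        docs = [["every", "unique1"], ["every"], ["every", "unique3"]]
        dtm = tp.build_dtm(docs)
        with pytest.warns(UserWarning, match="dropped"):
            filtered = tp.tfidf_filter(dtm, 0.1)
        assert filtered.dropped_doc_ids == ("d1",)
        assert filtered.shape[0] == 2


class TestGibbsLDA:
    def test_k1_recovers_corpus_frequencies(self):
        docs = [["a", "a", "b"], ["b", "c"]]
        dtm = tp.build_dtm(docs)
        res = tp.fit_lda_gibbs(dtm, 1, beta=1e-8, n_iter=5, burn_in=2, seed=0)
        freqs = np.array([2, 2, 1]) / 5
        assert res.topic_word[0] == pytest.approx(freqs, abs=1e-6)
        assert res.doc_topic == pytest.approx(np.ones((2, 1)))

    def test_disjoint_vocabularies_separate(self):
        rng = np.random.default_rng(5)
        block_a = [f"a{i}" for i in range(10)]
        block_b = [f"b{i}" for i in range(10)]
        docs = []
        for _ in range(40):
            docs.append(list(rng.choice(block_a, size=20)))
            docs.append(list(rng.choice(block_b, size=20)))
        dtm = tp.build_dtm(docs)
        res = tp.fit_lda_gibbs(dtm, 2, alpha=1.0, n_iter=150, burn_in=75, seed=1)
        a_idx = [i for i, w in enumerate(dtm.vocab) if w.startswith("a")]
        masses = res.topic_word[:, a_idx].sum(axis=1)
        assert max(masses) > 0.95 and min(masses) < 0.05

    def test_same_seed_bit_identical(self):
        docs = [["a", "b", "c"], ["c", "d"], ["a", "d", "d"]]
        dtm = tp.build_dtm(docs)
        r1 = tp.fit_lda_gibbs(dtm, 2, n_iter=30, burn_in=10, seed=7)
        r2 = tp.fit_lda_gibbs(dtm, 2, n_iter=30, burn_in=10, seed=7)
        assert (r1.assignments == r2.assignments).all()
        assert (r1.topic_word == r2.topic_word).all()

    def test_row_sums_are_distributions(self):
        docs = [["a", "b", "c", "d"] * 3 for _ in range(10)]
        dtm = tp.build_dtm(docs)
        res = tp.fit_lda_gibbs(dtm, 3, n_iter=20, burn_in=10, seed=3)
        assert np.allclose(res.topic_word.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(res.doc_topic.sum(axis=1), 1.0, atol=1e-9)

    def test_parameter_domain(self):
        dtm = tp.build_dtm([["a", "b"]])
        with pytest.raises(ParameterError):
            tp.GibbsLDA(dtm, 0)
        with pytest.raises(ParameterError):
            tp.GibbsLDA(dtm, 5)  # K > V
        with pytest.raises(ParameterError):
            tp.GibbsLDA(dtm, 2).fit(n_iter=10, burn_in=10)


class TestSelectK:
    def test_identical_topic_rows_forced_values(self):
        phi = np.array([[0.5, 0.3, 0.2], [0.5, 0.3, 0.2]])
        assert tp._caojuan(phi) == pytest.approx(1.0)
        assert tp._deveaud(phi) == pytest.approx(0.0)

    def test_jensen_shannon_matches_direct_summation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = rng.dirichlet(np.ones(20))
            q = rng.dirichlet(np.ones(20))
            m = 0.5 * (p + q)
            direct = 0.5 * sum(
                pi * math.log(pi / mi) for pi, mi in zip(p, m) if pi > 0
            ) + 0.5 * sum(qi * math.log(qi / mi) for qi, mi in zip(q, m) if qi > 0)
            assert tp.jensen_shannon(p, q) == pytest.approx(direct, abs=1e-9)

    def test_planted_k_favored(self):
        # 3 disjoint planted topics; CaoJuan should prefer K near 3 over K=6
        rng = np.random.default_rng(11)
        blocks = [[f"t{k}w{i}" for i in range(8)] for k in range(3)]
        docs = [list(rng.choice(blocks[d % 3], size=15)) for d in range(60)]
        dtm = tp.build_dtm(docs)
        report = tp.select_k(dtm, [2, 3, 6], n_iter=80, burn_in=40, seed=2)
        assert report.loc[3, "caojuan2009"] < report.loc[6, "caojuan2009"]
        assert set(report.columns) == {
            "griffiths2004", "caojuan2009", "arun2010", "deveaud2014"
        }

    def test_empty_candidates_rejected(self):
        dtm = tp.build_dtm([["a", "b"]])
        with pytest.raises(ParameterError):
            tp.select_k(dtm, [])


class TestPrevalence:
    def test_identical_groups_null(self):
        theta = np.tile([0.25, 0.75], (40, 1))
        res = _results_from_phi_theta(np.full((2, 4), 0.25), theta)
        gender = ["woman"] * 20 + ["man"] * 20
        prev = tp.estimate_prevalence(res, gender, n_boot=100, seed=0)
        assert prev["effect"].abs().max() == 0.0
        assert (prev["label"] == "indeterminate").all()

    def test_label_swap_negates_effects(self):
        rng = np.random.default_rng(8)
        theta = rng.dirichlet(np.ones(3), size=30)
        res = _results_from_phi_theta(np.full((3, 4), 0.25), theta)
        gender = np.where(np.arange(30) % 2 == 0, "woman", "man")
        swapped = np.where(gender == "woman", "man", "woman")
        e1 = tp.estimate_prevalence(res, gender, n_boot=50, seed=0)["effect"]
        e2 = tp.estimate_prevalence(res, swapped, n_boot=50, seed=0)["effect"]
        assert np.allclose(e1.to_numpy(), -e2.to_numpy())

    def test_effects_sum_to_zero(self):
        rng = np.random.default_rng(9)
        theta = rng.dirichlet(np.ones(5), size=50)
        res = _results_from_phi_theta(np.full((5, 4), 0.25), theta)
        gender = np.where(rng.random(50) < 0.5, "woman", "man")
        if len(set(gender)) < 2:  # pragma: no cover
            gender[0] = "woman"
            gender[1] = "man"
        prev = tp.estimate_prevalence(res, gender, n_boot=50, seed=0)
        assert abs(prev["effect"].sum()) < 1e-9

    def test_single_gender_rejected(self):
        theta = np.tile([0.5, 0.5], (4, 1))
        res = _results_from_phi_theta(np.full((2, 4), 0.25), theta)
        with pytest.raises(ParameterError):
            tp.estimate_prevalence(res, ["woman"] * 4, n_boot=10)


class TestLabelTopics:
    def test_k1_all_orderings_are_frequency_order(self):
        phi = np.array([[0.4, 0.3, 0.2, 0.1]])
        res = _results_from_phi_theta(phi, np.ones((3, 1)), vocab="abcd")
        prof = tp.label_topics(res, n=4)
        assert prof.prob[0] == list("abcd")
        assert prof.frex[0] == list("abcd")
        assert prof.score[0] == list("abcd")

    def test_frex_weight_zero_is_frequency_order(self):
        rng = np.random.default_rng(4)
        phi = rng.dirichlet(np.ones(6), size=3)
        res = _results_from_phi_theta(phi, rng.dirichlet(np.ones(3), size=5))
        prof = tp.label_topics(res, n=6, frex_weight=0.0)
        for k in range(3):
            assert prof.frex[k] == prof.prob[k]

    def test_three_topic_hand_oracle(self):
        phi = np.array(
            [
                [0.50, 0.20, 0.10, 0.10, 0.05, 0.05],
                [0.10, 0.40, 0.30, 0.10, 0.05, 0.05],
                [0.05, 0.05, 0.10, 0.20, 0.30, 0.30],
            ]
        )
        vocab = ["u", "v", "w", "x", "y", "z"]
        res = _results_from_phi_theta(phi, np.ones((3, 3)) / 3, vocab=vocab)
        prof = tp.label_topics(res, n=6, frex_weight=0.5)
        # independent recomputation with explicit loops
        ex = phi / phi.sum(axis=0, keepdims=True)
        for k in range(3):
            order_prob = sorted(
                range(6), key=lambda j: (-phi[k, j], vocab[j])
            )
            assert prof.prob[k] == [vocab[j] for j in order_prob]
            ecdf = lambda vals, j: sum(v <= vals[j] for v in vals) / len(vals)
            frex_vals = [
                1.0
                / (
                    0.5 / ecdf(list(ex[k]), j)
                    + 0.5 / ecdf(list(phi[k]), j)
                )
                for j in range(6)
            ]
            order_frex = sorted(
                range(6), key=lambda j: (-frex_vals[j], -phi[k, j], vocab[j])
            )
            assert prof.frex[k] == [vocab[j] for j in order_frex]
            score_vals = [
                phi[k, j]
                * (math.log(phi[k, j]) - np.mean([math.log(phi[i, j]) for i in range(3)]))
                for j in range(6)
            ]
            order_score = sorted(
                range(6), key=lambda j: (-score_vals[j], -phi[k, j], vocab[j])
            )
            assert prof.score[k] == [vocab[j] for j in order_score]

    def test_n_exceeding_vocabulary_rejected(self):
        res = _results_from_phi_theta(np.array([[0.5, 0.5]]), np.ones((2, 1)))
        with pytest.raises(ParameterError):
            tp.label_topics(res, n=3)


class TestSemanticCoherence:
    def test_always_cooccurring_words_maximal(self):
        docs = [["p", "q", "r"], ["p", "q", "s"], ["p", "q", "t"]]
        dtm = tp.build_dtm(docs)
        phi = np.zeros((1, len(dtm.vocab)))
        phi[0, dtm.vocab.index("p")] = 0.6
        phi[0, dtm.vocab.index("q")] = 0.4
        res = _results_from_phi_theta(phi, np.ones((3, 1)), vocab=dtm.vocab)
        c = tp.semantic_coherence(res, dtm, top_m=2)
        # top words p, q: D(q)=3, D(p,q)=3 -> log(4/3), the maximum given D(q)=3
        assert c[0] == pytest.approx(math.log(4 / 3))

    def test_never_cooccurring_hand_value(self):
        docs = [["p"], ["q"]]
        dtm = tp.build_dtm(docs)
        phi = np.array([[0.6, 0.4]])  # p then q by probability
        res = _results_from_phi_theta(phi, np.ones((2, 1)), vocab=dtm.vocab)
        c = tp.semantic_coherence(res, dtm, top_m=2)
        # D(p,q)=0, D(p)=1 -> log((0+1)/1) = 0
        assert c[0] == pytest.approx(0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(29)
        vocab = [f"w{i}" for i in range(10)]
        docs = [list(rng.choice(vocab, size=rng.integers(2, 8))) for _ in range(15)]
        dtm = tp.build_dtm(docs)
        phi = rng.dirichlet(np.ones(len(dtm.vocab)), size=2)
        res = _results_from_phi_theta(
            phi, np.ones((15, 2)) / 2, vocab=dtm.vocab
        )
        c = tp.semantic_coherence(res, dtm, top_m=5)
        doc_sets = [set(d) for d in docs]
        for k in range(2):
            top = res.top_words(k, 5)
            expected = 0.0
            for i in range(1, 5):
                for j in range(i):
                    d_j = sum(top[j] in s for s in doc_sets)
                    d_ij = sum(top[i] in s and top[j] in s for s in doc_sets)
                    expected += math.log((d_ij + 1) / d_j)
            assert c[k] == pytest.approx(expected)

    def test_top_m_domain(self):
        dtm = tp.build_dtm([["a", "b"]])
        res = _results_from_phi_theta(np.array([[0.5, 0.5]]), np.ones((1, 1)))
        with pytest.raises(ParameterError):
            tp.semantic_coherence(res, dtm, top_m=1)


class TestCorrelations:
    def test_two_topics_perfectly_anticorrelated(self):
        rng = np.random.default_rng(31)
        theta = rng.dirichlet(np.ones(2), size=20)
        res = _results_from_phi_theta(np.full((2, 4), 0.25), theta)
        corr = tp.topic_correlations(res)
        assert corr[0, 1] == pytest.approx(-1.0, abs=1e-9)
        assert corr[0, 0] == 1.0 and corr[1, 1] == 1.0

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(32)
        theta = rng.dirichlet(np.ones(4), size=40)
        res = _results_from_phi_theta(np.full((4, 4), 0.25), theta)
        corr = tp.topic_correlations(res)
        assert np.allclose(corr, corr.T)
        assert np.all(np.diag(corr) == 1.0)
        assert np.all(np.abs(corr) <= 1 + 1e-12)

    def test_planted_cooccurring_pair_positive(self):
        # topics 0 and 1 rise and fall together against topic 2
        rng = np.random.default_rng(33)
        share = rng.beta(2, 2, size=200)
        theta = np.column_stack([share * 0.5, share * 0.5, 1 - share])
        res = _results_from_phi_theta(np.full((3, 4), 0.25), theta)
        corr = tp.topic_correlations(res)
        assert corr[0, 1] > 0
        pos, neg = tp.correlation_edges(corr, cutoff=0.1)
        assert (0, 1) in {(i, j) for i, j, _ in pos}

    def test_k1_rejected(self):
        res = _results_from_phi_theta(np.array([[1.0]]), np.ones((5, 1)))
        with pytest.raises(ParameterError):
            tp.topic_correlations(res)


class TestTopicHappiness:
    def _profiles(self, words_by_topic):
        k = len(words_by_topic)
        return tp.TopicLabelProfile(
            n=max(len(w) for w in words_by_topic.values()),
            frex_weight=0.5,
            prob=words_by_topic,
            frex=words_by_topic,
            score=words_by_topic,
        )

    def _prevalence(self, effects):
        import pandas as pd

        return pd.DataFrame(
            {
                "topic": range(len(effects)),
                "effect": effects,
                "ci_lower": np.asarray(effects) - 0.01,
                "ci_upper": np.asarray(effects) + 0.01,
                "label": ["indeterminate"] * len(effects),
            }
        ).set_index("topic")

    def test_constant_scores_degenerate(self):
        lex = HappinessLexicon({"a": 5.0, "b": 5.0})
        th = tp.topic_happiness_analysis(
            self._profiles({0: ["a"], 1: ["b"]}), self._prevalence([-0.1, 0.1]), lex
        )
        assert th.degenerate
        assert th.slope == 0.0
        assert th.slope_p == 1.0

    def test_hand_ols_slope(self):
        lex = HappinessLexicon({"a": 2.0, "b": 5.0, "c": 8.0})
        th = tp.topic_happiness_analysis(
            self._profiles({0: ["a"], 1: ["b"], 2: ["c"]}),
            self._prevalence([-0.2, 0.0, 0.2]),
            lex,
        )
        assert th.slope == pytest.approx(3.0)
        ranks = th.per_topic["rank"].tolist()
        assert ranks == [1, 2, 3]

    def test_identical_pair_null(self):
        lex = HappinessLexicon({f"w{i}": 3.0 + i * 0.5 for i in range(6)})
        words = [f"w{i}" for i in range(6)]
        th = tp.topic_happiness_analysis(
            self._profiles({0: words, 1: words}),
            self._prevalence([-0.1, 0.1]),
            lex,
        )
        pair = th.pairwise.iloc[0]
        assert pair["W"] == 6 * 6 / 2
        assert pair["p"] == pytest.approx(1.0, abs=0.05)
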
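import math
import warnings

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment

from litpriority.preprocess import TermMatrix, Vocabulary, build_tfidf, build_vocabulary
from litpriority.topics import (
    NMFTopicModel,
    TopicModel,
    arun_divergence,
    assign_documents,
    average_jaccard,
    doc_topic_probability,
    fit_nmf,
    select_k,
    top_terms,
    topic_stability,
)


def term_matrix_from(values, lemmas=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    lemmas = lemmas or [f"t{j:02d}" for j in range(m)]
    vocab = Vocabulary(
        lemmas=tuple(lemmas),
        abs_freq=np.ones(m, dtype=np.int64),
        doc_freq=np.ones(m, dtype=np.int64),
        n_docs=n,
    )
    return TermMatrix(
        values=sp.csr_matrix(values),
        row_ids=tuple(f"d{i}" for i in range(n)),
        vocabulary=vocab,
    )


def make_model(W, H, lemmas=None):
    W, H = np.asarray(W, float), np.asarray(H, float)
    return TopicModel(
        W=W, H=H, k=H.shape[0], objective=0.0, seed=0, n_iter=1, converged=True,
        objective_trace=np.array([0.0]),
        row_ids=tuple(f"d{i}" for i in range(W.shape[0])),
        lemmas=tuple(lemmas or [f"t{j:02d}" for j in range(H.shape[1])]),
    )


class TestNMFEstimator:
    def test_exact_rank_one_input_recovered(self):
        rng = np.random.default_rng(0)
        R = np.outer(rng.uniform(1, 2, 30), rng.uniform(0.1, 1, 20))
        model = NMFTopicModel(n_topics=1, max_iter=500, tol=1e-12).fit(R)
        assert model.objective_ < 1e-8

    def test_objective_matches_independent_recomputation(self, planted_term_matrix):
        model = fit_nmf(planted_term_matrix, 6, seed=3)
        R = planted_term_matrix.values.toarray()
        f = 0.5 * np.sum((R - model.W @ model.H) ** 2)
        assert model.objective == pytest.approx(f, rel=1e-9)

    def test_objective_trace_non_increasing(self, planted_term_matrix):
        model = fit_nmf(planted_term_matrix, 5, seed=1)
        tr = model.objective_trace
        assert np.all(np.diff(tr) <= 1e-9 * (1 + tr[0]))

    def test_factors_nonnegative_and_deterministic(self, planted_term_matrix):
        a = fit_nmf(planted_term_matrix, 4, seed=7)
        b = fit_nmf(planted_term_matrix, 4, seed=7)
        assert (a.W >= 0).all() and (a.H >= 0).all()
        np.testing.assert_array_equal(a.W, b.W)

    def test_block_diagonal_planted_partition(self):
        rng = np.random.default_rng(5)
        R = np.zeros((60, 30))
        for b in range(3):
            R[b * 20:(b + 1) * 20, b * 10:(b + 1) * 10] = rng.uniform(0.5, 1.5, (20, 10))
        model = NMFTopicModel(n_topics=3, max_iter=300).fit(R)
        labels = np.argmax(model.W_, axis=1)
        # each block maps to one topic, and the three topics are distinct
        assert all(len(set(labels[b * 20:(b + 1) * 20])) == 1 for b in range(3))
        assert len(set(labels[::20])) == 3

    def test_k_larger_than_rank_is_error(self):
        with pytest.raises(ValueError, match="n_topics"):
            NMFTopicModel(n_topics=5).fit(np.ones((4, 3)))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            NMFTopicModel(n_topics=2).fit(-np.ones((4, 4)))

    def test_matches_reference_solver_quality(self, planted_term_matrix):
        """Final objective on a par with an independent NMF implementation."""
        from sklearn.decomposition import NMF

        ours = fit_nmf(planted_term_matrix, 6, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sk = NMF(n_components=6, init="nndsvda", max_iter=800, tol=1e-6).fit(
                planted_term_matrix.values
            )
        R = planted_term_matrix.values.toarray()
        sk_obj = 0.5 * np.sum((R - sk.transform(planted_term_matrix.values) @ sk.components_) ** 2)
        assert ours.objective <= 1.05 * sk_obj

    def test_get_set_params_roundtrip(self):
        est = NMFTopicModel(n_topics=3, tol=1e-3)
        est2 = NMFTopicModel().set_params(**est.get_params())
        assert est2.get_params() == est.get_params()


class TestTopTerms:
    def test_largest_weights_selected(self):
        model = make_model(np.eye(1), [[0.9, 0.1, 0.5]], lemmas=["a", "b", "c"])
        assert [t for t, _ in top_terms(model, 0, depth=2)] == ["a", "c"]

    def test_ties_broken_lexicographically(self):
        model = make_model(np.eye(1), [[0.5, 0.5, 0.5]], lemmas=["b", "c", "a"])
        assert [t for t, _ in top_terms(model, 0, depth=3)] == ["a", "b", "c"]

    def test_depth_truncated_to_vocabulary(self):
        model = make_model(np.eye(1), [[0.3, 0.2, 0.1]])
        assert len(top_terms(model, 0, depth=5)) == 3

    def test_bad_topic_id(self):
        model = make_model(np.eye(1), [[1.0, 0.0]])
        with pytest.raises(IndexError):
            top_terms(model, 1)


class TestAssignDocuments:
    def test_argmax_assignment_and_tie_rule(self):
        W = [[0.1, 0.7, 0.2], [0.5, 0.5, 0.0], [0.0, 0.0, 0.0]]
        model = make_model(W, np.ones((3, 4)))
        a = assign_documents(model)
        assert "d0" in a.by_topic[1]
        assert "d1" in a.by_topic[0]  # tie -> lowest topic id
        assert a.unassigned == {"d2"}

    def test_partition_conservation(self, planted_term_matrix):
        model = fit_nmf(planted_term_matrix, 6, seed=0)
        a = assign_documents(model)
        total = sum(len(s) for s in a.by_topic.values()) + len(a.unassigned)
        assert total == len(model.row_ids)
        all_docs = set().union(*a.by_topic.values(), a.unassigned)
        assert all_docs == set(model.row_ids)


class TestDocTopicProbability:
    def test_column_normalization(self):
        model = make_model([[2.0, 1.0], [2.0, 1.0], [0.0, 2.0]], np.ones((2, 3)))
        P = doc_topic_probability(model)
        np.testing.assert_allclose(P[0].to_numpy(), [0.5, 0.5, 0.0])
        np.testing.assert_allclose(P.sum(axis=0).to_numpy(), [1.0, 1.0])

    def test_single_document_corpus(self):
        model = make_model([[3.0]], np.ones((1, 2)))
        assert doc_topic_probability(model).iat[0, 0] == 1.0

    def test_degenerate_topic_column_is_error(self):
        model = make_model([[1.0, 0.0], [2.0, 0.0]], np.ones((2, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            doc_topic_probability(model)


class TestStabilityMetric:
    def test_average_jaccard_hand_enumeration(self):
        # depths 1..3: 1, 1, 2/4 -> mean 0.8333...
        assert average_jaccard(["a", "b", "c"], ["a", "b", "d"]) == pytest.approx(5 / 6)

    def test_average_jaccard_identity_and_disjoint(self):
        assert average_jaccard(list("abc"), list("abc")) == 1.0
        assert average_jaccard(list("abc"), list("xyz")) == 0.0

    def test_stability_bounded_and_high_for_separated_topics(self, planted_term_matrix):
        s = topic_stability(planted_term_matrix, 6, n_runs=4, depth=10, seed=0)
        assert 0.0 <= s <= 1.0
        assert s >= 0.8

    def test_invalid_parameters(self, planted_term_matrix):
        with pytest.raises(ValueError):
            topic_stability(planted_term_matrix, 6, n_runs=1)
        with pytest.raises(ValueError):
            topic_stability(planted_term_matrix, 6, sample_frac=0.0)


class TestArunDivergence:
    def test_identical_distributions_give_zero(self):
        # H orthonormal rows -> singular values (1,1); W column norms equal
        model = make_model(np.eye(2), np.eye(2))
        assert arun_divergence(model) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_symmetric_kl(self):
        # u = (.5,.5) from H = I2; v = (.9,.1) from W column norms (9,1)
        W = np.zeros((2, 2))
        W[0, 0], W[1, 1] = 9.0, 1.0
        model = make_model(W, np.eye(2))
        expected = (
            0.5 * math.log(0.5 / 0.9) + 0.5 * math.log(0.5 / 0.1)
            + 0.9 * math.log(0.9 / 0.5) + 0.1 * math.log(0.1 / 0.5)
        )
        assert arun_divergence(model) == pytest.approx(expected, rel=1e-12)

    def test_nonnegative(self, planted_term_matrix):
        model = fit_nmf(planted_term_matrix, 4, seed=2)
        assert arun_divergence(model) >= 0.0

    def test_k_one_convention(self):
        model = make_model(np.ones((3, 1)), np.ones((1, 4)))
        with pytest.warns(RuntimeWarning):
            assert arun_divergence(model) == 0.0


class TestSelectK:
    def test_singleton_grid_returns_that_k(self, planted_term_matrix):
        diag = select_k(planted_term_matrix, k_min=4, k_max=4, n_runs=2, depth=5, seed=0)
        assert diag.k_selected == 4
        assert diag.k_grid == (4,)

    def test_one_diagnostic_pair_per_candidate(self, planted_term_matrix):
        diag = select_k(planted_term_matrix, k_min=3, k_max=6, n_runs=2, depth=5, seed=0)
        assert len(diag.k_grid) == len(diag.stability) == len(diag.divergence) == 4

    def test_k_min_validated(self, planted_term_matrix):
        with pytest.raises(ValueError):
            select_k(planted_term_matrix, k_min=1, k_max=3)


def test_planted_topics_recovered_by_top_term_matching(planted_corpus, planted_term_matrix):
    """Fitting at the true k recovers the planted word distributions."""
    _, truth = planted_corpus
    model = fit_nmf(planted_term_matrix, 6, seed=0)
    lemma_index = {w: j for j, w in enumerate(model.lemmas)}
    depth = 10
    planted_lists = []
    for t in range(6):
        order = np.argsort(-truth.topic_word[t])
        # planted vocab ids -> lemma strings -> fitted matrix columns
        vocab_words = [f"w{''.join(chr(ord('b') + int(c)) for c in str(j).zfill(3))}"
                       for j in order]
        planted_lists.append([lemma_index[w] for w in vocab_words if w in lemma_index][:depth])
    fitted_lists = [np.argsort(-model.H[t])[:depth] for t in range(6)]
    score = np.zeros((6, 6))
    for a in range(6):
        for b in range(6):
            score[a, b] = average_jaccard(planted_lists[a], list(fitted_lists[b]), depth)
    rows, cols = linear_sum_assignment(-score)
    assert score[rows, cols].mean() >= 0.8
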
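import numpy as np
import pytest

from dsirep.corpus import CorpusBundle
from dsirep.factorization import DSIEmbedding
from dsirep.semantics import (
    analogy,
    analogy_accuracy,
    analogy_query_vector,
    conceptual_specificity,
    corpus_to_trajectory,
    population_similarity,
    top_words,
)
from dsirep.successor import sr_empirical


def labelled(X, labels):
    return DSIEmbedding(X=X, W=X.copy(), variant="decorr", labels=list(labels))


class TestCorpusToTrajectory:
    def test_tokens_become_states(self):
        bundle = CorpusBundle(
            tokens=np.array([0, 1, 0]), vocabulary=["a", "b"], doc_breaks=()
        )
        traj = corpus_to_trajectory(bundle)
        assert traj.states.tolist() == [0, 1, 0]

    def test_empty_rejected(self):
        bundle = CorpusBundle(tokens=np.array([], dtype=int), vocabulary=["a"], doc_breaks=())
        with pytest.raises(ValueError, match="empty"):
            corpus_to_trajectory(bundle)

    def test_document_boundary_resets_sr_window(self):
        bundle = CorpusBundle(
            tokens=np.array([0, 1, 2, 3]), vocabulary=list("abcd"), doc_breaks=(2,)
        )
        traj = corpus_to_trajectory(bundle)
        sr = sr_empirical(traj, 4, 0.9)
        assert sr.values[0, 2] == 0.0  # credit never crosses the break
        assert sr.values[0, 1] > 0.0


class TestTopWords:
    def test_known_column_maxima(self):
        X = np.array([[0.1, 3.0], [2.0, 1.0], [0.5, 2.0]])
        emb = labelled(X, ["apple", "pear", "plum"])
        assert top_words(emb, 0, k=2) == ["pear", "plum"]
        assert top_words(emb, 1, k=3) == ["apple", "plum", "pear"]

    def test_k_one_is_argmax(self):
        X = np.array([[0.0], [5.0], [1.0]])
        assert top_words(labelled(X, list("abc")), 0, k=1) == ["b"]

    def test_ties_broken_by_vocabulary_order(self):
        X = np.array([[1.0], [1.0], [2.0]])
        assert top_words(labelled(X, list("abc")), 0, k=3) == ["c", "a", "b"]

    def test_invariant_to_positive_rescaling(self, rng):
        X = rng.random((20, 3))
        emb1 = labelled(X, [f"w{i}" for i in range(20)])
        emb2 = labelled(X * 11.0, [f"w{i}" for i in range(20)])
        assert top_words(emb1, 2) == top_words(emb2, 2)

    def test_oversized_k_truncated_with_warning(self):
        X = np.ones((3, 1))
        with pytest.warns(UserWarning, match="exceeds"):
            out = top_words(labelled(X, list("abc")), 0, k=10)
        assert len(out) == 3


def binary_category_sim(word):
    """Similarity oracle: 1 iff same planted category prefix."""

    def sim(w1, w2):
        return 1.0 if w1.split("_")[0] == w2.split("_")[0] else 0.0

    return sim


class TestConceptualSpecificity:
    def make_vocab(self):
        return [f"c{c}_w{w}" for c in range(10) for w in range(10)]

    def test_pure_category_unit(self, rng):
        # a unit whose TOP-10 words all share one of 10 equal categories:
        # s_unit = 1, s_null ~ 0.0909 (random same-category collisions),
        # specificity ~ 10 (within binomial noise of the 1000-pair null)
        vocab = self.make_vocab()
        X = rng.random((100, 3)) * 0.1
        X[0:10, 0] = 1.0 + rng.random(10)  # category c0 dominates unit 0
        emb = labelled(X, vocab)
        report = conceptual_specificity(emb, binary_category_sim(None), seed=0)
        u0 = report.units[0]
        assert u0.s_unit == 1.0
        assert report.s_null == pytest.approx(45 * 10 / 4950, abs=0.03)
        assert 7.0 < u0.specificity < 15.0

    def test_spread_unit_not_significant(self, rng):
        vocab = self.make_vocab()
        X = np.zeros((100, 1))
        X[::10, 0] = 1.0 + np.arange(10)  # one top word from each category
        emb = labelled(X, vocab)
        report = conceptual_specificity(emb, binary_category_sim(None), seed=0)
        assert report.units[0].s_unit == 0.0
        assert not report.units[0].significant
        assert report.units[0].specificity == pytest.approx(-1.0)

    def test_reproducible_under_seed(self, rng):
        vocab = self.make_vocab()
        X = rng.random((100, 4))
        emb = labelled(X, vocab)
        r1 = conceptual_specificity(emb, binary_category_sim(None), seed=9)
        r2 = conceptual_specificity(emb, binary_category_sim(None), seed=9)
        assert r1.s_null == r2.s_null
        assert [u.significant for u in r1.units] == [u.significant for u in r2.units]


class TestPopulationSimilarity:
    def test_identical_vectors(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 0.5]])
        emb = labelled(X, list("abc"))
        scores = population_similarity(emb, [("a", "b")])
        assert scores[0] == pytest.approx(1.0)
        d = population_similarity(emb, [("a", "b")], metric="pearson")
        assert d[0] == pytest.approx(0.0)

    def test_orthogonal_vectors(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        emb = labelled(X, list("ab"))
        assert population_similarity(emb, [("a", "b")])[0] == pytest.approx(0.0)

    def test_zero_vector_flagged(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        emb = labelled(X, list("ab"))
        with pytest.warns(UserWarning, match="zero vector"):
            scores = population_similarity(emb, [("a", "b")])
        assert np.isnan(scores[0])

    def test_rank_correlation_against_reference(self, rng):
        X = rng.random((6, 4))
        emb = labelled(X, list("abcdef"))
        pairs = [("a", "b"), ("c", "d"), ("e", "f")]
        scores = population_similarity(emb, pairs)
        _, rho = population_similarity(emb, pairs, reference=scores)
        assert rho == pytest.approx(1.0)


def disentangled_capital_embedding():
    """One-hot factor units: capital, country, French, German (the classic
    France/Paris/Germany/Berlin factorization)."""
    vocab = ["france", "paris", "germany", "berlin", "other"]
    e = np.eye(4)
    rows = {
        "france": e[1] + e[2],   # country + French
        "paris": e[0] + e[2],    # capital + French
        "germany": e[1] + e[3],  # country + German
        "berlin": e[0] + e[3],   # capital + German
        "other": 0.9 * e[1],  # a second country-like word
    }
    X = np.stack([rows[w] for w in vocab])
    return labelled(X, vocab)


class TestAnalogy:
    def test_capital_structure_full_and_partial(self):
        emb = disentangled_capital_embedding()
        # France + Berlin - Germany -> Paris
        assert analogy(emb, "germany", "berlin", "france", n_top=1)[0] == "paris"
        assert analogy(emb, "germany", "berlin", "france", k_dims=2, n_top=1)[0] == "paris"

    def test_b_equals_a_returns_nearest_neighbor_of_c(self):
        emb = disentangled_capital_embedding()
        out = analogy(emb, "france", "france", "paris", n_top=1)
        assert out[0] == "berlin"  # shares the capital unit with paris

    def test_k_dims_full_equals_unrestricted(self):
        emb = disentangled_capital_embedding()
        q_full = analogy_query_vector(emb, "germany", "berlin", "france")
        q_all = analogy_query_vector(emb, "germany", "berlin", "france", k_dims=4)
        assert np.allclose(q_full, q_all)

    def test_k_dims_validated(self):
        emb = disentangled_capital_embedding()
        with pytest.raises(ValueError, match="k_dims"):
            analogy_query_vector(emb, "france", "paris", "germany", k_dims=9)

    def test_accuracy_on_consistent_quadruples(self):
        emb = disentangled_capital_embedding()
        quads = [
            ("france", "paris", "germany", "berlin"),
            ("paris", "france", "berlin", "germany"),
            ("france", "germany", "paris", "berlin"),
            ("paris", "berlin", "france", "germany"),
        ]
        assert analogy_accuracy(emb, quads) == 1.0
        assert analogy_accuracy(emb, quads, k_dims=2) == 1.0

    def test_shuffled_answers_near_chance(self, rng):
        n = 40
        X = rng.random((n, 8))
        vocab = [f"w{i}" for i in range(n)]
        emb = labelled(X, vocab)
        quads = [
            tuple(vocab[j] for j in rng.choice(n, size=4, replace=False))
            for _ in range(50)
        ]
        assert analogy_accuracy(emb, quads) <= 0.2  # chance ~ 1/(n-3)
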
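"""Word-as-state embeddings: conceptual specificity, similarity, analogy.

A token stream is treated exactly like a spatial trajectory (each word is
a state), so the successor-information pipeline and factorization carry
over unchanged; document boundaries reset the discounted-count window.
The evaluations here mirror the standard word-embedding toolbox — TOP-k
activating words per unit, a concept-specificity statistic against a
random-pair null, cosine / 1-Pearson population similarity, and additive
analogy a:b :: c:? with an optional partial-dimension variant that only
recombines the strongest dimensions of the difference vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .corpus import CorpusBundle
from .factorization import DSIEmbedding
from .gridworld import Trajectory


@dataclass
class UnitSpecificity:
    unit: int
    top_words: list
    s_unit: float
    significant: bool
    specificity: float


@dataclass
class SpecificityReport:
    units: list           # per-unit UnitSpecificity
    s_null: float         # mean of the null similarities
    threshold: float      # 95th percentile of the null
    fraction_significant: float
    mean_specificity: float


def corpus_to_trajectory(bundle: CorpusBundle) -> Trajectory:
    """The token sequence as a state trajectory; document boundaries become
    segment breaks so discounted counts never cross documents."""
    if len(bundle.tokens) == 0:
        raise ValueError("empty corpus")
    if bundle.tokens.min() < 0 or bundle.tokens.max() >= bundle.n_words:
        raise ValueError("token outside the vocabulary")
    return Trajectory(states=bundle.tokens, actions=None, breaks=bundle.doc_breaks)


def top_words(embedding: DSIEmbedding, unit: int, k: int = 10) -> list:
    """The k words with the largest activation on one unit, descending;
    ties broken by vocabulary order."""
    if embedding.labels is None:
        raise ValueError("embedding has no word labels")
    if not 0 <= unit < embedding.n_dims:
        raise ValueError("unit out of range")
    n = embedding.n_states
    if k > n:
        warnings.warn(f"k={k} exceeds vocabulary size {n}; truncating")
        k = n
    col = embedding.X[:, unit]
    # stable sort on (-value, vocab position) gives the tie-break for free
    order = np.argsort(-col, kind="stable")[:k]
    return [embedding.labels[i] for i in order]


def conceptual_specificity(
    embedding: DSIEmbedding,
    similarity_fn,
    n_null: int = 1000,
    seed: int = 0,
    k: int = 10,
) -> SpecificityReport:
    """Concept-specificity of every unit against a random-pair null.

    Per unit, ``s_unit`` is the mean similarity over the k(k-1)/2 pairs of
    its TOP-k words; the null is the similarity of ``n_null`` random word
    pairs.  A unit is significant when ``s_unit`` exceeds the null's 95th
    percentile, and its specificity is ``s_unit / s_null - 1``.
    """
    labels = embedding.labels
    if labels is None or len(labels) < 2:
        raise ValueError("need a labelled embedding with >= 2 words")
    rng = np.random.default_rng(seed)
    n = len(labels)
    null = np.empty(n_null)
    for i in range(n_null):
        a, b = rng.choice(n, size=2, replace=False)
        null[i] = similarity_fn(labels[a], labels[b])
    s_null = float(null.mean())
    threshold = float(np.percentile(null, 95))
    if s_null == 0:
        warnings.warn("null mean similarity is 0; specificity undefined")

    units = []
    for u in range(embedding.n_dims):
        tw = top_words(embedding, u, k)
        sims = [
            similarity_fn(tw[i], tw[j])
            for i in range(len(tw))
            for j in range(i + 1, len(tw))
        ]
        s_unit = float(np.mean(sims))
        spec = s_unit / s_null - 1.0 if s_null != 0 else float("nan")
        units.append(
            UnitSpecificity(
                unit=u,
                top_words=tw,
                s_unit=s_unit,
                significant=bool(s_unit > threshold),
                specificity=spec,
            )
        )
    return SpecificityReport(
        units=units,
        s_null=s_null,
        threshold=threshold,
        fraction_significant=float(np.mean([u.significant for u in units])),
        mean_specificity=float(np.nanmean([u.specificity for u in units])),
    )


def _vec(embedding: DSIEmbedding, word: str) -> np.ndarray:
    try:
        i = embedding.labels.index(word)
    except (ValueError, AttributeError):
        raise KeyError(f"word {word!r} not in vocabulary") from None
    return embedding.X[i]


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu <= 1e-12 or nv <= 1e-12:
        warnings.warn("zero vector in cosine similarity")
        return float("nan")
    return float(u @ v / (nu * nv))


def pearson_dissimilarity(u: np.ndarray, v: np.ndarray) -> float:
    """1 - Pearson correlation between two representation vectors."""
    if u.std() <= 1e-12 or v.std() <= 1e-12:
        warnings.warn("constant vector in Pearson dissimilarity")
        return float("nan")
    return float(1.0 - np.corrcoef(u, v)[0, 1])


def population_similarity(
    embedding: DSIEmbedding, word_pairs, metric: str = "cosine", reference=None
):
    """Similarity scores per word pair, plus the Spearman rank correlation
    against an optional reference score list."""
    fn = cosine_similarity if metric == "cosine" else pearson_dissimilarity
    scores = np.array([fn(_vec(embedding, a), _vec(embedding, b)) for a, b in word_pairs])
    if reference is None:
        return scores
    rho = spearmanr(scores, np.asarray(reference, dtype=float)).statistic
    return scores, float(rho)


def analogy_query_vector(
    embedding: DSIEmbedding, a: str, b: str, c: str, k_dims: int | None = None
) -> np.ndarray:
    """Query vector for a:b :: c:?.

    Full form: ``x(c) + x(b) - x(a)``.  With ``k_dims`` only the k/2
    largest and k/2 smallest dimensions of the difference ``x(b) - x(a)``
    are added to x(c) (the extra dimension goes to the max side when k is
    odd); the result is clipped at 0.
    """
    xa, xb, xc = _vec(embedding, a), _vec(embedding, b), _vec(embedding, c)
    diff = xb - xa
    if k_dims is not None:
        D = embedding.n_dims
        if not 1 <= k_dims <= D:
            raise ValueError("k_dims must lie in [1, D]")
        n_max = (k_dims + 1) // 2
        n_min = k_dims - n_max
        order = np.argsort(diff)
        keep = np.zeros(D, dtype=bool)
        keep[order[-n_max:]] = True
        if n_min > 0:
            keep[order[:n_min]] = True
        diff = np.where(keep, diff, 0.0)
    return np.maximum(xc + diff, 0.0)


def analogy(
    embedding: DSIEmbedding, a: str, b: str, c: str, k_dims: int | None = None, n_top: int = 5
) -> list:
    """Ranked candidate answers for a:b :: c:? (a, b, c excluded)."""
    q = analogy_query_vector(embedding, a, b, c, k_dims)
    X = embedding.X
    Xn = X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)
    qn = q / max(np.linalg.norm(q), 1e-12)
    sims = Xn @ qn
    for w in (a, b, c):
        sims[embedding.labels.index(w)] = -np.inf
    order = np.argsort(-sims)[:n_top]
    return [embedding.labels[i] for i in order]


def analogy_accuracy(embedding: DSIEmbedding, quadruples, k_dims: int | None = None) -> float:
    """Fraction of quadruples (a, b, c, d) whose top-1 answer equals d."""
    if not quadruples:
        return float("nan")
    hits = sum(
        analogy(embedding, a, b, c, k_dims=k_dims, n_top=1)[0] == d
        for a, b, c, d in quadruples
    )
    return hits / len(quadruples)
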
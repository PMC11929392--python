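"""Synthetic token streams with planted categorical and relational structure.

The categorical generator emulates topical text: each document activates a
small set of semantic categories and samples tokens with probability mass
boosted on the active categories' words, over a background vocabulary.
The relational generator plants two-factor words (family role x entity
identity, e.g. country/capital x France/Germany) whose co-occurrence
couples words sharing either factor, and enumerates all consistent
analogy quadruples as ground truth.  Both are fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CorpusSpec:
    n_categories: int = 10
    words_per_category: int = 10
    n_background: int = 50
    n_families: int = 2
    pairs_per_family: int = 4
    doc_length: int = 200
    n_docs: int = 1000
    boost: float = 30.0
    categories_per_doc: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_categories, self.words_per_category, self.doc_length, self.n_docs) < 1:
            raise ValueError("all counts must be >= 1")
        if self.boost <= 1:
            raise ValueError("boost must exceed 1 for planted structure to exist")


@dataclass
class CorpusBundle:
    tokens: np.ndarray              # vocabulary indices, all documents concatenated
    vocabulary: list                # ordered word strings
    doc_breaks: tuple               # token positions where a new document starts
    categories: np.ndarray | None = None   # per-word category id (-1 = background)
    quadruples: list = field(default_factory=list)  # (a, b, c, d) word strings
    word_latent: np.ndarray | None = None  # per-word latent coordinate (similarity oracle)

    @property
    def n_words(self) -> int:
        return len(self.vocabulary)

    def index(self, word: str) -> int:
        return self.vocabulary.index(word)


def generate_categorical_corpus(spec: CorpusSpec) -> CorpusBundle:
    """Documents from a category-mixture process.

    Each document samples ``categories_per_doc`` active categories; each
    token is drawn with weight ``boost`` on active-category words and 1 on
    every other word.  Background words belong to no category (label -1).
    """
    import warnings

    if spec.n_categories == 1:
        warnings.warn("single category: no planted contrast")
    rng = np.random.default_rng(spec.seed)
    vocab, cats = [], []
    for c in range(spec.n_categories):
        for w in range(spec.words_per_category):
            vocab.append(f"cat{c:02d}_w{w:02d}")
            cats.append(c)
    for w in range(spec.n_background):
        vocab.append(f"bg_w{w:03d}")
        cats.append(-1)
    cats = np.array(cats)
    n_words = len(vocab)
    latent = rng.uniform(0.0, 1.0, size=n_words)

    tokens = np.empty(spec.n_docs * spec.doc_length, dtype=np.int64)
    breaks = []
    k = min(spec.categories_per_doc, spec.n_categories)
    for d in range(spec.n_docs):
        if d > 0:
            breaks.append(d * spec.doc_length)
        active = rng.choice(spec.n_categories, size=k, replace=False)
        weights = np.ones(n_words)
        weights[np.isin(cats, active)] = spec.boost
        weights /= weights.sum()
        tokens[d * spec.doc_length : (d + 1) * spec.doc_length] = rng.choice(
            n_words, size=spec.doc_length, p=weights
        )
    return CorpusBundle(
        tokens=tokens,
        vocabulary=vocab,
        doc_breaks=tuple(breaks),
        categories=cats,
        word_latent=latent,
    )


def _family_words(spec: CorpusSpec):
    """Word strings for two-factor (role x entity) relational families."""
    words = {}
    for f in range(spec.n_families):
        for e in range(spec.pairs_per_family):
            for role in (0, 1):
                words[(f, e, role)] = f"fam{f}_ent{e:02d}_r{role}"
    return words


def enumerate_quadruples(spec: CorpusSpec) -> list:
    """All consistent analogy quadruples a:b :: c:d.

    For each family and each unordered pair of entities {e, e'}, four
    ordered quadruples exist: two role-swaps (a=(e,r0), b=(e,r1),
    c=(e',r0), d=(e',r1) and the reverse direction) and two entity-swaps.
    """
    words = _family_words(spec)
    quads = []
    for f in range(spec.n_families):
        for e1 in range(spec.pairs_per_family):
            for e2 in range(e1 + 1, spec.pairs_per_family):
                a0, a1 = words[(f, e1, 0)], words[(f, e1, 1)]
                b0, b1 = words[(f, e2, 0)], words[(f, e2, 1)]
                quads.append((a0, a1, b0, b1))  # role swap, forward
                quads.append((a1, a0, b1, b0))  # role swap, reverse
                quads.append((a0, b0, a1, b1))  # entity swap, forward
                quads.append((b0, a0, b1, a1))  # entity swap, reverse
    return quads


def generate_relational_corpus(spec: CorpusSpec) -> CorpusBundle:
    """Token stream coupling words that share a role or an entity factor.

    Each document picks a family and a theme: an *entity* theme boosts
    both role-words of one entity, a *role* theme boosts one role's words
    across all of the family's entities.  Tokens mix the boosted set with
    the background vocabulary.
    """
    if spec.n_families < 2 or spec.pairs_per_family < 2:
        raise ValueError("need >= 2 relational families with >= 2 pairs each")
    rng = np.random.default_rng(spec.seed)
    fam_words = _family_words(spec)
    vocab = list(fam_words.values())
    fam_index = {w: i for i, w in enumerate(vocab)}
    for w in range(spec.n_background):
        vocab.append(f"bg_w{w:03d}")
    n_words = len(vocab)
    latent = rng.uniform(0.0, 1.0, size=n_words)

    tokens = np.empty(spec.n_docs * spec.doc_length, dtype=np.int64)
    breaks = []
    for d in range(spec.n_docs):
        if d > 0:
            breaks.append(d * spec.doc_length)
        f = int(rng.integers(spec.n_families))
        if rng.random() < 0.5:  # entity theme
            e = int(rng.integers(spec.pairs_per_family))
            boosted = [fam_index[fam_words[(f, e, r)]] for r in (0, 1)]
        else:  # role theme
            r = int(rng.integers(2))
            boosted = [
                fam_index[fam_words[(f, e, r)]] for e in range(spec.pairs_per_family)
            ]
        weights = np.ones(n_words)
        weights[boosted] = spec.boost * n_words / len(boosted)
        weights /= weights.sum()
        tokens[d * spec.doc_length : (d + 1) * spec.doc_length] = rng.choice(
            n_words, size=spec.doc_length, p=weights
        )
    return CorpusBundle(
        tokens=tokens,
        vocabulary=vocab,
        doc_breaks=tuple(breaks),
        categories=None,
        quadruples=enumerate_quadruples(spec),
        word_latent=latent,
    )


def cooccurrence_contrast(bundle: CorpusBundle, window: int = 5):
    """Mean within-category vs between-category co-occurrence counts in a
    symmetric window (diagnostic for planted structure)."""
    cats = bundle.categories
    n = bundle.n_words
    counts = np.zeros((n, n))
    tokens = bundle.tokens
    bounds = [0, *bundle.doc_breaks, len(tokens)]
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = tokens[a:b]
        for lag in range(1, window + 1):
            np.add.at(counts, (seg[:-lag], seg[lag:]), 1.0)
    counts = counts + counts.T
    in_cat = (cats[:, None] == cats[None, :]) & (cats[:, None] >= 0)
    np.fill_diagonal(in_cat, False)
    out_cat = (cats[:, None] != cats[None, :]) & (cats[:, None] >= 0) & (cats[None, :] >= 0)
    return counts[in_cat].mean(), counts[out_cat].mean()


def category_similarity_oracle(bundle: CorpusBundle):
    """Ground-truth graded similarity function for the categorical corpus.

    Same planted category -> 1.0; otherwise a smooth positive value
    ``0.5 * exp(-3 |z1 - z2|)`` from per-word latent coordinates, so the
    null distribution of random-pair similarities is continuous and its
    95th percentile is meaningful.
    """
    cats = bundle.categories
    latent = bundle.word_latent
    index = {w: i for i, w in enumerate(bundle.vocabulary)}

    def sim(w1: str, w2: str) -> float:
        i, j = index[w1], index[w2]
        if cats[i] >= 0 and cats[i] == cats[j]:
            return 1.0
        return 0.5 * float(np.exp(-3.0 * abs(latent[i] - latent[j])))

    return sim


def write_corpus(bundle: CorpusBundle, text_path, truth_path=None, quad_path=None):
    """Plain-text export: one document per line; ground truth as
    ``word,category`` CSV and the standard four-words-per-line quadruple
    format."""
    bounds = [0, *bundle.doc_breaks, len(bundle.tokens)]
    with open(text_path, "w") as fh:
        for a, b in zip(bounds[:-1], bounds[1:]):
            fh.write(" ".join(bundle.vocabulary[t] for t in bundle.tokens[a:b]) + "\n")
    if truth_path is not None and bundle.categories is not None:
        with open(truth_path, "w") as fh:
            fh.write("word,category\n")
            for w, c in zip(bundle.vocabulary, bundle.categories):
                fh.write(f"{w},{c}\n")
    if quad_path is not None and bundle.quadruples:
        with open(quad_path, "w") as fh:
            for q in bundle.quadruples:
                fh.write(" ".join(q) + "\n")


def read_corpus(text_path) -> CorpusBundle:
    """Read a plain-text corpus (one document per line, whitespace tokens,
    lowercased); the vocabulary is every distinct token in order of first
    appearance."""
    docs = []
    with open(text_path) as fh:
        for line in fh:
            words = line.lower().split()
            if words:
                docs.append(words)
    if not docs:
        raise ValueError("empty corpus")
    vocab: list = []
    index: dict = {}
    tokens = []
    breaks = []
    for d, words in enumerate(docs):
        if d > 0:
            breaks.append(len(tokens))
        for w in words:
            if w not in index:
                index[w] = len(vocab)
                vocab.append(w)
            tokens.append(index[w])
    return CorpusBundle(
        tokens=np.array(tokens, dtype=np.int64),
        vocabulary=vocab,
        doc_breaks=tuple(breaks),
    )
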
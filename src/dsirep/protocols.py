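"""Canonical simulation protocols of the study.

These functions bundle the full pipelines behind the headline results so
that scripts and tests reproduce them identically:

* :func:`spatial_experiment` — 30x30 open-room training of the decorr and
  sparse variants with gridness classification and the 1,000-trial
  path-integration protocol.
* :func:`context_experiment` — barrier contexts A / B / Φ on a shared
  footprint, compositional inference A+B−Φ (full, partial top-k, and
  grid-only), and goal-directed navigation in the unseen context A+B.
* :func:`word_experiment` — synthetic categorical and relational corpora,
  concept-specificity and partial-dimension analogy across constraint
  variants.

Problem sizes follow the study conditions (30x30 room, D=100, gamma=0.99
spatial / 0.9 word); walk and corpus lengths are package choices recorded
here as defaults.
"""

from __future__ import annotations

import numpy as np

from . import corpus as corpus_mod
from . import semantics
from .context import ContextSet, compose_context, compose_partial, unit_distance
from .factorization import FactorizationConfig, factorize
from .gridness import classify_grid_units
from .gridworld import EnvGraph, build_room, random_walk
from .navigation import navigation_benchmark, path_integration_success_rate
from .successor import psi_from_trajectory

SPATIAL_GAMMA = 0.99
WORD_GAMMA = 0.9
WALK_LENGTH = 1_000_000

# barrier layouts of the context experiment (30x30 footprint): two
# disjoint, non-touching straight walls with gaps at opposite sides
WALL_A = [((10, 4), (10, 14))]
WALL_B = [((20, 16), (20, 26))]

# linear-RL softmax temperature for navigation around barriers; the
# greedy (T=0) limit loops in the value field's two-cycles next to walls
NAV_TEMPERATURE = 0.1


def spatial_config(variant: str, seed: int, n_dims: int = 100, n_iter: int = 6000):
    if variant == "decorr":
        return FactorizationConfig(
            n_dims=n_dims, variant="decorr", beta=6000.0, rho_l2=2.5,
            learning_rate=0.02, n_iter=n_iter, seed=seed,
        )
    if variant == "sparse":
        return FactorizationConfig(
            n_dims=n_dims, variant="sparse", beta=0.0, rho_l2=0.0, rho_l1=1.0,
            learning_rate=0.03, n_iter=n_iter, seed=seed,
        )
    if variant == "decorr-nonneg-off":
        return FactorizationConfig(
            n_dims=n_dims, variant="decorr-nonneg-off", beta=4000.0, rho_l2=2.0,
            learning_rate=0.03, n_iter=n_iter, seed=seed,
        )
    raise ValueError(f"unknown variant {variant!r}")


def train_room(
    env: EnvGraph,
    seed: int,
    variant: str = "decorr",
    gamma: float = SPATIAL_GAMMA,
    walk_length: int = WALK_LENGTH,
    n_dims: int = 100,
    n_iter: int = 6000,
):
    """Random walk -> PSI -> embedding for one room and seed."""
    walk = random_walk(env, walk_length, seed=seed)
    psi = psi_from_trajectory(walk, env.n_states, gamma)
    return factorize(psi.values, spatial_config(variant, seed, n_dims, n_iter))


def spatial_experiment(seeds=range(5), gamma=SPATIAL_GAMMA, progress=None):
    """Open-room battery behind the grid-fraction and path-integration
    results; returns a list of per-seed dicts."""
    env = build_room(30, 30)
    results = []
    for seed in seeds:
        walk = random_walk(env, WALK_LENGTH, seed=seed)
        psi = psi_from_trajectory(walk, env.n_states, gamma)
        decorr = factorize(psi.values, spatial_config("decorr", seed))
        _, frac_x = classify_grid_units(decorr, env, 100, seed=seed, source="X")
        _, frac_w = classify_grid_units(decorr, env, 100, seed=seed, source="W")
        _, pi_decorr = path_integration_success_rate(
            decorr, env, n_trials=1000, n_steps=10, seed=seed
        )
        sparse = factorize(psi.values, spatial_config("sparse", seed, n_iter=6000))
        _, pi_sparse = path_integration_success_rate(
            sparse, env, n_trials=1000, n_steps=10, seed=seed
        )
        row = dict(
            seed=seed,
            grid_fraction_x=frac_x,
            grid_fraction_w=frac_w,
            pi_successes_decorr=pi_decorr,
            pi_successes_sparse=pi_sparse,
        )
        results.append(row)
        if progress is not None:
            progress(row)
    return results


def _cross_wall_sampler(env: EnvGraph, rng):
    """Start in the top quarter, goal in the bottom quarter, so paths must
    negotiate both walls."""
    top = [i for i, (r, c) in enumerate(env.states) if r < 5]
    bottom = [i for i, (r, c) in enumerate(env.states) if r >= env.height - 5]
    return int(rng.choice(top)), int(rng.choice(bottom))


def context_experiment(
    seed: int = 0,
    n_trials: int = 1000,
    top_ks=(1, 2, 3, 4, 6, 8, 12, 16, 24, 32, 48, 64, 100),
    n_iter: int = 6000,
    n_dims: int = 100,
):
    """Train contexts A / B / Φ, compose A+B−Φ, and benchmark navigation
    in the unseen two-wall context.

    Returns a dict with mean normalized path lengths per condition
    (``full``, ``A_only``, ``B_only``, ``grid_only``, ``top_k`` per k),
    per-unit representational distances B↔Φ, grid labels in Φ, and the
    smallest k whose top-k partial composition performs within 5% of the
    full composition.
    """
    footprint = dict(PHI=[], A=WALL_A, B=WALL_B)
    envs = {name: build_room(30, 30, walls) for name, walls in footprint.items()}
    env_ab = build_room(30, 30, WALL_A + WALL_B)
    # continual training: the no-barrier context Φ is learned from scratch;
    # A and B fine-tune Φ's solution on their own walks, which preserves
    # unit identity across contexts — the composition x(A)+x(B)-x(Φ) and
    # per-unit representational distances are defined unit-by-unit
    embs = {"PHI": train_room(envs["PHI"], seed=seed, n_dims=n_dims, n_iter=n_iter)}
    for name in ("A", "B"):
        env = envs[name]
        rows = np.array([envs["PHI"].index_of[pos] for pos in env.states])
        walk = random_walk(env, WALK_LENGTH, seed=seed + {"A": 11, "B": 23}[name])
        psi = psi_from_trajectory(walk, env.n_states, SPATIAL_GAMMA)
        cfg = spatial_config("decorr", seed, n_dims=n_dims, n_iter=n_iter // 2)
        cfg.learning_rate = 0.02
        # proximal anchoring keeps units aligned with Φ and concentrates
        # the contextual change on the units the new layout requires
        embs[name] = factorize(
            psi.values, cfg,
            warm_start=(embs["PHI"].X[rows], embs["PHI"].W[rows]),
            anchor_weight=10.0,
        )
    ctx = ContextSet.build({n: (envs[n], embs[n]) for n in envs})

    phi_results, _ = classify_grid_units(embs["PHI"], envs["PHI"], 100, seed=seed)
    grid_labels = np.array([r.is_grid for r in phi_results])

    def bench(embedding, env, trial_seed):
        return navigation_benchmark(
            embedding, env, n_trials=n_trials, seed=trial_seed,
            max_steps_factor=8, temperature=NAV_TEMPERATURE,
            start_goal_sampler=lambda rng: _cross_wall_sampler(env, rng),
        )["mean_normalized_length"]

    def restrict(emb_src, env_to, name):
        """Re-index a context's embedding onto the A+B state set."""
        rows = np.array(
            [envs[name].index_of[pos] for pos in env_to.states]
        )
        from .factorization import DSIEmbedding

        return DSIEmbedding(
            X=emb_src.X[rows], W=emb_src.W[rows], variant=emb_src.variant
        )

    composed = compose_context(ctx, env_ab)
    out = {
        "full": bench(composed, env_ab, seed + 1),
        "A_only": bench(restrict(embs["A"], env_ab, "A"), env_ab, seed + 1),
        "B_only": bench(restrict(embs["B"], env_ab, "B"), env_ab, seed + 1),
        "grid_only": bench(
            compose_partial(ctx, env_ab, units=np.flatnonzero(grid_labels)),
            env_ab, seed + 1,
        ),
        "top_k": {},
    }
    for k in top_ks:
        partial = compose_partial(ctx, env_ab, top_k=k)
        out["top_k"][k] = bench(partial, env_ab, seed + 1)

    distances = unit_distance(ctx, "B", "PHI").distances
    out["unit_distances"] = distances
    out["grid_labels"] = grid_labels
    out["min_sufficient_k"] = next(
        (k for k in top_ks if out["top_k"][k] <= 1.05 * out["full"]), None
    )
    return out


def word_experiment(
    seed: int = 0,
    variants=("decorr", "sparse", "decorr-nonneg-off"),
    n_dims: int = 30,
    n_iter: int = 4000,
):
    """Synthetic-corpus evaluation of concept specificity and analogy.

    Trains each variant on the categorical corpus (specificity) and the
    relational corpus (analogy at full and restricted dimensionality).
    """
    cat_spec = corpus_mod.CorpusSpec(seed=seed)
    cat = corpus_mod.generate_categorical_corpus(cat_spec)
    sim = corpus_mod.category_similarity_oracle(cat)
    cat_psi = psi_from_trajectory(
        semantics.corpus_to_trajectory(cat), cat.n_words, WORD_GAMMA
    )
    rel_spec = corpus_mod.CorpusSpec(seed=seed + 1)
    rel = corpus_mod.generate_relational_corpus(rel_spec)
    rel_psi = psi_from_trajectory(
        semantics.corpus_to_trajectory(rel), rel.n_words, WORD_GAMMA
    )

    def word_config(variant, train_seed):
        # word-scale term weights: the word PSI is two orders of magnitude
        # smaller than the spatial one, so the constraint weights shrink
        # accordingly (sparse keeps the L1 weight that yields concept units)
        if variant == "sparse":
            return FactorizationConfig(
                n_dims=n_dims, variant="sparse", beta=0.0, rho_l2=0.0,
                rho_l1=3.0, learning_rate=0.02, n_iter=n_iter, seed=train_seed,
            )
        return FactorizationConfig(
            n_dims=n_dims, variant=variant, beta=100.0, rho_l2=0.5,
            learning_rate=0.02, n_iter=n_iter, seed=train_seed,
        )

    out = {}
    for variant in variants:
        emb_cat = factorize(
            cat_psi.values, word_config(variant, seed), labels=cat.vocabulary
        )
        report = semantics.conceptual_specificity(emb_cat, sim, seed=seed)
        emb_rel = factorize(
            rel_psi.values, word_config(variant, seed), labels=rel.vocabulary
        )
        out[variant] = dict(
            fraction_significant=report.fraction_significant,
            mean_specificity=report.mean_specificity,
            specificity_report=report,
            analogy_full=semantics.analogy_accuracy(emb_rel, rel.quadruples),
            analogy_k2=semantics.analogy_accuracy(emb_rel, rel.quadruples, k_dims=2),
            analogy_k4=semantics.analogy_accuracy(emb_rel, rel.quadruples, k_dims=4),
            embedding_cat=emb_cat,
            embedding_rel=emb_rel,
        )
    out["categorical_bundle"] = cat
    out["relational_bundle"] = rel
    return out
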
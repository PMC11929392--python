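"""Config-driven experiment runner.

An experiment config (dict or YAML file) fully determines a pipeline run:
random walk / corpus -> SR -> PSI -> factorization -> analysis.  The
runner writes embeddings, CSV tables and a JSON manifest of metrics to
the output directory, next to a snapshot of the resolved config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import corpus as corpus_mod
from . import gridness, navigation, semantics, textio
from .factorization import FactorizationConfig, factorize
from .gridworld import build_room, random_walk
from .successor import psi_from_trajectory

_SPACE_DEFAULTS = dict(
    width=30, height=30, barriers=[], gamma=0.99, n_dims=100, variant="decorr",
    walk_length=1_000_000, n_shuffles=100, pi_trials=1000, pi_steps=10,
)
_WORD_DEFAULTS = dict(gamma=0.9, n_dims=30, variant="decorr")

_REQUIRED = ("experiment", "seeds", "out_dir")


def _resolve(config):
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    for key in _REQUIRED:
        if key not in config:
            raise ValueError(f"experiment config is missing required field {key!r}")
    return config


def make_factorization_config(cfg: dict, seed: int) -> FactorizationConfig:
    kw = dict(n_dims=cfg.get("n_dims", 100), variant=cfg.get("variant", "decorr"), seed=seed)
    for key in ("beta", "rho_l2", "rho_l1", "learning_rate", "n_iter"):
        if key in cfg:
            kw[key] = cfg[key]
    if kw["variant"] == "sparse":
        kw.setdefault("beta", 0.0)
        kw.setdefault("rho_l2", 0.0)
    return FactorizationConfig(**kw)


def train_spatial(cfg: dict, seed: int):
    """Walk -> PSI -> embedding for one seed; returns (env, embedding)."""
    env = build_room(cfg["width"], cfg["height"], cfg.get("barriers"))
    walk = random_walk(env, cfg["walk_length"], seed=seed)
    psi = psi_from_trajectory(walk, env.n_states, cfg["gamma"])
    emb = factorize(psi.values, make_factorization_config(cfg, seed))
    return env, emb


def run_experiment(config) -> dict:
    """Execute the named pipeline; returns (and writes) the manifest."""
    cfg = _resolve(config)
    name = cfg["experiment"]
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    runners = {"space": _run_space, "words": _run_words}
    if name not in runners:
        raise ValueError(f"unknown experiment {name!r} (choose from {sorted(runners)})")
    try:
        manifest = runners[name](cfg, out)
    except Exception as exc:
        raise RuntimeError(f"experiment stage {name!r} failed: {exc}") from exc
    manifest["config"] = {k: v for k, v in cfg.items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    return manifest


def _run_space(cfg, out: Path) -> dict:
    cfg = {**_SPACE_DEFAULTS, **cfg}
    per_seed = []
    for seed in cfg["seeds"]:
        env, emb = train_spatial(cfg, seed)
        results, frac_x = gridness.classify_grid_units(
            emb, env, n_shuffles=cfg["n_shuffles"], seed=seed, source="X"
        )
        _, pi_count = navigation.path_integration_success_rate(
            emb, env, n_trials=cfg["pi_trials"], n_steps=cfg["pi_steps"], seed=seed
        )
        textio.write_embedding(out / f"embedding_seed{seed}", emb)
        _write_gridness_table(out / f"gridness_seed{seed}.csv", results)
        per_seed.append(
            dict(
                seed=seed,
                grid_fraction_x=frac_x,
                path_integration_successes=pi_count,
                final_loss=float(emb.loss_trace[-1]),
            )
        )
    return dict(
        experiment="space",
        per_seed=per_seed,
        mean_grid_fraction_x=float(np.mean([r["grid_fraction_x"] for r in per_seed])),
    )


def _run_words(cfg, out: Path) -> dict:
    cfg = {**_WORD_DEFAULTS, **cfg}
    spec = corpus_mod.CorpusSpec(seed=cfg.get("corpus_seed", 0))
    bundle = corpus_mod.generate_categorical_corpus(spec)
    sim = corpus_mod.category_similarity_oracle(bundle)
    traj = semantics.corpus_to_trajectory(bundle)
    from .successor import psi_from_trajectory as _psi

    psi = _psi(traj, bundle.n_words, cfg["gamma"])
    per_seed = []
    for seed in cfg["seeds"]:
        emb = factorize(
            psi.values, make_factorization_config(cfg, seed), labels=bundle.vocabulary
        )
        report = semantics.conceptual_specificity(emb, sim, seed=seed)
        textio.write_embedding(out / f"word_embedding_seed{seed}", emb)
        per_seed.append(
            dict(
                seed=seed,
                fraction_significant=report.fraction_significant,
                mean_specificity=report.mean_specificity,
            )
        )
    return dict(experiment="words", per_seed=per_seed)


def _write_gridness_table(path, results):
    with open(path, "w") as fh:
        fh.write("unit,score,threshold,is_grid\n")
        for r in results:
            fh.write(f"{r.unit},{r.score},{r.null_threshold},{int(r.is_grid)}\n")
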
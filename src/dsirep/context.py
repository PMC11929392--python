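"""Compositional inference of unseen barrier contexts.

Embeddings trained separately in contexts A, B and Φ (no barriers) on the
same room footprint are combined position-wise as

    x_{A+B}(i) = max(x_A(i) + x_B(i) - x_Φ(i), 0)

to predict representations for the unseen two-barrier context A+B.  The
positional index i refers to a cell that is free in every context, so the
composed embedding is defined exactly on the free cells of A+B.  The same
rule is applied to the goal vectors W so that navigation can run in the
composed context.  Per-unit representational distance between two
contexts is the summed squared difference of a unit's values at aligned
positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .factorization import DSIEmbedding
from .gridworld import EnvGraph


@dataclass
class ContextSet:
    """Aligned embeddings for named contexts sharing one room footprint."""

    envs: dict       # name -> EnvGraph
    embeddings: dict  # name -> DSIEmbedding
    common: list      # (row, col) cells free in every context, raster order
    alignment: dict   # name -> state indices of the common cells

    @classmethod
    def build(cls, contexts: dict) -> "ContextSet":
        """``contexts`` maps name -> (env, embedding)."""
        names = list(contexts)
        envs = {n: contexts[n][0] for n in names}
        embs = {n: contexts[n][1] for n in names}
        w, h = envs[names[0]].width, envs[names[0]].height
        for n in names:
            if (envs[n].width, envs[n].height) != (w, h):
                raise ValueError("contexts must share the same room footprint")
            if embs[n].n_states != envs[n].n_states:
                raise ValueError(f"embedding/environment size mismatch in {n!r}")
        free_sets = [set(envs[n].states) for n in names]
        common = sorted(set.intersection(*free_sets))
        alignment = {
            n: np.array([envs[n].index_of[pos] for pos in common]) for n in names
        }
        return cls(envs=envs, embeddings=embs, common=common, alignment=alignment)

    def aligned(self, name: str, source: str = "X") -> np.ndarray:
        emb = self.embeddings[name]
        M = emb.X if source == "X" else emb.W
        return M[self.alignment[name]]


@dataclass
class UnitDistanceTable:
    distances: np.ndarray           # per-unit d_k >= 0
    labels: np.ndarray | None = None  # per-unit is_grid labels, optional


def _check_out_env(ctx: ContextSet, out_env: EnvGraph):
    if set(out_env.states) - set(ctx.common):
        raise ValueError(
            "output environment has free cells outside the aligned footprint"
        )


def compose_context(
    ctx: ContextSet, out_env: EnvGraph, a: str = "A", b: str = "B", phi: str = "PHI"
) -> DSIEmbedding:
    """Compose x(A) + x(B) - x(Φ) (clipped at 0) on the free cells of
    ``out_env`` — both X and W."""
    return compose_partial(ctx, out_env, units=None, a=a, b=b, phi=phi)


def compose_partial(
    ctx: ContextSet,
    out_env: EnvGraph,
    units=None,
    top_k: int | None = None,
    a: str = "A",
    b: str = "B",
    phi: str = "PHI",
) -> DSIEmbedding:
    """Composition restricted to a unit subset; other units copy context A.

    ``units=None`` composes every unit; ``top_k`` selects the k units with
    the largest representational distance between contexts ``b`` and
    ``phi``.  An explicitly empty subset returns context A with a warning.
    """
    _check_out_env(ctx, out_env)
    D = ctx.embeddings[a].n_dims
    if top_k is not None:
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        d = unit_distance(ctx, b, phi).distances
        units = np.argsort(d)[::-1][: min(top_k, D)]
    if units is None:
        sel = np.ones(D, dtype=bool)
    else:
        sel = np.zeros(D, dtype=bool)
        sel[np.asarray(list(units), dtype=int)] = True
        if not sel.any():
            warnings.warn("empty unit subset; returning context A unchanged")
    pos_index = {pos: i for i, pos in enumerate(ctx.common)}
    rows = np.array([pos_index[pos] for pos in out_env.states])

    out = {}
    for source in ("X", "W"):
        A = ctx.aligned(a, source)[rows]
        B = ctx.aligned(b, source)[rows]
        P = ctx.aligned(phi, source)[rows]
        comp = A.copy()
        comp[:, sel] = np.maximum(A[:, sel] + B[:, sel] - P[:, sel], 0.0)
        out[source] = comp
    base = ctx.embeddings[a]
    return DSIEmbedding(
        X=out["X"], W=out["W"], variant=base.variant, config=base.config
    )


def unit_distance(ctx: ContextSet, x: str, y: str, source: str = "X") -> UnitDistanceTable:
    """Per-unit representational distance d_k = sum_i (x_k(i) - y_k(i))^2
    over aligned positions."""
    Xa = ctx.aligned(x, source)
    Xb = ctx.aligned(y, source)
    return UnitDistanceTable(distances=((Xa - Xb) ** 2).sum(axis=0))


def grid_vs_nongrid_distance(
    ctx: ContextSet, gridness_labels: np.ndarray, x: str = "B", y: str = "PHI"
):
    """Mean representational distance of grid vs non-grid units.

    ``gridness_labels`` are per-unit booleans computed in the no-barrier
    context.  Returns ``(means, table)`` where means maps group name to
    the mean distance (NaN with a warning when a group is empty).
    """
    labels = np.asarray(gridness_labels, dtype=bool)
    table = unit_distance(ctx, x, y)
    table.labels = labels
    d = table.distances
    if labels.shape != d.shape:
        raise ValueError("labels must have one entry per unit")
    means = {}
    for name, sel in (("grid", labels), ("nongrid", ~labels)):
        if sel.any():
            means[name] = float(d[sel].mean())
        else:
            warnings.warn(f"group {name!r} is empty; mean undefined")
            means[name] = float("nan")
    return means, table
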
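"""Plain-text readers and writers for embeddings, environments, trajectories.

Embeddings use the word2vec text dialect: a header line ``N D`` followed
by one ``label v1 ... vD`` line per row.  Values are printed with
``repr`` precision so a write/read round-trip is bit-identical.
"""

from __future__ import annotations

import numpy as np

from .factorization import DSIEmbedding
from .gridworld import EnvGraph, Trajectory, build_room


def write_embedding_matrix(path, labels, M: np.ndarray):
    M = np.asarray(M, dtype=float)
    if len(labels) != M.shape[0]:
        raise ValueError("one label per row required")
    with open(path, "w") as fh:
        fh.write(f"{M.shape[0]} {M.shape[1]}\n")
        for label, row in zip(labels, M):
            fh.write(str(label) + " " + " ".join(repr(float(x)) for x in row) + "\n")


def read_embedding_matrix(path):
    """Returns ``(labels, matrix)``; malformed lines raise with the line
    number."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: line 1: malformed header (expected 'N D')")
        try:
            n, d = int(header[0]), int(header[1])
        except ValueError:
            raise ValueError(f"{path}: line 1: non-integer header") from None
        labels, rows = [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != d + 1:
                raise ValueError(
                    f"{path}: line {ln}: expected {d + 1} fields, got {len(parts)}"
                )
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(labels) != n:
        raise ValueError(f"{path}: header promised {n} rows, found {len(labels)}")
    return labels, np.array(rows)


def write_embedding(prefix, embedding: DSIEmbedding):
    """Write X and W beside each other as ``<prefix>.x.txt`` / ``.w.txt``."""
    labels = embedding.labels or list(range(embedding.n_states))
    write_embedding_matrix(f"{prefix}.x.txt", labels, embedding.X)
    write_embedding_matrix(f"{prefix}.w.txt", labels, embedding.W)


def read_embedding(prefix, variant: str = "decorr") -> DSIEmbedding:
    labels, X = read_embedding_matrix(f"{prefix}.x.txt")
    labels_w, W = read_embedding_matrix(f"{prefix}.w.txt")
    if labels != labels_w:
        raise ValueError("X and W label mismatch")
    return DSIEmbedding(X=X, W=W, variant=variant, labels=labels)


def write_env_config(path, env: EnvGraph):
    """Key-value text: width, height, and one ``wall`` line per blocked
    cell (inclusive single-cell ranges)."""
    with open(path, "w") as fh:
        fh.write(f"width {env.width}\n")
        fh.write(f"height {env.height}\n")
        for r, c in sorted(env.blocked):
            fh.write(f"wall {r} {c} {r} {c}\n")


def read_env_config(path) -> EnvGraph:
    width = height = None
    walls = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            key = parts[0]
            if key == "width":
                width = int(parts[1])
            elif key == "height":
                height = int(parts[1])
            elif key == "wall":
                r1, c1, r2, c2 = map(int, parts[1:5])
                walls.append(((r1, c1), (r2, c2)))
            else:
                raise ValueError(f"{path}: line {ln}: unknown key {key!r}")
    if width is None or height is None:
        raise ValueError(f"{path}: missing width or height")
    return build_room(width, height, walls)


def write_trajectory(path, trajectory: Trajectory, env: EnvGraph | None = None):
    with open(path, "w") as fh:
        if env is not None:
            fh.write(f"# env {env.config_hash()}\n")
        for s in trajectory.states:
            fh.write(f"{s}\n")


def read_trajectory(path) -> Trajectory:
    states = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            states.append(int(line))
    return Trajectory(states=np.array(states, dtype=np.int64))
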
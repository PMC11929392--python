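"""Discrete 2-D gridworld environments and random-walk trajectories.

States are the free cells of a ``height x width`` room, indexed in raster
order (row-major over free cells).  Movement is 4-neighbour (N, S, E, W);
``N`` decreases the row index so rate maps render in conventional raster
orientation.  Barriers are blocked cells; the free-cell graph of every
environment must be connected.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

ACTIONS: tuple[str, ...] = ("N", "S", "E", "W")
_DELTA = {"N": (-1, 0), "S": (1, 0), "E": (0, 1), "W": (0, -1)}
_REVERSE = {"N": "S", "S": "N", "E": "W", "W": "E"}


class DisconnectedEnvironmentError(ValueError):
    """Raised when barriers split the free cells into unreachable components."""


@dataclass(frozen=True)
class EnvGraph:
    """Discrete state space of a rectangular room with blocked cells.

    Attributes
    ----------
    width, height : int
        Room dimensions in cells.
    blocked : frozenset of (row, col)
        Barrier cells (not part of the state space).
    states : tuple of (row, col)
        Free cells in raster order; the tuple position is the state index.
    adjacency : tuple of dict
        Per state, the available actions mapped to the successor state index.
    """

    width: int
    height: int
    blocked: frozenset
    states: tuple
    adjacency: tuple

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def index_of(self) -> dict:
        return {pos: i for i, pos in enumerate(self.states)}

    def neighbor_array(self) -> np.ndarray:
        """(n_states, 4) successor indices per action, -1 where unavailable."""
        out = np.full((self.n_states, len(ACTIONS)), -1, dtype=np.int64)
        for s, adj in enumerate(self.adjacency):
            for a, s2 in adj.items():
                out[s, ACTIONS.index(a)] = s2
        return out

    def degree(self) -> np.ndarray:
        return np.array([len(adj) for adj in self.adjacency], dtype=np.int64)

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic matrix of the default (uniform over available
        actions) policy."""
        T = np.zeros((self.n_states, self.n_states))
        for s, adj in enumerate(self.adjacency):
            p = 1.0 / len(adj)
            for s2 in adj.values():
                T[s, s2] += p
        return T

    def config_hash(self) -> str:
        import hashlib

        key = f"{self.width}x{self.height}:{sorted(self.blocked)}"
        return hashlib.sha1(key.encode()).hexdigest()[:12]


@dataclass
class Trajectory:
    """A sequence of state indices, optionally with the generating actions.

    ``breaks`` lists positions where a new independent segment starts
    (used for document boundaries in token streams); discounted-count
    estimators never carry credit across a break.
    """

    states: np.ndarray
    actions: Sequence[str] | None = None
    breaks: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.actions is not None and len(self.actions) != len(self.states) - 1:
            raise ValueError("actions must have length len(states) - 1")

    def __len__(self) -> int:
        return len(self.states)

    def segments(self):
        """Yield (start, stop) half-open bounds of independent segments."""
        bounds = [0, *sorted(self.breaks), len(self.states)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b > a:
                yield a, b


def _expand_barrier_spec(spec, width: int, height: int) -> set:
    """Accept single cells ``(r, c)`` or inclusive rectangles
    ``((r1, c1), (r2, c2))`` (wall segments)."""
    cells: set = set()
    if spec is None:
        return cells
    for item in spec:
        item = tuple(item)
        if len(item) == 2 and np.isscalar(item[0]):
            cells.add((int(item[0]), int(item[1])))
        else:
            (r1, c1), (r2, c2) = item
            for r in range(min(r1, r2), max(r1, r2) + 1):
                for c in range(min(c1, c2), max(c1, c2) + 1):
                    cells.add((r, c))
    for r, c in cells:
        if not (0 <= r < height and 0 <= c < width):
            raise ValueError(f"barrier cell {(r, c)} outside {height}x{width} room")
    return cells


def build_room(width: int, height: int, barrier_spec: Iterable | None = None) -> EnvGraph:
    """Build a connected rectangular room with optional barrier cells.

    Raises :class:`DisconnectedEnvironmentError` (naming the unreachable
    component sizes) if the barriers split the free-cell graph, and
    ``ValueError`` if fewer than 2 free cells remain or a barrier lies
    outside the room.
    """
    if width < 2 or height < 2:
        raise ValueError("room must be at least 2x2")
    blocked = _expand_barrier_spec(barrier_spec, width, height)
    states = tuple(
        (r, c) for r in range(height) for c in range(width) if (r, c) not in blocked
    )
    if len(states) < 2:
        raise ValueError("fewer than 2 free cells remain")
    index = {pos: i for i, pos in enumerate(states)}
    adjacency = []
    for r, c in states:
        adj = {}
        for a, (dr, dc) in _DELTA.items():
            npos = (r + dr, c + dc)
            if npos in index:
                adj[a] = index[npos]
        adjacency.append(adj)
    env = EnvGraph(width, height, frozenset(blocked), states, tuple(adjacency))
    comp = _components(env)
    if comp.max() > 0:
        sizes = np.bincount(comp)
        raise DisconnectedEnvironmentError(
            f"free-cell graph is disconnected: {len(sizes)} components of sizes "
            f"{sizes.tolist()} (largest kept first); adjust the barrier layout"
        )
    return env


def _components(env: EnvGraph) -> np.ndarray:
    label = np.full(env.n_states, -1, dtype=np.int64)
    current = 0
    for seed in range(env.n_states):
        if label[seed] >= 0:
            continue
        queue = deque([seed])
        label[seed] = current
        while queue:
            s = queue.popleft()
            for s2 in env.adjacency[s].values():
                if label[s2] < 0:
                    label[s2] = current
                    queue.append(s2)
        current += 1
    return label


def random_walk(env: EnvGraph, length: int, start="uniform", seed: int = 0) -> Trajectory:
    """Uniform random walk over available actions (the default policy).

    ``length`` counts states, so the trajectory takes ``length - 1`` moves.
    ``start`` is a state index or ``"uniform"`` for a uniformly random
    initial state.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    if start == "uniform":
        s = int(rng.integers(env.n_states))
    else:
        s = int(start)
        if not 0 <= s < env.n_states:
            raise ValueError(f"start state {s} out of range")
    nbr = env.neighbor_array()
    avail = [np.flatnonzero(nbr[i] >= 0) for i in range(env.n_states)]
    states = np.empty(length, dtype=np.int64)
    actions = []
    states[0] = s
    # pre-draw uniforms; index into the per-state action list
    u = rng.random(max(length - 1, 1))
    for t in range(length - 1):
        acts = avail[s]
        a = acts[int(u[t] * len(acts))]
        actions.append(ACTIONS[a])
        s = int(nbr[s, a])
        states[t + 1] = s
    return Trajectory(states=states, actions=actions)


def shortest_path_length(env: EnvGraph, s: int, g: int) -> int:
    """Breadth-first-search distance in moves between two states."""
    return int(bfs_distances(env, g)[s])


def bfs_distances(env: EnvGraph, source: int) -> np.ndarray:
    """BFS distances from ``source`` to every state (raises if any state is
    unreachable, which cannot happen for environments built here)."""
    if not 0 <= source < env.n_states:
        raise ValueError("source out of range")
    dist = np.full(env.n_states, -1, dtype=np.int64)
    dist[source] = 0
    queue = deque([source])
    while queue:
        s = queue.popleft()
        for s2 in env.adjacency[s].values():
            if dist[s2] < 0:
                dist[s2] = dist[s] + 1
                queue.append(s2)
    if (dist < 0).any():
        raise ValueError("unreachable states from source")
    return dist
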
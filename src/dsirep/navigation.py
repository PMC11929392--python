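"""Path integration and goal-directed navigation over DSI embeddings.

Path integration propagates a state vector through movement-conditional
linear maps (one D x D matrix per action, fitted by ridge least squares
over all legal transitions) and decodes the current state as the nearest
state vector.  Goal-directed navigation treats ``x(s') . w(goal)`` as a
value proxy — it approximates the successor-information value of s' with
the goal as destination — and ascends it greedily over the neighbours of
the current state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .factorization import DSIEmbedding
from .gridworld import ACTIONS, EnvGraph, Trajectory, bfs_distances


@dataclass
class MovementModel:
    matrices: dict          # action label -> D x D matrix
    X: np.ndarray           # decoder reference (state vectors)
    residuals: dict         # action label -> mean squared fit residual
    metric: str = "cosine"  # decoder similarity ("cosine" | "dot")


@dataclass
class NavigationTrial:
    start: int
    goal: int
    path: Trajectory
    reached: bool
    normalized_length: float


def fit_movement_models(
    embedding: DSIEmbedding, env: EnvGraph, ridge: float = 1e-6, metric: str = "cosine"
) -> MovementModel:
    """Fit per-action linear maps M_a minimising ``sum ||x(s') - M_a x(s)||^2``
    over all legal transitions of action a (ridge-regularised)."""
    X = embedding.X
    D = X.shape[1]
    matrices, residuals = {}, {}
    for a in ACTIONS:
        src = [s for s, adj in enumerate(env.adjacency) if a in adj]
        if not src:
            warnings.warn(f"action {a!r} has no legal transition; using identity")
            matrices[a] = np.eye(D)
            residuals[a] = float("nan")
            continue
        dst = [env.adjacency[s][a] for s in src]
        Xin, Xout = X[src], X[dst]
        G = Xin.T @ Xin + ridge * np.eye(D)
        M = np.linalg.solve(G, Xin.T @ Xout).T
        matrices[a] = M
        residuals[a] = float(((Xout - Xin @ M.T) ** 2).mean())
    return MovementModel(matrices=matrices, X=X, residuals=residuals, metric=metric)


def _decode(model: MovementModel, V: np.ndarray) -> np.ndarray:
    """Nearest-state decoding of a batch of vectors (rows of V)."""
    X = model.X
    if model.metric == "cosine":
        Xn = X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)
        Vn = V / np.maximum(np.linalg.norm(V, axis=1, keepdims=True), 1e-12)
        S = Vn @ Xn.T
    else:
        S = V @ X.T
    return np.argmax(S, axis=1)


def path_integrate(
    model: MovementModel, start: int, actions, snap_each_step: bool = True
) -> Trajectory:
    """Decode the state sequence implied by a movement sequence.

    With ``snap_each_step`` the working vector is reset to the decoded
    state's vector after every step (attractor-style denoising).
    """
    decoded = [int(start)]
    v = model.X[start].copy()
    for a in actions:
        if a not in model.matrices:
            raise ValueError(f"unknown action {a!r}")
        v = model.matrices[a] @ v
        s_hat = int(_decode(model, v[None])[0])
        decoded.append(s_hat)
        if snap_each_step:
            v = model.X[s_hat].copy()
    return Trajectory(states=np.array(decoded), actions=list(actions))


def path_integration_success_rate(
    embedding: DSIEmbedding,
    env: EnvGraph,
    n_trials: int = 1000,
    n_steps: int = 10,
    seed: int = 0,
    model: MovementModel | None = None,
    snap_each_step: bool = True,
):
    """Fraction of trials whose decoded path matches the true path at every
    step (random start, ``n_steps`` random legal movements per trial).

    Returns ``(success_fraction, success_count)``.  Vectorised over trials.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if model is None:
        model = fit_movement_models(embedding, env)
    rng = np.random.default_rng(seed)
    nbr = env.neighbor_array()
    avail = [np.flatnonzero(nbr[s] >= 0) for s in range(env.n_states)]

    true_state = rng.integers(env.n_states, size=n_trials)
    V = model.X[true_state].copy()
    ok = np.ones(n_trials, dtype=bool)
    u = rng.random((n_steps, n_trials))
    for t in range(n_steps):
        acts = np.empty(n_trials, dtype=np.int64)
        for i in range(n_trials):
            options = avail[true_state[i]]
            acts[i] = options[int(u[t, i] * len(options))]
        next_state = nbr[true_state, acts]
        for ai, a in enumerate(ACTIONS):
            sel = acts == ai
            if sel.any():
                V[sel] = V[sel] @ model.matrices[a].T
        decoded = _decode(model, V)
        ok &= decoded == next_state
        if snap_each_step:
            V = model.X[decoded].copy()
        true_state = next_state
    count = int(ok.sum())
    return count / n_trials, count


def navigate(
    embedding: DSIEmbedding,
    env: EnvGraph,
    start: int,
    goal: int,
    max_steps: int = 200,
    seed: int = 0,
    temperature: float = 0.0,
) -> NavigationTrial:
    """Goal-directed navigation on the value proxy x(s') . w(goal).

    With ``temperature == 0`` (default) the move is greedy: the neighbour
    maximising the proxy, ties broken uniformly at random.  A positive
    temperature applies the linear-RL decision rule — neighbours sampled
    with probability proportional to ``exp(value / T)`` — which escapes
    the local two-cycles the rectified value field exhibits next to
    barriers (greedy provably loops there even with the exact kernel).
    Runs until the goal is reached or ``max_steps`` moves were taken.
    The normalized length is the number of moves over the BFS
    shortest-path length (defined as 1.0 when start == goal).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    rng = np.random.default_rng(seed)
    w_goal = embedding.W[goal]
    value = embedding.X @ w_goal
    states = [int(start)]
    actions = []
    s = int(start)
    while s != goal and len(actions) < max_steps:
        adj = env.adjacency[s]
        acts = list(adj.keys())
        vals = np.array([value[adj[a]] for a in acts])
        if temperature > 0:
            p = np.exp((vals - vals.max()) / temperature)
            a = acts[int(rng.choice(len(acts), p=p / p.sum()))]
        else:
            best = np.flatnonzero(vals == vals.max())
            a = acts[int(rng.choice(best))]
        s = adj[a]
        actions.append(a)
        states.append(s)
    reached = s == goal
    shortest = bfs_distances(env, goal)[start]
    if shortest == 0:
        norm = 1.0
    else:
        norm = len(actions) / shortest
    return NavigationTrial(
        start=int(start),
        goal=int(goal),
        path=Trajectory(states=np.array(states), actions=actions),
        reached=bool(reached),
        normalized_length=float(norm),
    )


def navigation_benchmark(
    embedding: DSIEmbedding,
    env: EnvGraph,
    n_trials: int = 1000,
    seed: int = 0,
    max_steps_factor: int = 8,
    start_goal_sampler=None,
    temperature: float = 0.0,
):
    """Run many navigation trials with random start/goal pairs.

    ``start_goal_sampler(rng) -> (start, goal)`` customises sampling
    (default: uniform distinct states).  The per-trial step cap is
    ``max_steps_factor x`` the shortest path.  Returns a dict with the
    trial list, mean normalized path length (non-reaching trials enter at
    their capped length), and the reach rate.
    """
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_trials):
        if start_goal_sampler is None:
            start, goal = rng.choice(env.n_states, size=2, replace=False)
        else:
            start, goal = start_goal_sampler(rng)
        shortest = max(int(bfs_distances(env, int(goal))[int(start)]), 1)
        trial = navigate(
            embedding, env, int(start), int(goal),
            max_steps=max_steps_factor * shortest,
            seed=int(rng.integers(2**31)),
            temperature=temperature,
        )
        trials.append(trial)
    mean_norm = float(np.mean([t.normalized_length for t in trials]))
    reach_rate = float(np.mean([t.reached for t in trials]))
    return {"trials": trials, "mean_normalized_length": mean_norm, "reach_rate": reach_rate}
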
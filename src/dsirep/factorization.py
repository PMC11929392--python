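"""Constrained factorization of the PSI matrix into paired embeddings.

The PSI matrix is approximated by a low-rank nonnegative product
``PSI(s, s') ~ x(s) . w(s')`` with X holding the state vectors and W the
goal vectors (both ``N_s x D``, D < N_s).  Two named variants mirror two
constraint regimes:

``decorr``
    nonnegativity + squared pairwise Pearson correlations between the
    columns (units) of X + L2 norms of X and W.  Decorrelation plus
    nonnegativity is the regime under which hexagonal grid-like units
    emerge from spatial PSI.
``sparse``
    nonnegativity + L1 norms of X and W (no decorrelation), which favours
    spatially localised, place-cell-like units.
``decorr-nonneg-off``
    the decorr objective with the nonnegativity projection disabled
    (ablation).

Optimisation is projected gradient descent with Adam-style per-parameter
step scaling; nonnegativity is enforced by clipping at zero after every
step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_VARIANTS = ("decorr", "sparse", "decorr-nonneg-off")


@dataclass
class FactorizationConfig:
    """Hyper-parameters of the factorization.

    Term weights multiply plain sums: the reconstruction term is the full
    sum of squared errors, ``beta`` weights the summed squared unit-pair
    correlations of X, ``rho_l2``/``rho_l1`` weight the summed squared /
    absolute entries of X and W.  Defaults were chosen on the 30x30
    open-room fixture and are recorded with every trained embedding.
    """

    n_dims: int = 100
    variant: str = "decorr"
    beta: float = 6000.0
    rho_l2: float = 2.5
    rho_l1: float = 1.0
    learning_rate: float = 0.02
    n_iter: int = 6000
    seed: int = 0
    nonneg: bool = True
    lr_decay: str = "none"    # "none" | "cosine"
    init: str = "random"      # "random" | "nndsvd"
    dtype: str = "float32"    # compute precision of the optimisation

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if min(self.beta, self.rho_l2, self.rho_l1) < 0:
            raise ValueError("term weights must be nonnegative")
        if self.variant == "decorr-nonneg-off":
            self.nonneg = False

    @property
    def use_decorr(self) -> bool:
        return self.variant in ("decorr", "decorr-nonneg-off")


def decorr_config(n_dims: int = 100, **kw) -> FactorizationConfig:
    return FactorizationConfig(n_dims=n_dims, variant="decorr", **kw)


def sparse_config(n_dims: int = 100, **kw) -> FactorizationConfig:
    kw.setdefault("rho_l1", 1.0)
    return FactorizationConfig(n_dims=n_dims, variant="sparse", beta=0.0, rho_l2=0.0, **kw)


def nonneg_off_config(n_dims: int = 100, **kw) -> FactorizationConfig:
    return FactorizationConfig(n_dims=n_dims, variant="decorr-nonneg-off", **kw)


@dataclass
class DSIEmbedding:
    """Paired state vectors X and goal vectors W (``N_s x D`` each)."""

    X: np.ndarray
    W: np.ndarray
    variant: str
    config: FactorizationConfig | None = None
    loss_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))
    labels: list | None = None  # state indices or word strings

    @property
    def n_states(self) -> int:
        return self.X.shape[0]

    @property
    def n_dims(self) -> int:
        return self.X.shape[1]

    def dead_units(self, tol: float = 1e-12) -> np.ndarray:
        return np.flatnonzero(
            (np.abs(self.X) <= tol).all(axis=0) | (np.abs(self.W) <= tol).all(axis=0)
        )


def reconstruct(embedding: DSIEmbedding) -> np.ndarray:
    """The rank-D approximation ``X @ W.T`` of the PSI matrix."""
    return embedding.X @ embedding.W.T


def _column_corr(X: np.ndarray, eps: float = 1e-12):
    """Pearson correlation matrix between columns of X, with centred and
    normalised intermediates returned for gradient computation."""
    U = X - X.mean(axis=0, keepdims=True)
    s = np.sqrt((U**2).sum(axis=0))
    s = np.maximum(s, eps)
    Uh = U / s
    C = Uh.T @ Uh
    return C, Uh, s


def objective(embedding: DSIEmbedding, psi: np.ndarray, config: FactorizationConfig):
    """Objective value with per-term breakdown (dict)."""
    total, terms, _, _ = _objective_grad(embedding.X, embedding.W, psi, config)
    return total, terms


def _objective_grad(X, W, psi, config: FactorizationConfig):
    if np.isnan(X).any() or np.isnan(W).any() or np.isnan(psi).any():
        raise ValueError("NaN in factorization inputs")
    R = X @ W.T - psi
    recon = float((R**2).sum())
    gX = 2.0 * (R @ W)
    gW = 2.0 * (R.T @ X)
    terms = {"reconstruction": recon, "decorrelation": 0.0, "l2": 0.0, "l1": 0.0}
    if config.use_decorr and config.beta > 0:
        C, Uh, s = _column_corr(X)
        mask = ~np.eye(C.shape[0], dtype=bool)
        # sum over unordered unit pairs: an identical pair contributes 1
        terms["decorrelation"] = config.beta * 0.5 * float((C[mask] ** 2).sum())
        # d/dUh of (1/2) sum_{k!=l} C_kl^2 is Uh @ (2 C*mask); chain through
        # the normalisation Uh = U/||U|| and the centering of U.
        B = 2.0 * (C * mask)
        A = Uh @ B
        A = (A - Uh * (Uh * A).sum(axis=0, keepdims=True)) / s
        A -= A.mean(axis=0, keepdims=True)
        gX += config.beta * A
    if config.variant == "sparse":
        terms["l1"] = config.rho_l1 * float(np.abs(X).sum() + np.abs(W).sum())
        gX += config.rho_l1 * np.sign(X)
        gW += config.rho_l1 * np.sign(W)
    else:
        terms["l2"] = config.rho_l2 * float((X**2).sum() + (W**2).sum())
        gX += 2.0 * config.rho_l2 * X
        gW += 2.0 * config.rho_l2 * W
    total = float(sum(terms.values()))
    return total, terms, gX, gW


class DivergenceError(RuntimeError):
    pass


def factorize(
    psi: np.ndarray,
    config: FactorizationConfig,
    labels=None,
    warm_start: tuple | None = None,
    anchor_weight: float = 0.0,
) -> DSIEmbedding:
    """Fit X, W >= 0 (unless disabled) to ``psi`` by projected Adam.

    Initialisation is seeded uniform on [0, c) with c scaled so the initial
    product matches the mean PSI magnitude; ``warm_start=(X0, W0)`` starts
    from an existing solution instead (used for continual training across
    contexts, which preserves unit identity); a positive ``anchor_weight``
    mu additionally adds a proximal penalty mu*(||X-X0||^2 + ||W-W0||^2),
    so adaptation to a new context concentrates on the entries the new
    reconstruction actually requires to change.  A unit whose X or W column
    stays identically zero for more than 10% of the iterations is
    re-initialised once (dead-unit rescue).  Raises
    :class:`DivergenceError` when the loss exceeds 10x its initial value.
    """
    psi = np.asarray(psi, dtype=np.dtype(config.dtype))
    if psi.ndim != 2 or psi.shape[0] != psi.shape[1]:
        raise ValueError("psi must be square")
    if (psi < 0).any():
        raise ValueError("psi must be nonnegative")
    n = psi.shape[0]
    D = config.n_dims
    if D >= n:
        raise ValueError("n_dims must be smaller than the number of states")
    rng = np.random.default_rng(config.seed)
    scale = np.sqrt(max(psi.mean(), 1e-12) / D)
    if warm_start is not None:
        X0, W0 = warm_start
        if X0.shape != (n, D) or W0.shape != (n, D):
            raise ValueError("warm-start matrices must have shape (n_states, n_dims)")
        X, W = X0.copy(), W0.copy()
        X0a = X0.astype(psi.dtype)
        W0a = W0.astype(psi.dtype)
    elif config.init == "nndsvd":
        # SVD-based nonnegative init (NNDSVDa) speeds convergence greatly
        from sklearn.decomposition._nmf import _initialize_nmf

        Xi, Hi = _initialize_nmf(psi, D, init="nndsvda", random_state=config.seed)
        X, W = np.ascontiguousarray(Xi), np.ascontiguousarray(Hi.T)
    else:
        X = rng.uniform(0.0, 2.0 * scale, size=(n, D))
        W = rng.uniform(0.0, 2.0 * scale, size=(n, D))
        if not config.nonneg:
            X -= scale
            W -= scale
    X = X.astype(psi.dtype)
    W = W.astype(psi.dtype)

    mX = np.zeros_like(X); vX = np.zeros_like(X)
    mW = np.zeros_like(W); vW = np.zeros_like(W)
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    trace = np.empty(config.n_iter)
    initial = None
    dead_iters = np.zeros(D, dtype=np.int64)
    rescued = np.zeros(D, dtype=bool)
    dead_budget = max(int(0.1 * config.n_iter), 1)

    if anchor_weight > 0 and warm_start is None:
        raise ValueError("anchor_weight requires warm_start")

    for it in range(config.n_iter):
        total, _, gX, gW = _objective_grad(X, W, psi, config)
        if anchor_weight > 0:
            dX = X - X0a
            dW = W - W0a
            total += anchor_weight * float((dX**2).sum() + (dW**2).sum())
            gX += 2.0 * anchor_weight * dX
            gW += 2.0 * anchor_weight * dW
        trace[it] = total
        if initial is None:
            initial = total
        if total > 10.0 * initial:
            raise DivergenceError(
                "factorization loss exceeded 10x its initial value; "
                "reduce the learning rate"
            )
        t = it + 1
        if config.lr_decay == "cosine":
            step = lr * 0.5 * (1.0 + np.cos(np.pi * it / config.n_iter))
        else:
            step = lr
        mX = b1 * mX + (1 - b1) * gX; vX = b2 * vX + (1 - b2) * gX**2
        mW = b1 * mW + (1 - b1) * gW; vW = b2 * vW + (1 - b2) * gW**2
        corr1 = 1 - b1**t; corr2 = 1 - b2**t
        X -= step * (mX / corr1) / (np.sqrt(vX / corr2) + eps)
        W -= step * (mW / corr1) / (np.sqrt(vW / corr2) + eps)
        if config.nonneg:
            np.maximum(X, 0.0, out=X)
            np.maximum(W, 0.0, out=W)
            dead = (X.max(axis=0) <= 0.0) | (W.max(axis=0) <= 0.0)
            dead_iters[dead] += 1
            revive = dead & (dead_iters > dead_budget) & ~rescued
            if revive.any():
                k = int(revive.sum())
                X[:, revive] = rng.uniform(0.0, 2.0 * scale, size=(n, k))
                W[:, revive] = rng.uniform(0.0, 2.0 * scale, size=(n, k))
                rescued |= revive
                dead_iters[revive] = 0

    return DSIEmbedding(
        X=X.astype(np.float64), W=W.astype(np.float64), variant=config.variant,
        config=replace(config), loss_trace=trace, labels=labels,
    )


def mean_abs_column_corr(X: np.ndarray) -> float:
    """Mean absolute off-diagonal Pearson correlation between columns."""
    C, _, _ = _column_corr(X)
    mask = ~np.eye(C.shape[0], dtype=bool)
    return float(np.abs(C[mask]).mean())
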
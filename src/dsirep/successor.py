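"""Successor representation (SR), occupancy, and successor information.

The SR under a fixed policy is the discounted expected future occupancy

    SR(s, s') = E[ sum_t gamma^t 1{s_t = s'} | s_0 = s ],

including the t = 0 term.  Successor information normalises its log by the
self-information of the destination state,

    SI(s, s') = log SR(s, s') - log P(s'),

and the positive part PSI = max(SI, 0) discards weak long-range
relationships, in direct analogy with positive pointwise mutual
information for word co-occurrence.  Natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .gridworld import Trajectory

EPS_FLOOR = 1e-12


@dataclass
class SRMatrix:
    values: np.ndarray
    gamma: float
    source: str  # "empirical" | "analytic"
    unvisited: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))


@dataclass
class OccupancyVector:
    values: np.ndarray
    zero_visit: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))


@dataclass
class PSIMatrix:
    values: np.ndarray
    gamma: float
    epsilon_floor: float = EPS_FLOOR
    n_degenerate: int = 0  # entries zeroed because SR or P hit the floor


def sr_analytic(transition_matrix: np.ndarray, gamma: float) -> SRMatrix:
    """Closed-form SR ``(I - gamma T)^-1`` of a row-stochastic matrix.

    Row sums equal ``1 / (1 - gamma)`` exactly (geometric series).
    """
    T = np.asarray(transition_matrix, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must sum to 1")
    if (T < 0).any():
        raise ValueError("transition matrix entries must be nonnegative")
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1)")
    M = np.linalg.inv(np.eye(len(T)) - gamma * T)
    return SRMatrix(values=M, gamma=gamma, source="analytic")


def sr_empirical(trajectory: Trajectory, n_states: int, gamma: float) -> SRMatrix:
    """Estimate the SR by discounted forward counting along a trajectory.

    For each visit of state s at time t the future indicator sum
    ``sum_k gamma^k 1{s_{t+k} = s'}`` (truncated at the segment end) is
    accumulated; row s is the average over visits of s.  Segment breaks in
    the trajectory reset the window.  Rows of never-visited states are left
    at zero and flagged in ``unvisited``.
    """
    if not 0 <= gamma < 1:
        raise ValueError("gamma must lie in [0, 1)")
    states = trajectory.states
    if len(states) < 2:
        raise ValueError("trajectory must contain at least 2 states")
    if states.min() < 0 or states.max() >= n_states:
        raise ValueError("state index out of range")
    M = np.zeros((n_states, n_states))
    visits = np.zeros(n_states, dtype=np.int64)
    for a, b in trajectory.segments():
        seg = states[a:b]
        visits += np.bincount(seg, minlength=n_states)
        # discounted tail sums per destination column via a reversed
        # first-order IIR filter: f_t = 1{s_t = col} + gamma * f_{t+1}
        for col in np.unique(seg):
            ind = (seg == col).astype(float)
            f = lfilter([1.0], [1.0, -gamma], ind[::-1])[::-1]
            M[:, col] += np.bincount(seg, weights=f, minlength=n_states)
    visited = visits > 0
    M[visited] /= visits[visited, None]
    return SRMatrix(
        values=M,
        gamma=gamma,
        source="empirical",
        unvisited=np.flatnonzero(~visited),
    )


def transition_counts(trajectory: Trajectory, n_states: int) -> np.ndarray:
    """Row-normalised empirical transition matrix of a trajectory (segment
    breaks contribute no transition).  Rows of never-exited states are
    uniform (they cannot influence downstream SR values of visited rows
    materially)."""
    C = np.zeros((n_states, n_states))
    for a, b in trajectory.segments():
        seg = trajectory.states[a:b]
        np.add.at(C, (seg[:-1], seg[1:]), 1.0)
    totals = C.sum(axis=1, keepdims=True)
    T = np.where(totals > 0, C / np.maximum(totals, 1), 1.0 / n_states)
    return T


def sr_from_counts(trajectory: Trajectory, n_states: int, gamma: float) -> SRMatrix:
    """SR estimated as the closed form ``(I - gamma T_hat)^-1`` of the
    empirically counted transition matrix.

    This is the fixed point that temporal-difference SR learning converges
    to on the same data; it has far lower variance than Monte-Carlo
    discounted counting (:func:`sr_empirical`) and is the default
    estimator of the training pipelines.
    """
    That = transition_counts(trajectory, n_states)
    sr = sr_analytic(That, gamma)
    visits = np.bincount(trajectory.states, minlength=n_states)
    return SRMatrix(
        values=sr.values,
        gamma=gamma,
        source="empirical",
        unvisited=np.flatnonzero(visits == 0),
    )


def occupancy(source, n_states: int | None = None) -> OccupancyVector:
    """Occupancy P(s') — empirical visit frequency of a trajectory, or the
    stationary distribution (leading left eigenvector) of a row-stochastic
    matrix."""
    if isinstance(source, Trajectory):
        if n_states is None:
            raise ValueError("n_states required for trajectory input")
        counts = np.bincount(source.states, minlength=n_states).astype(float)
        p = counts / counts.sum()
        return OccupancyVector(values=p, zero_visit=np.flatnonzero(counts == 0))
    T = np.asarray(source, dtype=float)
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must sum to 1")
    w, v = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    p = np.real(v[:, k])
    p = np.abs(p) / np.abs(p).sum()
    return OccupancyVector(values=p, zero_visit=np.flatnonzero(p <= 0))


def compute_psi(sr: SRMatrix, occ: OccupancyVector) -> PSIMatrix:
    """Rectified successor information max(log SR - log P, 0).

    Entries where SR or P(s') vanish carry no evidence of association and
    are set to 0; their count is reported for diagnostics.
    """
    M = sr.values
    p = occ.values
    if M.shape[1] != len(p):
        raise ValueError("SR and occupancy dimensions disagree")
    degenerate = (M <= EPS_FLOOR) | (p[None, :] <= EPS_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        si = np.log(np.maximum(M, EPS_FLOOR)) - np.log(np.maximum(p, EPS_FLOOR))[None, :]
    psi = np.maximum(si, 0.0)
    psi[degenerate] = 0.0
    return PSIMatrix(
        values=psi,
        gamma=sr.gamma,
        n_degenerate=int(np.count_nonzero(degenerate & (si > 0))),
    )


def psi_from_trajectory(
    trajectory: Trajectory, n_states: int, gamma: float, estimator: str = "counts"
) -> PSIMatrix:
    """Convenience pipeline: empirical SR + empirical occupancy -> PSI.

    ``estimator`` selects :func:`sr_from_counts` (default) or the
    Monte-Carlo :func:`sr_empirical` (``"montecarlo"``).
    """
    if estimator == "counts":
        sr = sr_from_counts(trajectory, n_states, gamma)
    elif estimator == "montecarlo":
        sr = sr_empirical(trajectory, n_states, gamma)
    else:
        raise ValueError(f"unknown SR estimator {estimator!r}")
    occ = occupancy(trajectory, n_states)
    return compute_psi(sr, occ)
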
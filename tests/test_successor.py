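import numpy as np
import pytest

from dsirep.gridworld import Trajectory, build_room, random_walk
from dsirep.successor import (
    OccupancyVector,
    compute_psi,
    occupancy,
    psi_from_trajectory,
    sr_analytic,
    sr_empirical,
    sr_from_counts,
)

SWAP = np.array([[0.0, 1.0], [1.0, 0.0]])


class TestAnalyticSR:
    def test_swap_chain_closed_form(self):
        # brute-force partial sums of gamma^t T^t as the oracle
        sr = sr_analytic(SWAP, 0.5)
        brute = sum(0.5**t * np.linalg.matrix_power(SWAP, t) for t in range(60))
        assert np.allclose(sr.values, brute, atol=1e-12)
        assert np.allclose(sr.values, [[4 / 3, 2 / 3], [2 / 3, 4 / 3]])

    def test_gamma_to_zero_limit_is_identity(self):
        sr = sr_analytic(SWAP, 1e-9)
        assert np.allclose(sr.values, np.eye(2), atol=1e-8)

    def test_row_sums_geometric(self, open_room_10):
        sr = sr_analytic(open_room_10.transition_matrix(), 0.5)
        assert np.allclose(sr.values.sum(axis=1), 2.0)

    def test_rejects_non_stochastic(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sr_analytic(np.array([[0.5, 0.1], [0.2, 0.8]]), 0.5)

    def test_rejects_bad_gamma(self):
        with pytest.raises(ValueError):
            sr_analytic(SWAP, 1.0)


class TestEmpiricalSR:
    def test_alternation_converges_to_analytic(self):
        traj = Trajectory(states=np.tile([0, 1], 5000))
        sr = sr_empirical(traj, 2, 0.5)
        assert np.allclose(sr.values, [[4 / 3, 2 / 3], [2 / 3, 4 / 3]], atol=1e-2)

    def test_gamma_zero_gives_identity_rows(self):
        traj = Trajectory(states=np.array([0, 1, 0, 1, 1, 0]))
        sr = sr_empirical(traj, 2, 0.0)
        assert np.allclose(sr.values, np.eye(2))

    def test_error_decreases_with_length(self):
        # Frobenius distance to the analytic SR shrinks over decades of
        # trajectory length (30x30 open room, gamma=0.99)
        env = build_room(30, 30)
        target = sr_analytic(env.transition_matrix(), 0.99).values
        errs = []
        for length in (10_000, 100_000, 1_000_000):
            walk = random_walk(env, length, seed=2)
            est = sr_empirical(walk, env.n_states, 0.99).values
            errs.append(np.linalg.norm(est - target))
        assert errs[0] > errs[1] > errs[2]

    def test_unvisited_rows_flagged(self):
        traj = Trajectory(states=np.array([0, 1, 0, 1]))
        sr = sr_empirical(traj, 3, 0.5)
        assert sr.unvisited.tolist() == [2]
        assert np.allclose(sr.values[2], 0.0)

    def test_out_of_range_state(self):
        with pytest.raises(ValueError, match="out of range"):
            sr_empirical(Trajectory(states=np.array([0, 5])), 3, 0.5)

    def test_break_resets_window(self):
        # credit never crosses a segment break
        traj = Trajectory(states=np.array([0, 1, 2, 3]), breaks=(2,))
        sr = sr_empirical(traj, 4, 0.9)
        assert sr.values[0, 2] == 0.0
        assert sr.values[1, 3] == 0.0
        assert sr.values[0, 1] > 0.0


class TestCountsSR:
    def test_matches_analytic_on_deterministic_chain(self):
        traj = Trajectory(states=np.tile([0, 1], 50))
        sr = sr_from_counts(traj, 2, 0.5)
        assert np.allclose(sr.values, [[4 / 3, 2 / 3], [2 / 3, 4 / 3]])

    def test_approaches_analytic_on_room_walk(self, open_room_10):
        walk = random_walk(open_room_10, 200_000, seed=3)
        est = sr_from_counts(walk, open_room_10.n_states, 0.95).values
        target = sr_analytic(open_room_10.transition_matrix(), 0.95).values
        assert np.linalg.norm(est - target) / np.linalg.norm(target) < 0.05


class TestOccupancy:
    def test_swap_chain_symmetric(self):
        occ = occupancy(Trajectory(states=np.tile([0, 1], 100)), 2)
        assert np.allclose(occ.values, [0.5, 0.5])

    def test_stationary_proportional_to_degree(self, open_room_10):
        occ = occupancy(open_room_10.transition_matrix())
        stat = open_room_10.degree() / open_room_10.degree().sum()
        assert np.allclose(occ.values, stat, atol=1e-10)

    def test_sums_to_one(self, open_room_10):
        walk = random_walk(open_room_10, 1000, seed=0)
        occ = occupancy(walk, open_room_10.n_states)
        assert abs(occ.values.sum() - 1.0) < 1e-9

    def test_zero_visit_flagged(self):
        occ = occupancy(Trajectory(states=np.array([0, 0, 1])), 3)
        assert occ.zero_visit.tolist() == [2]


class TestPSI:
    def test_direct_arithmetic(self):
        sr = sr_analytic(SWAP, 0.5)
        occ = OccupancyVector(values=np.array([0.5, 0.5]))
        psi = compute_psi(sr, occ)
        # SR entry 4/3 against P = 0.5 -> log(8/3), natural log
        assert np.isclose(psi.values[0, 0], np.log(8 / 3))

    def test_rectification(self):
        sr = sr_analytic(SWAP, 0.5)
        sr.values = np.array([[0.3, 0.3], [0.3, 0.3]])
        psi = compute_psi(sr, OccupancyVector(values=np.array([0.5, 0.5])))
        assert (psi.values == 0).all()  # log(0.6) < 0 everywhere

    def test_uniform_case_constant(self):
        sr = sr_analytic(SWAP, 0.5)
        sr.values = np.full((2, 2), 1.5)
        psi = compute_psi(sr, OccupancyVector(values=np.array([0.5, 0.5])))
        assert np.allclose(psi.values, np.log(3.0))

    def test_degenerate_entries_zeroed_and_counted(self):
        sr = sr_analytic(SWAP, 0.5)
        sr.values = np.array([[2.0, 0.0], [0.0, 2.0]])
        psi = compute_psi(sr, OccupancyVector(values=np.array([1.0, 0.0])))
        assert psi.values[0, 1] == 0.0 and psi.values[1, 1] == 0.0
        assert np.isfinite(psi.values).all()

    def test_nonnegative_and_finite(self, open_room_10):
        walk = random_walk(open_room_10, 50_000, seed=1)
        psi = psi_from_trajectory(walk, open_room_10.n_states, 0.95)
        assert (psi.values >= 0).all() and np.isfinite(psi.values).all()

    def test_pmi_correspondence_two_state_chain(self):
        # log SR(s,s') - log P(s') equals the PMI-style series
        # log sum_t gamma^t P(s_t=s', s_0=s) - log P(s) - log P(s')
        # for the stationary two-state swap chain (t = 0 included).
        gamma = 0.5
        p = np.array([0.5, 0.5])
        sr = sr_analytic(SWAP, gamma)
        si = np.log(sr.values) - np.log(p)[None, :]
        series = sum(
            gamma**t * (np.diag(p) @ np.linalg.matrix_power(SWAP, t))
            for t in range(200)
        )
        pmi = np.log(series) - np.log(p)[:, None] - np.log(p)[None, :]
        assert np.allclose(si, pmi, atol=1e-10)
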
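"""Master-equation kinetics: rate matrices, equilibria, propagation."""

import math

import numpy as np
import pytest
import scipy.linalg

from cotrafold import (
    CoarseLandscape,
    Structure,
    TimeGrid,
    build_rate_matrix,
    coarse_grain,
    equilibrium_distribution,
    lookahead_times,
    propagate,
)
from cotrafold.energy_model import GAS_CONSTANT
from cotrafold.kinetics import (
    DetailedBalanceError,
    boltzmann_distribution,
    free_energy_functional,
)
from conftest import random_landscape

RT = GAS_CONSTANT * 310.15


def random_detailed_balance_system(rng, n):
    """Random energies plus symmetric saddles => detailed-balance R."""
    nodes = [Structure(frozenset({(i + 1, 40 - i)}), 40) for i in range(n)]
    energies = dict(zip(nodes, np.round(rng.normal(0, 2, n), 3)))
    edges = {}
    for i in range(1, n):
        j = int(rng.integers(0, i))
        a, b = nodes[i], nodes[j]
        key = (a, b) if a < b else (b, a)
        edges[key] = max(energies[a], energies[b]) + float(rng.exponential(1.0))
    coarse = CoarseLandscape(
        length=40,
        energies=energies,
        occupancies={nodes[0]: 1.0, **{x: 0.0 for x in nodes[1:]}},
        edges=edges,
    )
    return coarse


class TestRateMatrix:
    def test_single_state(self):
        coarse = CoarseLandscape(
            length=10,
            energies={Structure(frozenset(), 10): 0.0},
            occupancies={Structure(frozenset(), 10): 1.0},
            edges={},
        )
        R, reps = build_rate_matrix(coarse, 1e5, 310.15)
        assert R.shape == (1, 1) and R[0, 0] == 0.0

    def test_two_equal_states_symmetric(self):
        a, b = Structure(frozenset({(1, 9)}), 10), Structure(frozenset({(2, 8)}), 10)
        coarse = CoarseLandscape(
            length=10,
            energies={a: -1.0, b: -1.0},
            occupancies={a: 1.0, b: 0.0},
            edges={(min(a, b), max(a, b)): 1.0},
        )
        R, _ = build_rate_matrix(coarse, 1e5, 310.15)
        k = 1e5 * math.exp(-2.0 / RT)
        assert R == pytest.approx(np.array([[-k, k], [k, -k]]))

    def test_columns_sum_to_zero(self, rng):
        for _ in range(20):
            coarse = random_detailed_balance_system(rng, int(rng.integers(2, 12)))
            R, _ = build_rate_matrix(coarse, 1e5, 310.15)
            assert np.abs(R.sum(axis=0)).max() < 1e-12 * max(1.0, np.abs(R).max())
            assert (np.diag(R) <= 0).all()
            off = R - np.diag(np.diag(R))
            assert (off >= 0).all()


class TestEquilibrium:
    def test_two_equal_states(self):
        R = np.array([[-1.0, 1.0], [1.0, -1.0]])
        p = equilibrium_distribution(R, [0.0, 0.0], RT)
        assert p == pytest.approx([0.5, 0.5])

    def test_boltzmann_ratio_ln2(self):
        # state 1 lies RT·ln2 above state 0 => equilibrium [2/3, 1/3]
        dE = RT * math.log(2)
        k_down = 1.0
        k_up = math.exp(-dE / RT)  # detailed balance fixes the ratio
        R = np.array([[-k_up, k_down], [k_up, -k_down]])
        p = equilibrium_distribution(R, [0.0, dE], RT)
        assert p == pytest.approx([2 / 3, 1 / 3])

    def test_stationarity_residual(self, rng):
        for _ in range(20):
            coarse = random_detailed_balance_system(rng, 8)
            R, reps = build_rate_matrix(coarse, 1e2, 310.15)
            p = equilibrium_distribution(R, [coarse.energies[r] for r in reps], RT)
            assert np.abs(R @ p).max() < 1e-9 * max(1.0, np.abs(R).max())

    def test_detailed_balance_violation_raises(self):
        # a 3-cycle with inconsistent rates
        R = np.array(
            [[-2.0, 0.1, 1.0], [1.0, -1.1, 0.5], [1.0, 1.0, -1.5]]
        )
        with pytest.raises(DetailedBalanceError):
            equilibrium_distribution(R, [0.0, 0.0, 0.0], RT)


class TestPropagate:
    def test_zero_matrix_keeps_p0(self):
        p0 = np.array([0.3, 0.7])
        out = propagate(np.zeros((2, 2)), p0, [0.1, 1.0, 10.0], p_inf=np.array([0.5, 0.5]))
        assert out == pytest.approx(np.tile(p0, (3, 1)))

    def test_two_state_closed_form(self):
        k12, k21 = 3.0, 1.0  # state 1 -> 2 and back
        R = np.array([[-k12, k21], [k12, -k21]])
        p_inf = np.array([k21, k12]) / (k12 + k21)
        p0 = np.array([1.0, 0.0])
        times = np.geomspace(1e-3, 10, 50)
        out = propagate(R, p0, times, p_inf=p_inf)
        expected1 = p_inf[0] + (p0[0] - p_inf[0]) * np.exp(-(k12 + k21) * times)
        assert np.abs(out[:, 0] - expected1).max() < 1e-9

    def test_eigen_agrees_with_pade(self, rng):
        for _ in range(10):
            coarse = random_detailed_balance_system(rng, 10)
            R, reps = build_rate_matrix(coarse, 1e2, 310.15)
            energies = [coarse.energies[r] for r in reps]
            p0 = np.zeros(10)
            p0[0] = 1.0
            times = np.geomspace(1e-4, 1.0, 20)
            out = propagate(R, p0, times, energies=energies, RT=RT)
            for t, row in zip(times, out):
                direct = scipy.linalg.expm(R * t) @ p0
                assert np.abs(row - direct).max() < 1e-8

    def test_relaxation_to_boltzmann(self, rng):
        coarse = random_detailed_balance_system(rng, 6)
        R, reps = build_rate_matrix(coarse, 1e2, 310.15)
        energies = [coarse.energies[r] for r in reps]
        p_inf = boltzmann_distribution(energies, RT)
        lam = np.sort(np.linalg.eigvals(R).real)
        slowest = -lam[-2]  # second-largest eigenvalue magnitude
        t = 100.0 / slowest
        p0 = np.zeros(6)
        p0[int(np.argmax(energies))] = 1.0
        out = propagate(R, p0, [t], p_inf=p_inf)
        tv = 0.5 * np.abs(out[0] - p_inf).sum()
        assert tv < 1e-6

    def test_occupancies_sum_to_one_and_nonnegative(self, rng):
        for _ in range(20):
            coarse = random_detailed_balance_system(rng, int(rng.integers(2, 12)))
            R, reps = build_rate_matrix(coarse, 1e3, 310.15)
            energies = [coarse.energies[r] for r in reps]
            p0 = np.zeros(len(reps))
            p0[0] = 1.0
            times = np.geomspace(1e-6, 1e3, 60)
            out = propagate(R, p0, times, energies=energies, RT=RT)
            assert np.abs(out.sum(axis=1) - 1.0).max() < 1e-9
            assert out.min() >= 0.0

    def test_free_energy_functional_non_increasing(self, rng):
        coarse = random_detailed_balance_system(rng, 8)
        R, reps = build_rate_matrix(coarse, 1e2, 310.15)
        energies = [coarse.energies[r] for r in reps]
        p0 = np.full(8, 1 / 8)
        times = np.geomspace(1e-4, 1e2, 80)
        out = propagate(R, p0, times, energies=energies, RT=RT)
        fs = [free_energy_functional(row, energies, RT) for row in out]
        for a, b in zip(fs, fs[1:]):
            assert b <= a + 1e-7

    def test_agrees_with_gillespie_on_coarse_chain(self, rng):
        # brute-force stochastic simulation of the same Markov chain
        k12, k21, k23, k32 = 5.0, 2.0, 1.0, 3.0
        R = np.array(
            [
                [-k12, k21, 0.0],
                [k12, -(k21 + k23), k32],
                [0.0, k23, -k32],
            ]
        )
        t_obs = 0.7
        p0 = np.array([1.0, 0.0, 0.0])
        # eigen path needs detailed balance; this chain satisfies it
        p1 = k21 * k32
        p2 = k12 * k32
        p3 = k12 * k23
        p_inf = np.array([p1, p2, p3], dtype=float)
        p_inf /= p_inf.sum()
        det = propagate(R, p0, [t_obs], p_inf=p_inf)[0]
        n_traj = 10_000
        counts = np.zeros(3)
        rates = {0: [(1, k12)], 1: [(0, k21), (2, k23)], 2: [(1, k32)]}
        for _ in range(n_traj):
            state, t = 0, 0.0
            while True:
                out = rates[state]
                total = sum(r for _, r in out)
                t += rng.exponential(1.0 / total)
                if t >= t_obs:
                    break
                u = rng.random() * total
                acc = 0.0
                for nxt, r in out:
                    acc += r
                    if u <= acc:
                        state = nxt
                        break
            counts[state] += 1
        freq = counts / n_traj
        sigma = np.sqrt(det * (1 - det) / n_traj)
        assert (np.abs(freq - det) <= 3 * sigma + 1e-12).all()


class TestTimeGrids:
    def test_time_grid_shape(self):
        g = TimeGrid(t1=0.04, t8=10.0)
        lin, log = g.linear_times(), g.log_times()
        assert lin[0] > 0 and lin[-1] == pytest.approx(0.04)
        assert log[0] > 0.04 and log[-1] == pytest.approx(10.0)
        assert np.all(np.diff(np.concatenate([lin, log])) > 0)

    def test_lookahead_after_transcription(self):
        g = lookahead_times(50, 50, 0.04, 60.0)
        assert g.t8 == 60.0

    def test_lookahead_sums_remaining_extension_times(self):
        g = lookahead_times(40, 50, 0.04, 60.0)
        assert g.t8 == pytest.approx(10 * 0.04)

    def test_lookahead_includes_pause(self):
        l, L = 40, 50
        g = lookahead_times(l, L, 0.04, 60.0, pause_sites={l + 3: 2.0})
        assert g.t8 == pytest.approx((L - l) * 0.04 + 2.0)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            TimeGrid(t1=0.0, t8=1.0)
        with pytest.raises(ValueError):
            lookahead_times(0, 10, 0.04, 60.0)
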
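import math

import numpy as np
import pytest

from spatialpd.dynamics import DynamicsParams, elementary_update, imitation_probability
from spatialpd.lattice import (
    C,
    D,
    LatticeState,
    PayoffParams,
    compute_payoffs,
    init_lattice,
)
from spatialpd.memory import MemoryParams, MemoryState
from spatialpd.simulate import Simulation

from conftest import lattice_from_rows


class TestImitationProbability:
    def test_equal_payoffs_give_half(self):
        assert imitation_probability(2.0, 2.0, 1.0, 0.1) == pytest.approx(0.5)

    def test_scaling_by_memory_factor(self):
        assert imitation_probability(2.0, 2.0, 0.3, 0.1) == pytest.approx(0.15)

    def test_direct_evaluation(self):
        # payoff gap of one noise unit: 1/(1+e)
        expected = 1.0 / (1.0 + math.exp(1.0))
        assert imitation_probability(1.1, 1.0, 1.0, 0.1) == pytest.approx(expected, rel=1e-12)

    def test_numerically_stable_for_huge_gaps(self):
        assert imitation_probability(100.0, 0.0, 1.0, 0.1) == pytest.approx(0.0, abs=1e-300)
        assert imitation_probability(0.0, 100.0, 0.7, 0.1) == pytest.approx(0.7)
        assert np.isfinite(imitation_probability(74.5, 0.0, 1.0, 0.1))

    def test_zero_temperature_limit(self):
        # K -> 0: step function of the payoff difference, halved at ties
        h = 0.8
        assert imitation_probability(1.0, 2.0, h, 1e-9) == pytest.approx(h, abs=1e-6)
        assert imitation_probability(2.0, 1.0, h, 1e-9) == pytest.approx(0.0, abs=1e-6)
        assert imitation_probability(1.5, 1.5, h, 1e-9) == pytest.approx(h / 2, abs=1e-6)

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValueError):
            imitation_probability(1.0, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            DynamicsParams(K=-0.1)


def _manual_probability(state, site, nbr_site, K, T, h=1.0):
    """Independent scalar evaluation of the damped Fermi probability."""
    pay = compute_payoffs(state, PayoffParams(T=T))
    px, py = pay[site], pay[nbr_site]
    return h / (1.0 + math.exp((px - py) / K))


class TestElementaryUpdate:
    def setup_method(self):
        self.rows = [[C, D, C], [D, C, C], [C, C, D]]
        self.T = 1.3
        self.payoff = PayoffParams(T=self.T)
        self.mem_params = MemoryParams(M=0)
        self.dyn = DynamicsParams(K=0.1)

    def _update(self, site_rc, direction, u, rows=None):
        state = lattice_from_rows(rows or self.rows)
        mem = MemoryState(9, 0)
        site = site_rc[0] * 3 + site_rc[1]
        changed = elementary_update(
            state, mem, self.payoff, self.mem_params, self.dyn, site, direction, u
        )
        return state, changed

    def test_accepted_switch_matches_hand_computation(self):
        # focal (1,1)=C, neighbor up (0,1)=D
        p = _manual_probability(lattice_from_rows(self.rows), (1, 1), (0, 1), 0.1, self.T)
        state, changed = self._update((1, 1), 0, u=p * 0.9)
        assert changed and state.cells[1, 1] == D

    def test_rejected_switch_leaves_lattice_unchanged(self):
        # focal (0,1)=D out-earns its C neighbor (1,1): acceptance ~ 0
        p = _manual_probability(lattice_from_rows(self.rows), (0, 1), (1, 1), 0.1, self.T)
        assert p < 1e-6
        state, changed = self._update((0, 1), 1, u=max(p * 2, 1e-4))
        assert not changed and state.cells[0, 1] == D

    def test_copying_identical_strategy_is_noop(self):
        # focal (1,1)=C, neighbor right (1,2)=C: accepted draw changes nothing
        state, changed = self._update((1, 1), 3, u=0.0)
        assert not changed and (state.cells == lattice_from_rows(self.rows).cells).all()

    def test_only_focal_cell_may_change(self):
        before = lattice_from_rows(self.rows).cells.copy()
        state, _ = self._update((2, 2), 2, u=0.0)
        diff = np.argwhere(state.cells != before)
        assert len(diff) <= 1
        if len(diff):
            assert tuple(diff[0]) == (2, 2)

    def test_zero_memory_factor_blocks_imitation(self):
        # a fully stable learner with beta ~ 1 has H ~ 0: near-certain rejection
        state = lattice_from_rows(self.rows)
        mem = MemoryState(9, 2)
        for _ in range(2):
            mem.push(state.cells.reshape(-1))
        params = MemoryParams(M=2, beta=0.999999)
        changed = elementary_update(
            state, mem, self.payoff, params, self.dyn, 4, 0, u=1e-5
        )
        assert not changed


def classic_fermi_reference(L, T, K, steps, seed):
    """Independent classic (memoryless) Fermi simulation sharing the draw protocol.

    Geometry, payoffs and scheduling are coded from scratch; the random
    stream (init uniforms, then per step: focal sites, directions,
    acceptance uniforms) matches the package's documented order.
    """
    rng = np.random.default_rng(seed)
    cells = (rng.random((L, L)) < 0.5).astype(np.uint8)
    table = {(C, C): 1.0, (C, D): 0.0, (D, C): T, (D, D): 0.0}
    N = L * L

    def payoff(grid, r, c):
        total = 0.0
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            total += table[(int(grid[r % L, c % L]), int(grid[rr % L, cc % L]))]
        return total

    traj = []
    for _ in range(steps):
        sites = rng.integers(0, N, size=N)
        dirs = rng.integers(0, 4, size=N)
        accs = rng.random(N)
        moves = {0: (-1, 0), 1: (1, 0), 2: (0, -1), 3: (0, 1)}
        for k in range(N):
            r, c = divmod(int(sites[k]), L)
            dr, dc = moves[int(dirs[k])]
            rr, cc = (r + dr) % L, (c + dc) % L
            px, py = payoff(cells, r, c), payoff(cells, rr, cc)
            z = (px - py) / K
            if z > 0:
                e = np.exp(-z) if z < 745.0 else 0.0
                p = e / (1.0 + e)
            else:
                p = 1.0 / (1.0 + np.exp(z))
            if accs[k] < p:
                cells[r, c] = cells[rr, cc]
        traj.append(cells.copy())
    return traj


class TestMonteCarloStep:
    @pytest.mark.parametrize("strategy", [C, D])
    @pytest.mark.parametrize("scheme", ["asynchronous", "synchronous"])
    def test_homogeneous_lattices_are_absorbing(self, strategy, scheme):
        sim = Simulation(L=6, M=3, T=1.4, p_c=float(strategy), seed=9,
                         update_scheme=scheme)
        ts = sim.run(100)
        assert (sim.state.cells == strategy).all()
        assert (ts["pc"] == float(strategy)).all()

    @pytest.mark.parametrize("engine", ["fast", "reference"])
    def test_memoryless_dynamics_equals_classic_fermi_reference(self, engine):
        L, T, K, steps, seed = 5, 1.3, 0.1, 20, 123
        sim = Simulation(L=L, M=0, T=T, K=K, seed=seed, engine=engine)
        reference = classic_fermi_reference(L, T, K, steps, seed)
        for expected in reference:
            sim.step()
            assert (sim.state.cells == expected).all()

    def test_fast_and_reference_engines_are_trajectory_identical(self):
        a = Simulation(L=6, M=3, beta=0.5, T=1.3, seed=77, engine="fast")
        b = Simulation(L=6, M=3, beta=0.5, T=1.3, seed=77, engine="reference")
        assert (a.state.cells == b.state.cells).all()
        for _ in range(25):
            a.step()
            b.step()
            assert (a.state.cells == b.state.cells).all()
            assert (a.mem.run_len == b.mem.run_len).all()
            assert (a.mem.length == b.mem.length).all()
            assert (a.mem.switches == b.mem.switches).all()

    def test_identical_seeds_give_bit_identical_runs(self):
        ts1 = Simulation(L=8, M=4, T=1.2, seed=3).run(30)
        ts2 = Simulation(L=8, M=4, T=1.2, seed=3).run(30)
        assert ts1.equals(ts2)

    def test_neighbor_stability_option_runs(self):
        sim = Simulation(L=6, M=3, T=1.2, seed=4, stability_of="neighbor")
        sim.run(10)

    def test_fixed_boundary_runs_and_conserves_shape(self):
        sim = Simulation(L=6, M=2, T=1.2, seed=4, boundary="fixed")
        sim.run(10)
        assert sim.state.cells.shape == (6, 6)
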
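"""High-level simulation driver tying lattice, memory and dynamics together.

:class:`Simulation` owns the lattice, the per-agent memory buffers, all
parameters and a single seeded random generator, and advances the system
one Monte Carlo step at a time.  Two engines with identical semantics and
identical random-draw consumption are available: ``"fast"`` (compiled
inner loop, the default) and ``"reference"`` (pure Python, used for
cross-checks and tiny lattices).  Given the same configuration and seed
the two produce bit-identical trajectories.
"""

from __future__ import annotations

import numpy as np

from . import observables
from .dynamics import DynamicsParams, _async_mcs_kernel, monte_carlo_step
from .lattice import LatticeState, PayoffParams, init_lattice, neighbor_table
from .memory import MemoryParams, MemoryState


class Simulation:
    """A configured spatial prisoner's-dilemma run.

    Parameters
    ----------
    L : lattice side length (N = L**2 agents).
    M : memory length in rounds (M = 0 recovers the classic Fermi rule).
    beta : weight of the strategy history in decisions; the damping
        factor H has floor 1 - beta, so larger beta means stronger
        inertia of stable agents.
    T : temptation payoff (R = 1, P = S = 0 unless ``payoff`` is given).
    K : Fermi selection noise.
    p_c : initial cooperation probability.
    seed : int seed or ``numpy.random.Generator``; drives the initial
        lattice and every subsequent draw.
    reset_threshold : switch-fraction above which a memory is cleared
        (1.0 disables resets).
    stability_of : whose stability damps imitation, ``"self"`` (default)
        or ``"neighbor"``.
    update_scheme : ``"asynchronous"`` (default) or ``"synchronous"``.
    boundary : ``"periodic"`` (default) or ``"fixed"``.
    engine : ``"fast"`` or ``"reference"``.
    """

    def __init__(
        self,
        L: int = 200,
        M: int = 5,
        beta: float = 0.5,
        T: float = 1.05,
        K: float = 0.1,
        p_c: float = 0.5,
        seed=None,
        reset_threshold: float = 0.5,
        stability_of: str = "self",
        update_scheme: str = "asynchronous",
        boundary: str = "periodic",
        engine: str = "fast",
        payoff: PayoffParams | None = None,
    ):
        if engine not in ("fast", "reference"):
            raise ValueError("engine must be 'fast' or 'reference'")
        self.payoff = payoff if payoff is not None else PayoffParams(T=T)
        self.mem_params = MemoryParams(
            M=M, beta=beta, reset_threshold=reset_threshold, stability_of=stability_of
        )
        self.dyn = DynamicsParams(K=K, update_scheme=update_scheme)
        self.boundary = boundary
        self.engine = engine
        self.rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.state = init_lattice(L, p_c, self.rng)
        self.mem = MemoryState(self.state.n_sites, M)
        self._nbr = neighbor_table(L, boundary)
        self._tab = self.payoff.table()

    # -- stepping -----------------------------------------------------------

    def step(self) -> None:
        """Advance one Monte Carlo step (N elementary updates + memory round)."""
        if self.engine == "reference" or self.dyn.update_scheme == "synchronous":
            monte_carlo_step(
                self.state, self.mem, self.payoff, self.mem_params, self.dyn,
                self.rng, nbr=self._nbr,
            )
            return
        N = self.state.n_sites
        strat = self.state.cells.reshape(-1)
        sites = self.rng.integers(0, N, size=N)
        dirs = self.rng.integers(0, 4, size=N)
        accs = self.rng.random(N)
        use_mem = self.mem.M > 0
        denom = (
            self.mem.denominators().astype(np.float64)
            if use_mem else np.ones(N, dtype=np.float64)
        )
        _async_mcs_kernel(
            strat, self._nbr, self._tab, self.dyn.K, self.mem_params.beta,
            use_mem, self.mem_params.stability_of == "self",
            self.mem.length, self.mem.run_len, self.mem.newest, denom,
            sites, dirs, accs,
        )
        self.mem.push(strat)
        self.mem.maybe_reset(self.mem_params.reset_threshold)
        self.state.t += 1

    def run(self, steps: int, record_every: int = 1):
        """Run ``steps`` Monte Carlo steps and return the recorded time series.

        Observables are recorded at t = 0 and then every ``record_every``
        steps, after the step's memory round.  Retentions are lag-1 between
        consecutive *recorded* states; ``rho`` is NaN for M = 0, and
        retentions are NaN at t = 0 or when a strategy is extinct at the
        earlier recorded step.
        """
        rows = [self._record(prev=None)]
        prev = self.state.copy()
        for _ in range(steps):
            self.step()
            if self.state.t % record_every == 0:
                rows.append(self._record(prev=prev))
                prev = self.state.copy()
        return observables.timeseries_frame(rows)

    def _record(self, prev: LatticeState | None) -> dict:
        pc = observables.cooperation_rate(self.state)
        rho = (
            observables.mean_stability(self.mem, self.state)
            if self.mem.M > 0 else float("nan")
        )
        if prev is not None:
            pcc, pdd = observables.retention_probabilities(prev, self.state)
        else:
            pcc = pdd = float("nan")
        return {"t": self.state.t, "pc": pc, "rho": rho, "pcc": pcc, "pdd": pdd}
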
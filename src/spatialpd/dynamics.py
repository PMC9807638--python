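"""Memory-damped Fermi imitation dynamics and Monte Carlo scheduling.

A randomly chosen focal agent ``x`` picks one of its four neighbors ``y``
uniformly and copies ``y``'s strategy with probability

    P(s_x <- s_y) = H / (1 + exp((P_x - P_y) / K))

where ``P_x, P_y`` are the agents' current round payoffs, ``K > 0`` is the
selection noise, and ``H`` is the memory factor of the learner (by default;
see :mod:`spatialpd.memory`).  With ``H = 1`` (no memory, ``M = 0``) this
is the classic Fermi rule.

One Monte Carlo step (MCS) of the default asynchronous scheme performs
``N = L**2`` such elementary updates with the focal agent sampled with
replacement, recomputing payoffs from the live lattice for each update;
afterwards every agent records its (possibly new) strategy into its memory
buffer and the reset rule is applied.  A synchronous scheme, in which all
agents decide simultaneously from the pre-step lattice, is available as an
option.

Random draws per asynchronous MCS are generated in a fixed, documented
order from one ``numpy.random.Generator``: first the ``N`` focal sites,
then the ``N`` neighbor directions (0=up, 1=down, 2=left, 3=right), then
the ``N`` acceptance uniforms; every draw is consumed whether or not the
update is a no-op, so trajectories are bit-reproducible from (config,
seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .lattice import LatticeState, PayoffParams, neighbor_table
from .memory import MemoryParams, MemoryState, memory_factor


@dataclass(frozen=True)
class DynamicsParams:
    """Selection noise K and the update scheduling scheme."""

    K: float = 0.1
    update_scheme: str = "asynchronous"

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("noise K must be > 0")
        if self.update_scheme not in ("asynchronous", "synchronous"):
            raise ValueError("update_scheme must be 'asynchronous' or 'synchronous'")


def imitation_probability(P_x, P_y, H, K):
    """Probability that the focal agent copies the neighbor's strategy.

    Evaluates ``H / (1 + exp((P_x - P_y)/K))`` in an overflow-safe form;
    accepts scalars or arrays.  The result lies in ``[0, H]``.
    """
    if np.any(np.asarray(K) <= 0):
        raise ValueError("noise K must be > 0")
    z = (np.asarray(P_x, dtype=np.float64) - np.asarray(P_y, dtype=np.float64)) / K
    out = np.where(
        z > 0,
        np.exp(-np.minimum(np.abs(z), 745.0)) / (1.0 + np.exp(-np.minimum(np.abs(z), 745.0))),
        1.0 / (1.0 + np.exp(np.minimum(z, 0.0))),
    )
    out = H * out
    return float(out) if np.ndim(out) == 0 else out


def _site_payoff(strat_flat: np.ndarray, nbr: np.ndarray, tab: np.ndarray, i: int) -> float:
    """Round payoff of flat site ``i`` against its (existing) neighbors."""
    s = strat_flat[i]
    total = 0.0
    for z in nbr[i]:
        if z >= 0:
            total += tab[s, strat_flat[z]]
    return total


def elementary_update(
    state: LatticeState,
    mem: MemoryState,
    payoff: PayoffParams,
    mem_params: MemoryParams,
    dyn: DynamicsParams,
    site: int,
    direction: int,
    u: float,
    nbr: np.ndarray | None = None,
) -> bool:
    """One imitation attempt by flat site ``site`` toward neighbor ``direction``.

    ``u`` is the acceptance uniform.  Mutates ``state.cells`` in place (only
    the focal cell may change) and returns whether the strategy changed.
    Reference (pure-Python) path; the fast engine in
    :class:`spatialpd.simulate.Simulation` implements identical semantics.
    """
    if nbr is None:
        nbr = neighbor_table(state.L)
    flat = state.cells.reshape(-1)
    y = nbr[site, direction]
    if y < 0:  # fixed boundary, no neighbor in that direction: no-op
        return False
    tab = payoff.table()
    px = _site_payoff(flat, nbr, tab, site)
    py = _site_payoff(flat, nbr, tab, int(y))
    learner = site if mem_params.stability_of == "self" else int(y)
    if mem.M == 0 or mem.length[learner] == 0 or flat[learner] != mem.newest[learner]:
        h = 1.0
    else:
        h = memory_factor(
            int(mem.run_len[learner]), mem.M, int(mem.length[learner]), mem_params.beta
        )
    p = _fermi(px, py, h, dyn.K)
    old = flat[site]
    if u < p:
        flat[site] = flat[y]
    return flat[site] != old


def _fermi(px: float, py: float, h: float, K: float) -> float:
    # branch form shared (structurally) with the compiled kernel so that the
    # reference and fast paths agree bit-for-bit
    z = (px - py) / K
    if z > 0.0:
        e = np.exp(-z) if z < 745.0 else 0.0
        return h * e / (1.0 + e)
    return h / (1.0 + np.exp(z))


def monte_carlo_step(
    state: LatticeState,
    mem: MemoryState,
    payoff: PayoffParams,
    mem_params: MemoryParams,
    dyn: DynamicsParams,
    rng: np.random.Generator,
    nbr: np.ndarray | None = None,
) -> None:
    """One full Monte Carlo step (reference path); mutates state and memory.

    Asynchronous: N elementary updates (focal agents sampled with
    replacement), then the memory push and reset for every agent, then the
    step counter.  Synchronous: every agent decides once from the pre-step
    lattice and pre-step memory, all changes applied at once.
    """
    if nbr is None:
        nbr = neighbor_table(state.L)
    N = state.n_sites
    if dyn.update_scheme == "asynchronous":
        sites = rng.integers(0, N, size=N)
        dirs = rng.integers(0, 4, size=N)
        accs = rng.random(N)
        for k in range(N):
            elementary_update(
                state, mem, payoff, mem_params, dyn,
                int(sites[k]), int(dirs[k]), float(accs[k]), nbr=nbr,
            )
    else:
        dirs = rng.integers(0, 4, size=N)
        accs = rng.random(N)
        flat = state.cells.reshape(-1)
        tab = payoff.table()
        pay = np.array([_site_payoff(flat, nbr, tab, i) for i in range(N)])
        ys = nbr[np.arange(N), dirs]
        h = mem.memory_factors(flat, mem_params.beta) if mem.M > 0 else np.ones(N)
        if mem_params.stability_of == "neighbor":
            h = np.where(ys >= 0, h[np.where(ys >= 0, ys, 0)], 1.0)
        new = flat.copy()
        for i in range(N):
            y = ys[i]
            if y < 0:
                continue
            p = _fermi(pay[i], pay[y], float(h[i]), dyn.K)
            if accs[i] < p:
                new[i] = flat[y]
        flat[:] = new
    mem.push(state.cells.reshape(-1))
    mem.maybe_reset(mem_params.reset_threshold)
    state.t += 1


@njit(cache=True)
def _async_mcs_kernel(strat, nbr, tab, K, beta, use_mem, stab_self,
                      blen, run_len, newest, denom, sites, dirs, accs):
    """Compiled asynchronous MCS inner loop: N sequential imitation attempts.

    ``strat`` is the flat uint8 strategy vector (mutated in place);
    ``blen/run_len/newest/denom`` summarize the (frozen within the step)
    memory buffers; the three draw arrays follow the documented order.
    """
    N = strat.shape[0]
    for k in range(N):
        x = sites[k]
        y = nbr[x, dirs[k]]
        if y < 0:
            continue
        sx = strat[x]
        sy = strat[y]
        px = 0.0
        for j in range(4):
            z = nbr[x, j]
            if z >= 0:
                px += tab[sx, strat[z]]
        py = 0.0
        for j in range(4):
            z = nbr[y, j]
            if z >= 0:
                py += tab[sy, strat[z]]
        h = 1.0
        if use_mem:
            a = x if stab_self else y
            if blen[a] > 0 and strat[a] == newest[a]:
                h = 1.0 - beta * run_len[a] / denom[a]
        z2 = (px - py) / K
        if z2 > 0.0:
            e = np.exp(-z2) if z2 < 745.0 else 0.0
            p = h * e / (1.0 + e)
        else:
            p = h / (1.0 + np.exp(z2))
        if accs[k] < p:
            strat[x] = sy
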
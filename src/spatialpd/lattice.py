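"""Square-lattice population, neighborhood geometry, and round payoffs.

The population lives on an ``L x L`` grid; each site holds one of two pure
strategies, cooperate (``C``) or defect (``D``).  Strategies are stored as
``uint8`` with ``1 = C`` and ``0 = D`` (the same encoding is used in every
serialized snapshot).  Each agent interacts with its four von Neumann
neighbors (up, down, left, right); the default boundary is periodic, so
every site has exactly four neighbors and the dynamics is translation
invariant.

Payoffs follow the weak-dilemma parameterization: mutual cooperation pays
the reward ``R = 1``, mutual defection the punishment ``P = 0``, a
cooperator exploited by a defector receives the sucker's payoff ``S = 0``
while the defector collects the temptation ``T`` with ``1 < T <= 2``.  A
site's round payoff is the sum of its pairwise payoffs against its
neighbors, recomputed from the current strategies only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Strategy encoding used throughout (and in all file formats).
D: int = 0
C: int = 1

#: neighbor direction order: up, down, left, right (row, col offsets)
_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass(frozen=True)
class PayoffParams:
    """The prisoner's-dilemma payoff quadruple ``(R, S, T, P)``.

    Defaults give the weak dilemma ``R = 1``, ``P = S = 0`` with the
    temptation ``T`` as the single game parameter.  Validation enforces
    ``T >= R > P >= S`` and ``2R > T + S`` (the equality ``T = R`` is the
    degenerate no-dilemma corner, accepted for baseline comparisons).
    """

    T: float = 1.05
    R: float = 1.0
    P: float = 0.0
    S: float = 0.0

    def __post_init__(self) -> None:
        if not (self.T >= self.R > self.P >= self.S):
            raise ValueError(
                f"payoffs must satisfy T >= R > P >= S, got "
                f"T={self.T}, R={self.R}, P={self.P}, S={self.S}"
            )
        # equality permitted so the weak-dilemma upper edge T = 2 is usable
        if not (2 * self.R >= self.T + self.S):
            raise ValueError("payoffs must satisfy 2R >= T + S")

    def table(self) -> np.ndarray:
        """2x2 payoff matrix to the row player: ``table[s_x, s_y]``.

        Index 0 is D, index 1 is C, so ``table[1, 1] = R``,
        ``table[1, 0] = S``, ``table[0, 1] = T``, ``table[0, 0] = P``.
        """
        return np.array([[self.P, self.T], [self.S, self.R]], dtype=np.float64)


@dataclass
class LatticeState:
    """An ``L x L`` grid of strategies plus the elapsed Monte Carlo steps."""

    cells: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.uint8)
        if self.cells.ndim != 2 or self.cells.shape[0] != self.cells.shape[1]:
            raise ValueError("cells must be a square 2-D array")
        if self.cells.shape[0] < 2:
            raise ValueError("lattice side must be at least 2")
        if not np.isin(self.cells, (C, D)).all():
            raise ValueError("cells must contain only 0 (D) and 1 (C)")

    @property
    def L(self) -> int:
        return self.cells.shape[0]

    @property
    def n_sites(self) -> int:
        return self.cells.size

    def copy(self) -> "LatticeState":
        return LatticeState(self.cells.copy(), self.t)


def init_lattice(L: int, p_c: float = 0.5, seed=None) -> LatticeState:
    """Random initial lattice: each site is C independently with prob ``p_c``.

    Parameters
    ----------
    L : side length, at least 2.
    p_c : initial cooperation probability, in [0, 1] (default 0.5).
    seed : int seed or ``numpy.random.Generator``.
    """
    if L < 2:
        raise ValueError("lattice side L must be >= 2")
    if not 0.0 <= p_c <= 1.0:
        raise ValueError("p_c must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cells = (rng.random((L, L)) < p_c).astype(np.uint8)
    return LatticeState(cells, t=0)


def neighbors(state: LatticeState, site: tuple[int, int], boundary: str = "periodic"):
    """Von Neumann neighborhood of ``site`` in order up, down, left, right.

    With periodic boundaries every site has exactly four neighbors; with
    ``boundary="fixed"`` edge sites have fewer (out-of-range directions are
    dropped).
    """
    L = state.L
    r, c = site
    if not (0 <= r < L and 0 <= c < L):
        raise IndexError(f"site {site} outside {L}x{L} lattice")
    out = []
    for dr, dc in _OFFSETS:
        rr, cc = r + dr, c + dc
        if boundary == "periodic":
            out.append((rr % L, cc % L))
        elif 0 <= rr < L and 0 <= cc < L:
            out.append((rr, cc))
    return out


def pair_payoff(s_x: int, s_y: int, params: PayoffParams) -> tuple[float, float]:
    """Payoffs ``(to x, to y)`` for one game between strategies ``s_x, s_y``."""
    tab = params.table()
    return float(tab[s_x, s_y]), float(tab[s_y, s_x])


def neighbor_table(L: int, boundary: str = "periodic") -> np.ndarray:
    """Flat neighbor index table of shape ``(L*L, 4)``.

    Row ``i`` lists the flat indices of site ``i``'s neighbors in the order
    up, down, left, right; missing neighbors (fixed boundary) are ``-1``.
    """
    idx = np.arange(L * L).reshape(L, L)
    if boundary == "periodic":
        cols = [
            np.roll(idx, 1, axis=0),   # up
            np.roll(idx, -1, axis=0),  # down
            np.roll(idx, 1, axis=1),   # left
            np.roll(idx, -1, axis=1),  # right
        ]
        return np.stack([c.ravel() for c in cols], axis=1).astype(np.int64)
    if boundary != "fixed":
        raise ValueError(f"unknown boundary {boundary!r}")
    table = np.full((L * L, 4), -1, dtype=np.int64)
    for r in range(L):
        for c in range(L):
            i = r * L + c
            for k, (dr, dc) in enumerate(_OFFSETS):
                rr, cc = r + dr, c + dc
                if 0 <= rr < L and 0 <= cc < L:
                    table[i, k] = rr * L + cc
    return table


def compute_payoffs(state: LatticeState, params: PayoffParams,
                    boundary: str = "periodic") -> np.ndarray:
    """Round payoff of every site: sum of pair payoffs against its neighbors.

    Returns an ``L x L`` float array aligned with ``state.cells``.  Payoffs
    depend on the current strategies only; with default parameters each
    entry lies in ``[4S, 4T] = [0, 4T]``.
    """
    s = state.cells
    tab = params.table()
    out = np.zeros(s.shape, dtype=np.float64)
    if boundary == "periodic":
        for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            out += tab[s, np.roll(s, shift, axis=ax)]
        return out
    flat = s.ravel()
    table = neighbor_table(state.L, boundary)
    acc = np.zeros(flat.shape, dtype=np.float64)
    for k in range(4):
        nb = table[:, k]
        ok = nb >= 0
        acc[ok] += tab[flat[ok], flat[nb[ok]]]
    return acc.reshape(s.shape)


# ---------------------------------------------------------------------------
# snapshot serialization


def save_snapshot(state: LatticeState, path) -> None:
    """Write the lattice as L rows of L space-separated integers (1=C, 0=D)."""
    np.savetxt(path, state.cells, fmt="%d")


def load_snapshot(path, t: int = 0) -> LatticeState:
    """Read a text snapshot written by :func:`save_snapshot`."""
    cells = np.loadtxt(path, dtype=np.uint8)
    return LatticeState(np.atleast_2d(cells), t=t)


def render_snapshot(state: LatticeState, path, cell_px: int = 4) -> None:
    """Render the lattice to a PNG: red = cooperator, blue = defector."""
    from PIL import Image

    rgb = np.zeros((state.L, state.L, 3), dtype=np.uint8)
    coop = state.cells == C
    rgb[coop] = (220, 30, 30)
    rgb[~coop] = (30, 60, 220)
    img = Image.fromarray(rgb, mode="RGB")
    if cell_px > 1:
        img = img.resize((state.L * cell_px,) * 2, Image.NEAREST)
    img.save(path)
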
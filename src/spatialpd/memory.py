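"""Per-agent strategy history and the memory damping factor.

Each agent records its own strategy over the previous up-to-``M`` rounds.
The *stability count* ``n`` is the length of the unbroken run of
most-recent entries equal to the agent's current strategy; an agent whose
newest recorded strategy differs from its current one has ``n = 0``.  The
memory factor

    H = 1                  if M = 0
    H = 1 - beta * n / M   if M >= 1

multiplies the Fermi imitation probability, so agents with a stable recent
history are harder to convert; ``beta`` (0 < beta < 1) is the *weight* of
the strategy history in the decision: the larger ``beta``, the more a
stable history suppresses imitation (``H`` has floor ``1 - beta``), and
``beta -> 0`` recovers the memoryless Fermi rule.

During warm-up (fewer than ``M`` rounds recorded) the denominator is the
number of rounds actually stored rather than ``M``, keeping ``H`` in
``[1 - beta, 1]`` from the first round onward; an empty buffer gives
``n = 0`` and ``H = 1`` (no damping).

Agents that flip-flop have their memory *reset*: if the number of
adjacent-entry switches inside the buffer exceeds
``reset_threshold * (length - 1)`` the buffer is cleared.  The default
threshold is 0.5; a threshold of 1.0 disables resets (the switch count can
never exceed ``length - 1``).

Two representations are provided: :class:`MemoryBuffer`, a plain per-agent
deque used for small-scale work and as the reference semantics, and
:class:`MemoryState`, a vectorized population of circular buffers with
incrementally maintained run-length and switch counters used by the
simulation engine.  A property test in the suite pins the two to each
other.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

NEVER_RESET = 1.0  # switches <= len-1 always, so a fraction of 1.0 never triggers


@dataclass(frozen=True)
class MemoryParams:
    """Memory length ``M`` (rounds), history weight ``beta``, and reset policy."""

    M: int = 5
    beta: float = 0.5
    reset_threshold: float = 0.5
    stability_of: str = "self"  # whose stability damps imitation: self | neighbor

    def __post_init__(self) -> None:
        if self.M < 0:
            raise ValueError("memory length M must be >= 0")
        if self.M >= 1 and not (0.0 < self.beta < 1.0):
            raise ValueError("beta must lie strictly between 0 and 1")
        if not (0.0 <= self.reset_threshold <= 1.0):
            raise ValueError("reset_threshold must lie in [0, 1]")
        if self.stability_of not in ("self", "neighbor"):
            raise ValueError("stability_of must be 'self' or 'neighbor'")


class MemoryBuffer:
    """Ordered record (newest first) of one agent's last <= M strategies."""

    __slots__ = ("M", "entries")

    def __init__(self, M: int, entries=()):
        if M < 0:
            raise ValueError("capacity M must be >= 0")
        self.M = M
        self.entries = deque(entries, maxlen=M if M > 0 else 0)
        # deque with maxlen drops from the opposite end; enforce newest-first
        if len(self.entries) > (M or 0):
            raise ValueError("more entries than capacity")

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MemoryBuffer)
            and self.M == other.M
            and list(self.entries) == list(other.entries)
        )

    def push_round(self, s: int) -> None:
        """Prepend ``s`` as the newest entry, evicting the oldest if full."""
        if self.M == 0:
            return
        self.entries.appendleft(int(s))

    def stability_count(self, current: int) -> int:
        """Length of the maximal newest-first prefix equal to ``current``."""
        n = 0
        for e in self.entries:
            if e != current:
                break
            n += 1
        return n

    def switch_count(self) -> int:
        """Number of adjacent entry pairs that differ."""
        e = list(self.entries)
        return sum(a != b for a, b in zip(e, e[1:]))

    def maybe_reset(self, reset_threshold: float) -> bool:
        """Clear the buffer if it switches too often; returns True on reset."""
        k = len(self.entries)
        if k >= 2 and self.switch_count() > reset_threshold * (k - 1):
            self.entries.clear()
            return True
        return False


def memory_factor(n: int, M: int, effective_len: int, beta: float) -> float:
    """Damping factor H for stability count ``n`` out of ``M`` rounds.

    ``effective_len`` is the number of rounds currently stored; during
    warm-up (effective_len < M) it replaces ``M`` as the denominator.
    Always satisfies ``1 - beta <= H <= 1`` for ``M >= 1`` and ``H = 1``
    for ``M = 0`` or ``n = 0``.
    """
    if M == 0:
        return 1.0
    if not 0 <= n <= effective_len <= M:
        raise ValueError(f"need 0 <= n <= effective_len <= M, got n={n}, "
                         f"effective_len={effective_len}, M={M}")
    denom = M if effective_len >= M else max(effective_len, 1)
    return 1.0 - beta * n / denom


class MemoryState:
    """Vectorized memory buffers for a whole population of ``n_agents``.

    Keeps, per agent, a circular buffer of the last <= M recorded
    strategies plus three incrementally maintained summaries: the newest
    entry, the run length of identical newest entries, and the number of
    adjacent switches inside the buffer.  These make the stability count,
    the memory factor and the reset test O(1) per agent per round.
    """

    def __init__(self, n_agents: int, M: int):
        if M < 0:
            raise ValueError("M must be >= 0")
        self.n_agents = n_agents
        self.M = M
        cap = max(M, 1)
        self.buf = np.zeros((n_agents, cap), dtype=np.uint8)
        self.head = np.zeros(n_agents, dtype=np.int64)   # slot of next write (= oldest when full)
        self.length = np.zeros(n_agents, dtype=np.int64)
        self.run_len = np.zeros(n_agents, dtype=np.int64)
        self.newest = np.zeros(n_agents, dtype=np.uint8)
        self.switches = np.zeros(n_agents, dtype=np.int64)

    def push(self, strategies: np.ndarray) -> None:
        """Record the current strategy of every agent (one round)."""
        if self.M == 0:
            return
        # copy: the caller may pass (a view of) the live strategy array
        s = np.array(strategies, dtype=np.uint8, copy=True).ravel()
        ar = np.arange(self.n_agents)
        full = self.length == self.M
        # evicting the oldest entry removes the (oldest, second-oldest) pair
        if self.M >= 2:
            oldest = self.buf[ar, self.head]
            second = self.buf[ar, (self.head + 1) % self.M]
            self.switches -= (full & (self.length >= 2) & (oldest != second))
        same = (self.length > 0) & (s == self.newest)
        self.switches += ((self.length > 0) & ~same)
        self.run_len = np.where(same, np.minimum(self.run_len + 1, self.M), 1)
        self.buf[ar, self.head] = s
        self.head = (self.head + 1) % max(self.M, 1)
        self.length = np.minimum(self.length + 1, self.M)
        self.newest = s
        if self.M == 1:
            self.switches[:] = 0

    def maybe_reset(self, reset_threshold: float) -> np.ndarray:
        """Clear buffers that switch too often; returns the reset mask."""
        if self.M == 0:
            return np.zeros(self.n_agents, dtype=bool)
        trip = self.switches > reset_threshold * np.maximum(self.length - 1, 0)
        trip &= self.length >= 2
        if trip.any():
            self.head[trip] = 0
            self.length[trip] = 0
            self.run_len[trip] = 0
            self.switches[trip] = 0
        return trip

    def stability_counts(self, current: np.ndarray) -> np.ndarray:
        """Stability count n of every agent against its current strategy."""
        cur = np.asarray(current, dtype=np.uint8).ravel()
        agree = (self.length > 0) & (cur == self.newest)
        return np.where(agree, self.run_len, 0)

    def denominators(self) -> np.ndarray:
        """Per-agent denominator of n: M once full, stored length during warm-up."""
        if self.M == 0:
            raise ValueError("denominator undefined for M = 0")
        return np.where(self.length >= self.M, self.M, np.maximum(self.length, 1))

    def memory_factors(self, current: np.ndarray, beta: float) -> np.ndarray:
        """Vector of damping factors H for the whole population."""
        if self.M == 0:
            return np.ones(self.n_agents)
        n = self.stability_counts(current)
        return 1.0 - beta * n / self.denominators()

    def entries(self, i: int) -> list[int]:
        """Newest-first list of agent ``i``'s stored strategies (for inspection)."""
        k = int(self.length[i])
        if k == 0:
            return []
        pos = (self.head[i] - 1 - np.arange(k)) % max(self.M, 1)
        return [int(v) for v in self.buf[i, pos]]

    def copy(self) -> "MemoryState":
        other = MemoryState(self.n_agents, self.M)
        for name in ("buf", "head", "length", "run_len", "newest", "switches"):
            setattr(other, name, getattr(self, name).copy())
        return other
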
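"""Summary statistics of a run: cooperation rate, stability, retention.

``cooperation_rate`` is the fraction of lattice sites playing C.  The
population *stability* ``rho`` is the mean over agents of ``n / M`` where
``n`` is the agent's stability count (during memory warm-up the stored
length replaces ``M``, mirroring the memory factor).  The *retention
probabilities* ``P(C->C)`` and ``P(D->D)`` are the fractions of
cooperators (defectors) at one recorded step that still hold the same
strategy at the next recorded step; a retention is undefined (missing)
when its strategy is absent at the earlier step.

Time series are plain ``pandas.DataFrame`` objects with columns
``t, pc, rho, pcc, pdd``; missing values are NaN in memory and empty
fields in CSV output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lattice import C, D, LatticeState
from .memory import MemoryState

TIMESERIES_COLUMNS = ("t", "pc", "rho", "pcc", "pdd")


def cooperation_rate(state: LatticeState) -> float:
    """Fraction of sites playing C."""
    return float(np.count_nonzero(state.cells == C)) / state.n_sites


def mean_stability(mem: MemoryState, state: LatticeState) -> float:
    """Population mean of the per-agent stability fraction n / M.

    Uses the warm-up denominator (stored length) while buffers are filling.
    Undefined for M = 0.
    """
    if mem.M == 0:
        raise ValueError("stability is undefined for memory length M = 0")
    if mem.n_agents != state.n_sites:
        raise ValueError("memory population and lattice size disagree")
    n = mem.stability_counts(state.cells.reshape(-1))
    return float(np.mean(n / mem.denominators()))


def retention_probabilities(prev: LatticeState, curr: LatticeState) -> tuple[float, float]:
    """Lag-1 retention ``(P(C->C), P(D->D))`` between two recorded states.

    Either value is NaN when its strategy had no members at the earlier
    step.
    """
    if prev.cells.shape != curr.cells.shape:
        raise ValueError("lattice sizes disagree between the two states")
    was_c = prev.cells == C
    was_d = ~was_c
    n_c = int(was_c.sum())
    n_d = int(was_d.sum())
    pcc = float((curr.cells[was_c] == C).sum() / n_c) if n_c else float("nan")
    pdd = float((curr.cells[was_d] == D).sum() / n_d) if n_d else float("nan")
    return pcc, pdd


def timeseries_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble recorded rows into the canonical time-series frame."""
    df = pd.DataFrame(rows, columns=list(TIMESERIES_COLUMNS))
    df["t"] = df["t"].astype(int)
    return df


def write_timeseries(df: pd.DataFrame, path) -> None:
    """Write a time series CSV with header ``t,pc,rho,pcc,pdd``.

    Missing values are serialized as empty fields.
    """
    df.to_csv(path, index=False, na_rep="", float_format="%.10g")


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path)
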
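"""Config-driven experiment runner, parameter sweeps and figure recipes.

An :class:`ExperimentConfig` fixes the lattice, memory, dynamics and sweep
axes; :func:`run_experiment` executes every grid point x replicate, writes
one time-series CSV per run (plus optional lattice snapshots and a
resolved copy of the config) and returns a summary table with one row per
run: the steady-state cooperation rate (mean over an averaging window at
the end of the run), the final stability, and the first time the
cooperator retention overtakes the defector retention, if it does.

``figure_recipes`` returns canonical configs for the standard experiment
layouts (cooperation rate vs temptation for several memory lengths,
cooperation vs memory length, trajectories, steady-state snapshots,
stability and retention time series) at either full scale (L = 200,
10^4 MCS) or desk scale (L = 50-100, 2 x 10^3 MCS), identical parameter
grids.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import observables
from .lattice import save_snapshot
from .simulate import Simulation

log = logging.getLogger("spatialpd")

SWEEPABLE = ("T", "M", "beta", "K")

SUMMARY_COLUMNS = (
    "T", "M", "beta", "K", "replicate", "seed",
    "steady_pc", "final_rho", "crossing_t",
)


@dataclass
class ExperimentConfig:
    """Full description of one experiment (single point or sweep grid)."""

    name: str = "run"
    L: int = 200
    p_c: float = 0.5
    M: int = 5
    beta: float = 0.5
    reset_threshold: float = 0.5
    stability_of: str = "self"
    T: float = 1.05
    K: float = 0.1
    update_scheme: str = "asynchronous"
    boundary: str = "periodic"
    steps: int = 10_000
    record_every: int = 1
    sweep: dict = field(default_factory=dict)  # axis name -> list of values
    replicates: int = 1
    seed: int = 0
    averaging_window: int | None = None  # recorded rows; default last 10%
    snapshot_times: list = field(default_factory=list)
    outdir: str | None = None

    def __post_init__(self) -> None:
        for axis, values in self.sweep.items():
            if axis not in SWEEPABLE:
                raise ValueError(f"cannot sweep over {axis!r}; one of {SWEEPABLE}")
            if len(values) == 0:
                raise ValueError(f"swept list for {axis!r} is empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        n_recorded = self.steps // self.record_every
        if self.averaging_window is not None and self.averaging_window > n_recorded:
            raise ValueError("averaging window exceeds the number of recorded steps")

    def grid(self) -> list[dict]:
        """All sweep-grid points as parameter-override dicts (sorted axes)."""
        axes = sorted(self.sweep)
        if not axes:
            return [{}]
        return [
            dict(zip(axes, combo))
            for combo in itertools.product(*(self.sweep[a] for a in axes))
        ]

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        return cls(**yaml.safe_load(text))


def steady_state_pc(ts: pd.DataFrame, window: int | None = None) -> float:
    """Mean cooperation rate over the last ``window`` recorded rows.

    Defaults to the final 10% of recorded rows (at least one).
    """
    if window is None:
        window = max(1, len(ts) // 10)
    return float(ts["pc"].iloc[-window:].mean())


def retention_crossing(ts: pd.DataFrame) -> tuple[float, float]:
    """First recorded time at which P(C->C) exceeds P(D->D).

    Returns ``(t, retention value at the crossing)`` where the value is the
    midpoint of the two retentions at that step; ``(nan, nan)`` if the
    curves never cross.
    """
    ok = ts.dropna(subset=["pcc", "pdd"])
    above = ok[ok["pcc"] > ok["pdd"]]
    if len(above) == 0:
        return float("nan"), float("nan")
    row = above.iloc[0]
    return float(row["t"]), float((row["pcc"] + row["pdd"]) / 2.0)


def run_single(config: ExperimentConfig, overrides: dict, seed: int):
    """One simulation at a grid point; returns (time series, finished Simulation)."""
    params = {k: getattr(config, k) for k in ("L", "M", "beta", "T", "K", "p_c",
                                              "reset_threshold", "stability_of",
                                              "update_scheme", "boundary")}
    params.update(overrides)
    sim = Simulation(seed=seed, **params)
    ts = sim.run(config.steps, record_every=config.record_every)
    return ts, sim


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Execute the full sweep grid x replicates; returns the summary table.

    Replicate ``r`` uses seed ``config.seed + r`` (the same seeds at every
    grid point), so reruns with the same config and base seed reproduce
    every output byte-for-byte.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"{config.name}_config.yaml").write_text(config.to_yaml())
    rows = []
    for point in config.grid():
        for rep in range(config.replicates):
            seed = config.seed + rep
            t0 = time.perf_counter()
            ts, sim = run_single(config, point, seed)
            full = {k: point.get(k, getattr(config, k)) for k in SWEEPABLE}
            tag = (f"{config.name}_T{full['T']}_M{full['M']}"
                   f"_beta{full['beta']}_K{full['K']}_rep{rep}")
            if outdir is not None:
                observables.write_timeseries(ts, outdir / f"{tag}.csv")
                for snap_t in config.snapshot_times:
                    if snap_t == sim.state.t:
                        save_snapshot(sim.state, outdir / f"{tag}_t{snap_t}.txt")
            cross_t, _ = retention_crossing(ts)
            row = {
                **full,
                "replicate": rep,
                "seed": seed,
                "steady_pc": steady_state_pc(ts, config.averaging_window),
                "final_rho": float(ts["rho"].iloc[-1]),
                "crossing_t": cross_t,
            }
            rows.append(row)
            log.info("%s seed=%d steady_pc=%.4f final_rho=%.4f wall=%.2fs",
                     tag, seed, row["steady_pc"], row["final_rho"],
                     time.perf_counter() - t0)
    summary = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    if outdir is not None:
        summary.to_csv(outdir / f"{config.name}_summary.csv", index=False,
                       na_rep="", float_format="%.10g")
    return summary


# ---------------------------------------------------------------------------
# canonical experiment layouts

_FIG_T_GRID_FULL = [round(1.0 + 0.05 * k, 2) for k in range(1, 21)]   # 1.05 .. 2.0
_FIG_T_GRID_DESK = [1.05] + [round(1.0 + 0.1 * k, 2) for k in range(1, 11)]


def figure_recipes(name: str, scale: str = "desk") -> ExperimentConfig:
    """Canonical config for a standard experiment layout.

    ``scale="full"`` uses L = 200 and 10^4 MCS; ``scale="desk"`` uses
    L = 50-100 and 2 x 10^3 MCS with the same parameter grids.
    """
    if scale not in ("full", "desk"):
        raise ValueError("scale must be 'full' or 'desk'")
    full = scale == "full"
    steps = 10_000 if full else 2_000
    base = dict(name=name, beta=0.5, K=0.1, steps=steps, replicates=5, seed=0)
    if name == "fig1":
        # steady-state cooperation vs temptation for several memory lengths
        return ExperimentConfig(
            L=200 if full else 50,
            sweep={"M": [0, 1, 3, 5, 7, 9],
                   "T": _FIG_T_GRID_FULL if full else _FIG_T_GRID_DESK},
            **base,
        )
    if name == "fig2":
        # steady-state cooperation vs memory length for several (T, K)
        return ExperimentConfig(
            L=200 if full else 50,
            sweep={"T": [1.04, 1.05, 1.06],
                   "K": [0.1, 0.2, 0.3],
                   "M": [1, 2, 3, 5, 7, 10, 15, 20, 30, 50, 70, 100] if full
                        else [1, 2, 5, 10, 20, 50, 100]},
            **base,
        )
    if name == "fig3":
        # cooperation-rate trajectories for several memory lengths
        return ExperimentConfig(
            L=200 if full else 100, T=1.05,
            sweep={"M": [0, 1, 3, 5, 7, 9]},
            **base,
        )
    if name == "fig4":
        # steady-state strategy snapshots across memory lengths
        return ExperimentConfig(
            L=200 if full else 100, T=1.05,
            sweep={"M": [0, 1, 2, 5, 8, 10, 20, 30, 50, 80, 100, 200]},
            snapshot_times=[steps],
            **{**base, "replicates": 1},
        )
    if name == "fig7":
        # population stability trajectories
        return ExperimentConfig(
            L=200 if full else 100, T=1.05,
            sweep={"M": [3, 5, 7, 9]},
            **base,
        )
    if name == "fig8":
        # retention-probability trajectories
        return ExperimentConfig(
            L=200 if full else 100, T=1.05,
            sweep={"M": [3, 5, 7]},
            **base,
        )
    raise ValueError(f"unknown figure recipe {name!r}")


def stability_extrema(ensemble: dict[int, pd.DataFrame]) -> tuple[float, float]:
    """Transient minimum and equilibrium maximum of the stability curves.

    Given seed-averaged trajectories per memory length, returns
    ``(min, max)`` where ``min`` is the lowest value of rho(t) over the
    transient (t >= 1) across all curves and ``max`` is the largest
    end-of-run equilibrium value (mean over the final 10% of recorded
    rows) across curves.
    """
    lo, hi = np.inf, -np.inf
    for ts in ensemble.values():
        rho = ts["rho"].to_numpy()[1:]
        lo = min(lo, float(np.nanmin(rho)))
        tail = max(1, len(rho) // 10)
        hi = max(hi, float(np.nanmean(rho[-tail:])))
    return lo, hi


def early_retention(ensemble: dict[int, pd.DataFrame], n_steps: int = 5) -> tuple[float, float]:
    """Mean (P(C->C), P(D->D)) over the first ``n_steps`` recorded steps.

    Averaged across the curves of the ensemble; measures the retention
    level right after the random 50/50 start.
    """
    pcc = np.mean([np.nanmean(ts["pcc"].to_numpy()[1:1 + n_steps]) for ts in ensemble.values()])
    pdd = np.mean([np.nanmean(ts["pdd"].to_numpy()[1:1 + n_steps]) for ts in ensemble.values()])
    return float(pcc), float(pdd)


def crossing_retention(ensemble: dict[int, pd.DataFrame]) -> float:
    """Retention level at which P(C->C) first overtakes P(D->D).

    Returns the midpoint of the two retentions at the first crossing,
    averaged over the ensemble's curves.  A curve without a crossing
    contributes its value at the closest approach of the two retentions
    instead, so the statistic is always defined.
    """
    values = []
    for ts in ensemble.values():
        _, val = retention_crossing(ts)
        if np.isnan(val):
            ok = ts.dropna(subset=["pcc", "pdd"])
            gap = (ok["pcc"] - ok["pdd"]).abs()
            row = ok.loc[gap.idxmin()]
            val = float((row["pcc"] + row["pdd"]) / 2.0)
        values.append(val)
    return float(np.mean(values))


def recovery_onset(ensemble: dict[int, pd.DataFrame], window: int = 10) -> float:
    """Time step at which the cooperation rate begins its sustained rise.

    Smooths each curve's P_c(t) with a ``window``-step moving average and
    takes the time of the smoothed minimum (the turning point between the
    initial decline and the recovery), averaged across curves.
    """
    onsets = []
    for ts in ensemble.values():
        pc = ts["pc"].to_numpy()
        smooth = np.convolve(pc, np.ones(window) / window, mode="valid")
        idx = int(np.argmin(smooth)) + window // 2
        onsets.append(float(ts["t"].iloc[min(idx, len(ts) - 1)]))
    return float(np.mean(onsets))


def trajectory_ensemble(
    M_values,
    seeds,
    L: int = 100,
    steps: int = 2_000,
    T: float = 1.05,
    beta: float = 0.5,
    K: float = 0.1,
    **kwargs,
) -> dict[int, pd.DataFrame]:
    """Seed-averaged trajectories, one frame per memory length.

    Runs one simulation per (M, seed), averages the recorded observables
    across seeds pointwise in t, and returns ``{M: mean time series}``.
    Used for stability/retention/onset analyses.
    """
    out = {}
    for M in M_values:
        frames = []
        for seed in seeds:
            sim = Simulation(L=L, M=M, beta=beta, T=T, K=K, seed=seed, **kwargs)
            frames.append(sim.run(steps))
        stacked = pd.concat(frames).groupby("t", as_index=False).mean()
        out[int(M)] = stacked
    return out
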
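# Methods

## Model

The population is an `L x L` square lattice (N = L² agents) with periodic
boundaries; each site holds one pure strategy, cooperate (C, stored as 1)
or defect (D, stored as 0).  Agents play the weak prisoner's dilemma with
their four von Neumann neighbors: payoff to the row player is `R = 1`
(C,C), `S = 0` (C,D), `T` (D,C), `P = 0` (D,D), with the temptation
`1 < T <= 2` the single game parameter.  Validation enforces
`T >= R > P >= S` and `2R >= T + S`; the degenerate corners `T = 1`
(no dilemma) and `T = 2` (boundary of the sum constraint) are accepted
because both are useful baselines.  A site's round payoff is the sum of
its four pair payoffs, always recomputed from the current lattice —
payoffs are round quantities, never accumulated across rounds.

Strategy updating is the Fermi rule damped by the learner's own history.
Each agent keeps a buffer of its strategies over the previous up-to-`M`
rounds (strategies only; payoffs are not remembered).  Writing `n` for
the run length of the newest buffer entries equal to the agent's current
strategy, the memory factor is

    H = 1                    if M = 0, or the buffer is empty, or n = 0
    H = 1 - beta * n / M     otherwise,

and a focal agent `x` copies its chosen neighbor `y` with probability
`H_x / (1 + exp((P_x - P_y) / K))`.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `L` | lattice side | 200 | N = L² agents |
| `T` | temptation payoff | 1.05 | dilemma severity, in (1, 2] |
| `K` | selection noise | 0.1 | Fermi temperature; K→0 is deterministic imitation of the better |
| `M` | memory length (rounds) | 5 | M = 0 recovers the classic Fermi model |
| `beta` | history weight | 0.5 | floor of H is 1 − beta; beta→0 removes the memory effect |
| `reset_threshold` | switch fraction triggering a memory reset | 0.5 | 1.0 disables resets |
| `stability_of` | whose history damps an update | `self` | `neighbor` damps copying of stable neighbors instead |
| `update_scheme` | Monte Carlo scheduling | `asynchronous` | `synchronous` decides all agents from the pre-step lattice |
| `p_c` | initial cooperation probability | 0.5 | i.i.d. per site |

### Parameterization of the memory factor

The damping has one genuinely open design axis: whether the weight
parameter scales the *memory term* (`H = 1 − beta·n/M`, floor `1 − beta`)
or the *residual* (`H = 1 − (1−beta)·n/M`, floor `beta`).  The two are
the same family under `beta ↔ 1 − beta` and identical at `beta = 0.5`,
the default.  This package uses the first form so that `beta` reads as
the weight of history in the decision: increasing `beta` strengthens the
memory effect, and the monotonicity checks in the acceptance suite
(steady-state cooperation non-decreasing in `beta`) are stated in that
orientation.  The simulations here show that stronger damping favors
cooperation, so under this parameterization cooperation increases with
`beta`.

### Memory semantics

* Buffers start **empty**: no pre-history is fabricated, so the first
  Monte Carlo step is exactly the classic Fermi rule (H = 1).
* **Warm-up denominator.** For the first `M` rounds the buffer holds
  fewer than `M` entries; `n` is divided by the stored length (not `M`)
  until the buffer is full.  This keeps `H` in `[1 − beta, 1]` at all
  times instead of making young histories look artificially weak.
* **Reset rule.** After each round's push, a buffer whose adjacent-entry
  switch count exceeds `reset_threshold · (length − 1)` is cleared:
  chronic flip-floppers lose their history (and hence their damping).
  The threshold 0.5 ("switches in more than half the opportunities") is a
  documented, testable quantification of an otherwise qualitative rule;
  1.0 disables resets because the switch count can never exceed
  `length − 1`.
* Memory records once per Monte Carlo step, after all of that step's
  elementary updates, so `M` counts rounds, not elementary updates.

## Scheduling and randomness

One asynchronous MCS performs `N` elementary updates with the focal agent
sampled uniformly with replacement; each update draws a focal site, one
of its four neighbors (order up/down/left/right), and an acceptance
uniform.  All draws come from a single seeded `numpy.random.Generator` in
a fixed order — first the initial lattice uniforms, then per MCS the `N`
focal sites, the `N` directions, the `N` acceptance uniforms, every draw
consumed whether or not the update is a no-op — so a (config, seed) pair
reproduces a trajectory bit for bit.  Payoffs for the focal pair are
computed on demand from the live lattice.  The synchronous option
computes all payoffs and memory factors from the pre-step state and
applies all accepted copies at once; it uses one direction and one
acceptance draw per agent.

Two engines share these semantics: a compiled (numba) inner loop used by
default, and a pure-Python reference path.  The test suite pins them to
each other trajectory-for-trajectory, and pins the `M = 0` case to an
independently coded classic-Fermi simulation sharing the draw protocol.

The Fermi probability is evaluated in branch form
(`H·e/(1+e)` with `e = exp(−|z|)` for `z > 0`, else `H/(1+exp(z))`), so
payoff gaps up to |z| ≈ 700 noise units neither overflow nor lose the
`[0, H]` range; beyond that the probability saturates at 0 or `H`
exactly.

## Observables

* `pc` — cooperator fraction of the lattice.
* `rho` — population mean of `n / M` (warm-up denominator as above),
  measured after the round's memory push; undefined (NaN) for `M = 0`.
* `pcc`, `pdd` — lag-1 retention: the fraction of step-t cooperators
  (defectors) still cooperating (defecting) at step t+1, NaN when the
  strategy is absent at step t.  Retention is always lag-1 in *recorded*
  steps when `record_every > 1`.
* Recorded rows satisfy the bookkeeping identity
  `pc(t+1) = pc(t)·pcc(t+1) + (1 − pc(t))·(1 − pdd(t+1))` exactly, which
  the suite asserts on live runs.

Time series are written as CSV (`t,pc,rho,pcc,pdd`, missing values
empty); lattice snapshots as `L` rows of space-separated 0/1, optionally
rendered to PNG (red = C, blue = D).

## Experiment scales

Canonical figure recipes run at two scales with identical parameter
grids: *full* (L = 200, 10⁴ MCS) and *desk* (L = 50 for steady-state
sweeps, L = 100 for trajectory experiments; 2 × 10³ MCS; 5 replicates).
Desk scale is the package's default for validation: each sweep completes
in minutes on one core, and the transient phenomena of interest (the
early dip of `pc`, the stability transient, retention crossings) occur
within the first few hundred MCS.  Steady-state cooperation is the mean
of `pc` over the last 10% of recorded steps; replicate `r` of an
experiment uses seed `base + r`.

`scripts/acceptance.py` measures, at the canonical operating point
(beta = 0.5, K = 0.1, T = 1.05, L = 100, 2000 MCS, 5 seeds,
M ∈ {3,5,7,9}): the transient minimum and the equilibrium maximum of the
seed-averaged `rho(t)`; the mean retentions over the first five MCS
(M ∈ {3,5,7}); the retention level at the first `pcc > pdd` crossing
(closest approach if a curve never crosses); and the recovery onset,
defined as the time of the minimum of `pc(t)` smoothed with a 10-step
moving average (M ∈ {5,7,9}).

## What the simulations do and do not show

The initial condition is an i.i.d. 50/50 lattice — the standard
well-mixed start for this model family.  It probes whether cooperation
can *emerge* from disorder; it says nothing about invasion of a resident
population, structured initial conditions, or real social networks
(degree heterogeneity, clustering, mobility are all absent by design).

Within the model, the memory damping acts as strategy inertia: it slows
interface motion symmetrically but lets compact cooperator clusters
survive the early defector onslaught.  The suite verifies the resulting
claims that are robust at desk scale: full defection at `M = 0` for
`T = 1.05`; extinction of cooperation for every `M ≤ 9` once `T ≥ 1.6`;
steady-state cooperation non-decreasing in `M` and in `beta` at
`T = 1.05`; and a stability curve that saturates near 1 as the pattern
freezes.  At `T = 1.04` the package produces the characteristic
dip-then-recovery of `pc(t)` with onset near t ≈ 100 (see the README
example).

Known limitations:

* At the operating point `T = 1.05`, `beta = 0.5` the model sits at the
  edge of its cooperative phase: across the probed schemes (asynchronous
  and synchronous), stability attributions (self, neighbor) and reset
  policies, cooperation usually goes extinct within 2000 MCS at
  L ≤ 200.  Transient statistics tied to a recovering cooperative phase
  at exactly this point (a deep stability dip, low early retentions, a
  mid-range retention crossing, an onset near 100 MCS) are therefore not
  reproduced by this implementation; the corresponding acceptance checks
  fail and are left failing by design.  The same phenomenology appears
  0.01 lower in temptation.
* The asynchronous scheme caps per-round strategy turnover near 1 − 1/e
  (Poisson selection); statistics that imply half the population
  switching per round can only arise under the synchronous option.
* `rho` is measured after the memory push, so an agent always agrees
  with its newest entry at measurement time and `rho` is bounded below
  by the reciprocal of the warm-up denominator early on.
* Fixed (non-periodic) boundaries are supported but break translation
  invariance; all shipped experiments use periodic boundaries.
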
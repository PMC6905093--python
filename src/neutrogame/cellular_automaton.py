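"""Stochastic cellular automaton of the neutrophil game on a periodic lattice.

A side x side torus starts filled with *activated* (undecided) neutrophils.
Each iteration picks one activated cell uniformly at random; the cell plays
the pairwise game with every already-decided cell in its Moore neighborhood
of range 1 (undecided neighbors have no strategy and contribute no payoff)
and subtracts the exponential cost of the inflammation-triggering moieties
(ITMs) still unresolved, evaluated for each hypothetical choice.  The higher
total fitness wins; exact ties fall to apoptosis, the default death pathway.
The run ends after exactly side^2 decisions, when no activated cell remains.

Remaining-ITM accounting mirrors the mean-field ledger: a cell that has not
yet committed is booked at the apoptotic neutralization rate ``n`` (apoptosis
being the default pathway), so the ledger reads

    R = pool - m * (#necrotic) - n * (#everyone else) - (m or n for the
        focal cell's hypothetical choice)

with "#..." counted over the whole lattice under the GLOBAL sensing scheme
and over the 3x3 neighborhood under the LOCAL scheme (the ITM concentration
is spatially homogeneous, so a site senses the full pool value either way).
The pool is the raw initial ITM concentration by default; the power-law
exponent k belongs to the dose-response data fit, not to the dose itself
(``apply_power_k`` switches the transformed pool on for sensitivity runs,
and ``undecided_neutralize=False`` switches to a ledger in which undecided
cells neutralize nothing).

Decisions compare the two fitnesses through their difference evaluated in
log domain, which is exact and immune to exponential overflow at high doses:

    f(APO) - f(NEC) = (b+c) * d - exp(alpha R_nec) * expm1(alpha (R_apo - R_nec))

where d is the number of decided neighbors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .game_core import Strategy, build_payoff_matrix, payoff
from .parameter_space import DEFAULT_CONSTANTS, DataFitConstants, ParameterTuple

__all__ = [
    "CellState",
    "ITMScheme",
    "CAConfig",
    "LatticeState",
    "CARunResult",
    "init_lattice",
    "moore_neighborhood",
    "remaining_itms_ca",
    "strategy_fitness",
    "step",
    "run",
    "sweep_ca",
]

_EXP_CAP = 700.0  # cap on exp() arguments; beyond this the cost dwarfs any payoff


class CellState(IntEnum):
    """Lattice cell state; decided states share the Strategy integer codes."""

    APOPTOTIC = 0
    NECROTIC = 1
    ACTIVATED = 2


class ITMScheme(Enum):
    """How an activated cell senses the remaining-ITM cost."""

    GLOBAL = "global"
    LOCAL = "local"


@dataclass(frozen=True)
class CAConfig:
    """One cellular-automaton run.

    side                 lattice side length; side^2 cells stand in for N_T
    scheme               GLOBAL or LOCAL ITM sensing
    parameters           payoff/neutralization tuple (alpha, b, c, m, n)
    constants            data-fit constants (supplies k for the optional
                         pool transform)
    itms_initial         initial ITM concentration (the dose)
    seed                 RNG seed; fixes the whole decision sequence
    apply_power_k        transform the initial pool by ^k (sensitivity runs)
    floor_pool_at_zero   floor remaining-ITM values at 0
    undecided_neutralize book undecided cells at rate n in the ITM ledger
    zero_cost            drop the ITM cost term entirely (degeneration checks)
    snapshot_fractions   run fractions at which to record grid snapshots
    tie_rel_tol          relative tolerance under which fitnesses count as tied
    """

    parameters: ParameterTuple
    itms_initial: float
    scheme: ITMScheme = ITMScheme.GLOBAL
    constants: DataFitConstants = DEFAULT_CONSTANTS
    side: int = 50
    seed: int = 0
    apply_power_k: bool = False
    floor_pool_at_zero: bool = False
    undecided_neutralize: bool = True
    zero_cost: bool = False
    snapshot_fractions: tuple[float, ...] | None = None
    tie_rel_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.side <= 1:
            raise InvalidParameterError(f"side must be > 1, got {self.side}")
        if self.itms_initial < 0:
            raise InvalidParameterError("itms_initial must be >= 0")

    @property
    def n_cells(self) -> int:
        return self.side * self.side

    @property
    def initial_pool(self) -> float:
        if self.apply_power_k:
            return self.itms_initial ** self.constants.k
        return float(self.itms_initial)


@dataclass
class LatticeState:
    """Mutable CA state: the grid plus remaining-ITM bookkeeping and RNG.

    ``global_pool`` tracks initial_pool - m * decided_necrotic
    - n * decided_apoptotic (decided cells only; the undecided-cell booking
    happens at fitness-evaluation time).  ``order`` is a seeded permutation
    of all sites consumed lazily — distributionally equivalent to uniform
    choice among the remaining activated cells and cheaper than rejection
    sampling.
    """

    grid: np.ndarray
    decided_necrotic: int
    decided_apoptotic: int
    global_pool: float
    initial_pool: float
    rng: np.random.Generator
    order: np.ndarray
    cursor: int = 0
    _neighbors: np.ndarray = field(repr=False, default=None)  # (side^2, 8) flat indices

    @property
    def side(self) -> int:
        return self.grid.shape[0]

    @property
    def activated(self) -> int:
        return self.grid.size - self.decided_necrotic - self.decided_apoptotic


def moore_neighborhood(site: tuple[int, int], side: int) -> list[tuple[int, int]]:
    """The 8 toroidal Moore-range-1 neighbors of ``site``, excluding itself."""
    r, c = site
    if not (0 <= r < side and 0 <= c < side):
        raise InvalidParameterError(f"site {site} outside a {side}x{side} grid")
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            out.append(((r + dr) % side, (c + dc) % side))
    return out


def _neighbor_table(side: int) -> np.ndarray:
    """Flat-index Moore neighbors for every site, shape (side^2, 8)."""
    idx = np.arange(side * side).reshape(side, side)
    cols = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            cols.append(np.roll(np.roll(idx, -dr, axis=0), -dc, axis=1).ravel())
    return np.stack(cols, axis=1)


def init_lattice(config: CAConfig) -> LatticeState:
    """All-activated lattice with the initial ITM pool and a seeded visit order."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    return LatticeState(
        grid=np.full((config.side, config.side), CellState.ACTIVATED, dtype=np.int8),
        decided_necrotic=0,
        decided_apoptotic=0,
        global_pool=config.initial_pool,
        initial_pool=config.initial_pool,
        rng=rng,
        order=rng.permutation(n),
        _neighbors=_neighbor_table(config.side),
    )


def _neighbor_counts(state: LatticeState, flat_site: int) -> tuple[int, int]:
    """(necrotic, apoptotic) counts among the 8 Moore neighbors."""
    neigh = state.grid.ravel()[state._neighbors[flat_site]]
    return int(np.sum(neigh == CellState.NECROTIC)), int(
        np.sum(neigh == CellState.APOPTOTIC)
    )


def remaining_itms_ca(
    state: LatticeState,
    site: tuple[int, int],
    hypothetical: Strategy,
    config: CAConfig,
) -> float:
    """Remaining-ITM ledger sensed at ``site`` under a hypothetical choice."""
    m = config.parameters.m
    n = config.parameters.n
    own = m if hypothetical is Strategy.NECROSIS else n
    flat = site[0] * state.side + site[1]
    if config.scheme is ITMScheme.GLOBAL:
        value = state.global_pool - own
        if config.undecided_neutralize:
            value -= n * (state.activated - 1)  # everyone undecided but the focal cell
    else:
        n_nec, n_apo = _neighbor_counts(state, flat)
        value = state.initial_pool - m * n_nec - n * n_apo - own
        if config.undecided_neutralize:
            value -= n * (8 - n_nec - n_apo)
    if config.floor_pool_at_zero:
        value = max(0.0, value)
    return value


def strategy_fitness(
    state: LatticeState,
    site: tuple[int, int],
    strategy: Strategy,
    config: CAConfig,
) -> float:
    """Payoff against all decided Moore neighbors minus the remaining-ITM cost.

    Activated neighbors contribute zero payoff.  An overflowing cost
    exponential is flagged as -inf fitness; `step` avoids the overflow by
    comparing the two fitnesses in log domain instead.
    """
    mat = build_payoff_matrix(config.parameters.payoff_params)
    flat = site[0] * state.side + site[1]
    n_nec, n_apo = _neighbor_counts(state, flat)
    total = n_nec * payoff(strategy, Strategy.NECROSIS, mat) + n_apo * payoff(
        strategy, Strategy.APOPTOSIS, mat
    )
    if config.zero_cost:
        return total - 1.0  # constant cost: present but strategy-independent
    exponent = config.parameters.alpha * remaining_itms_ca(state, site, strategy, config)
    if exponent > _EXP_CAP:
        return -math.inf
    return total - math.exp(exponent)


def _decide(state: LatticeState, flat_site: int, config: CAConfig) -> Strategy:
    """Winning strategy at a site: sign of f(NEC) - f(APO), ties to apoptosis."""
    n_nec, n_apo = _neighbor_counts(state, flat_site)
    d = n_nec + n_apo
    # Payoff advantage of apoptosis over necrosis is (C-A) = (D-B) = b+c per
    # decided neighbor, independent of the neighbor's own strategy.
    pay_diff = config.parameters.bc_sum * d
    if config.zero_cost:
        cost_diff = 0.0
    else:
        site = (flat_site // state.side, flat_site % state.side)
        r_nec = remaining_itms_ca(state, site, Strategy.NECROSIS, config)
        r_apo = remaining_itms_ca(state, site, Strategy.APOPTOSIS, config)
        a_nec = config.parameters.alpha * r_nec
        a_apo = config.parameters.alpha * r_apo
        if a_apo == a_nec:
            cost_diff = 0.0
        else:
            # exp(a_apo) - exp(a_nec), overflow-free for any dose
            cost_diff = math.exp(min(a_nec, _EXP_CAP)) * math.expm1(a_apo - a_nec)
    if math.isclose(pay_diff, cost_diff, rel_tol=config.tie_rel_tol):
        return Strategy.APOPTOSIS
    if pay_diff < cost_diff:
        return Strategy.NECROSIS
    return Strategy.APOPTOSIS


def step(state: LatticeState, config: CAConfig) -> LatticeState:
    """Resolve one activated cell in place; returns the state for chaining."""
    if state.activated == 0:
        raise InvalidParameterError("no activated cell left to decide")
    flat = int(state.order[state.cursor])
    state.cursor += 1
    choice = _decide(state, flat, config)
    grid = state.grid.ravel()
    if choice is Strategy.NECROSIS:
        grid[flat] = CellState.NECROTIC
        state.decided_necrotic += 1
        state.global_pool -= config.parameters.m
    else:
        grid[flat] = CellState.APOPTOTIC
        state.decided_apoptotic += 1
        state.global_pool -= config.parameters.n
    return state


@dataclass(frozen=True)
class CARunResult:
    """Outcome of a completed run.

    ``cumulative_necrotic_per_step`` has one entry per decision (length
    side^2), non-decreasing with increments in {0, 1}.  ``snapshots`` maps
    a decision index to a grid copy (integer-coded: 0 apoptotic, 1 necrotic,
    2 activated).
    """

    percent_necrosis: float
    percent_apoptosis: float
    cumulative_necrotic_per_step: np.ndarray
    final_grid: np.ndarray
    config: CAConfig
    snapshots: dict[int, np.ndarray] | None = None


def run(config: CAConfig) -> CARunResult:
    """Run the automaton to completion: exactly side^2 decisions."""
    state = init_lattice(config)
    n = config.n_cells
    cumulative = np.empty(n, dtype=np.int64)
    snap_steps: dict[int, np.ndarray] | None = None
    wanted: set[int] = set()
    if config.snapshot_fractions is not None:
        snap_steps = {}
        wanted = {min(n, max(0, round(f * n))) for f in config.snapshot_fractions}
        if 0 in wanted:
            snap_steps[0] = state.grid.copy()
    for t in range(n):
        step(state, config)
        cumulative[t] = state.decided_necrotic
        if snap_steps is not None and (t + 1) in wanted:
            snap_steps[t + 1] = state.grid.copy()
    return CARunResult(
        percent_necrosis=100.0 * state.decided_necrotic / n,
        percent_apoptosis=100.0 * state.decided_apoptotic / n,
        cumulative_necrotic_per_step=cumulative,
        final_grid=state.grid.copy(),
        config=config,
        snapshots=snap_steps,
    )


def sweep_ca(
    tuples: Sequence[ParameterTuple],
    itms_grid: Iterable[float],
    seeds: Sequence[int],
    scheme: ITMScheme = ITMScheme.GLOBAL,
    constants: DataFitConstants = DEFAULT_CONSTANTS,
    side: int = 50,
    **config_kwargs,
) -> pd.DataFrame:
    """Mean and standard deviation of percent necrosis per ITM level.

    Every (tuple, seed) pair is run at every dose; the run seed is derived
    as ``seed * 100003 + tuple_index`` so replicates across tuples stay
    decorrelated yet fully reproducible.  Returns a DataFrame with columns
    itms_initial, mean_percent_necrosis, std_percent_necrosis, n_runs.
    """
    if not tuples or not seeds:
        raise InvalidParameterError("tuples and seeds must be non-empty")
    rows = []
    for itms in itms_grid:
        values = []
        for ti, tup in enumerate(tuples):
            for s in seeds:
                cfg = CAConfig(
                    parameters=tup,
                    itms_initial=float(itms),
                    scheme=scheme,
                    constants=constants,
                    side=side,
                    seed=s * 100003 + ti,
                    **config_kwargs,
                )
                values.append(run(cfg).percent_necrosis)
        arr = np.asarray(values)
        rows.append(
            {
                "itms_initial": float(itms),
                "mean_percent_necrosis": float(arr.mean()),
                "std_percent_necrosis": float(arr.std()),
                "n_runs": len(values),
            }
        )
    return pd.DataFrame(rows)
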
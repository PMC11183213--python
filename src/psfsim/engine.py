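"""Stochastic lattice dynamics of the plant community.

The community lives on a square grid with at most one plant per cell.  Each
time step applies, in order: immigration (empty cells are colonised from an
external species pool), recruitment (remaining empty cells are filled by
offspring of the standing community, chosen with probability proportional to
total species biomass — global dispersal), growth (multiplicative, capped by
the combined biomass of the von Neumann neighbourhood) and mortality (each
plant dies independently).  A dying plant leaves its soil conditioning
behind, so the *previous occupant* sets the growth rate of the next recruit
in that cell.

Growth rates are fixed at establishment from the interaction table and the
cell's soil state and never re-evaluated: a plant does not experience its
own conditioning of its cell, only the next occupant does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .networks import (
    GrowthRates,
    InteractionTable,
    ScenarioSpec,
    build_scenario_table,
)

__all__ = [
    "SimConfig",
    "GridState",
    "SimulationResult",
    "initialise",
    "step_immigration",
    "step_recruitment",
    "establishment_rate",
    "step_growth",
    "step_mortality",
    "introduce_invader",
    "run_simulation",
]

log = logging.getLogger(__name__)

EMPTY = -1  # occupant code for an empty cell


@dataclass(frozen=True)
class SimConfig:
    """All numeric parameters of a single simulation run.

    Defaults are the study conditions: a 100 x 100 grid, a pool of 100
    resident species, per-empty-cell immigration probability 0.001,
    per-plant mortality probability 0.1, 12,000 steps with 100 invader
    individuals introduced at step 10,001.  The neighbourhood biomass cap
    (focal plant plus its four von Neumann neighbours) sets the biomass
    scale; 100 units by default.
    """

    grid_side: int = 100
    n_resident_species: int = 100
    p_immigration: float = 0.001
    p_mortality: float = 0.1
    n_steps: int = 12_000
    invasion_step: int = 10_001
    n_invaders: int = 100
    initial_biomass: float = 1.0
    neighbourhood_cap: float = 100.0
    cap_mode: str = "rescale"  # "rescale" or "clip"
    toroidal: bool = False
    record_every: int = 500
    rng_seed: int = 0
    rates: GrowthRates = field(default_factory=GrowthRates)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_immigration <= 1.0:
            raise ValueError("p_immigration must be a probability")
        if not 0.0 <= self.p_mortality <= 1.0:
            raise ValueError("p_mortality must be a probability")
        for name in ("grid_side", "n_resident_species", "n_steps",
                     "n_invaders", "record_every"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.initial_biomass <= 0 or self.neighbourhood_cap <= 0:
            raise ValueError("biomass parameters must be positive")
        if self.cap_mode not in ("rescale", "share", "clip"):
            raise ValueError("cap_mode must be 'rescale', 'share' or 'clip'")

    @property
    def n_cells(self) -> int:
        return self.grid_side * self.grid_side


@dataclass
class GridState:
    """Lattice state: occupant species, biomass, fixed growth rate and soil.

    ``occupant`` is ``EMPTY`` (-1) for vacant cells; ``soil`` holds the
    species index that last conditioned the cell, or the table's
    unconditioned code for never-occupied soil.  ``biomass > 0`` iff the
    cell is occupied; ``growth_rate`` is meaningful only for occupied cells.
    """

    occupant: np.ndarray  # (side, side) int16
    biomass: np.ndarray  # (side, side) float64
    growth_rate: np.ndarray  # (side, side) float64
    soil: np.ndarray  # (side, side) int16

    @property
    def occupied(self) -> np.ndarray:
        return self.occupant != EMPTY

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.occupant != EMPTY))

    def species_biomass(self, n_species: int) -> np.ndarray:
        """Total biomass per species (residents then invader)."""
        occ = self.occupant != EMPTY
        return np.bincount(
            self.occupant[occ].astype(np.int64),
            weights=self.biomass[occ],
            minlength=n_species,
        )

    def species_abundance(self, n_species: int) -> np.ndarray:
        """Individual count per species (residents then invader)."""
        occ = self.occupant != EMPTY
        return np.bincount(
            self.occupant[occ].astype(np.int64), minlength=n_species
        )

    def copy(self) -> "GridState":
        return GridState(
            self.occupant.copy(),
            self.biomass.copy(),
            self.growth_rate.copy(),
            self.soil.copy(),
        )

    def to_frame(self):
        """Tidy per-cell snapshot (row, col, occupant, biomass, soil);
        empty cells have occupant -1 and unoccupied soil keeps its last
        conditioning species."""
        import pandas as pd

        side = self.occupant.shape[0]
        rows, cols = np.divmod(np.arange(side * side), side)
        return pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "occupant": self.occupant.ravel(),
                "biomass": self.biomass.ravel(),
                "growth_rate": self.growth_rate.ravel(),
                "soil": self.soil.ravel(),
            }
        )


def initialise(config: SimConfig, table: InteractionTable | None = None) -> GridState:
    """Empty grid with unconditioned soil everywhere."""
    side = config.grid_side
    unconditioned = (table.unconditioned if table is not None
                     else config.n_resident_species + 1)
    return GridState(
        occupant=np.full((side, side), EMPTY, dtype=np.int16),
        biomass=np.zeros((side, side)),
        growth_rate=np.zeros((side, side)),
        soil=np.full((side, side), unconditioned, dtype=np.int16),
    )


def establishment_rate(
    recruit_species: int | np.ndarray,
    soil: int | np.ndarray,
    table: InteractionTable,
) -> float | np.ndarray:
    """Growth factor a recruit establishes with on the given soil state.

    Unconditioned soil yields the standard rate for every species.  The
    returned rate stays fixed for the plant's lifetime.
    """
    values = table.values
    recruit = np.asarray(recruit_species)
    soil_arr = np.asarray(soil)
    if np.any(recruit < 0) or np.any(recruit > table.invader):
        raise KeyError("unknown recruit species index")
    if np.any(soil_arr < 0) or np.any(soil_arr > table.unconditioned):
        raise KeyError("unknown soil state")
    out = values[recruit, soil_arr]
    return float(out) if out.ndim == 0 else out


def _place(
    state: GridState,
    flat_cells: np.ndarray,
    species: np.ndarray,
    config: SimConfig,
    table: InteractionTable,
    values: np.ndarray | None = None,
) -> None:
    """Establish new individuals in the given (currently empty) flat cells."""
    if values is None:
        values = table.values
    occ = state.occupant.ravel()
    bio = state.biomass.ravel()
    rate = state.growth_rate.ravel()
    soil = state.soil.ravel()
    rate[flat_cells] = values[species, soil[flat_cells]]
    occ[flat_cells] = species
    bio[flat_cells] = config.initial_biomass
    soil[flat_cells] = species  # the occupant conditions its own cell

def step_immigration(
    state: GridState,
    config: SimConfig,
    table: InteractionTable,
    rng: np.random.Generator,
    _values: np.ndarray | None = None,
) -> GridState:
    """Each empty cell is independently colonised with probability
    ``p_immigration`` by a uniformly random *resident* species (the invader
    never immigrates)."""
    if config.p_immigration == 0.0:
        return state
    empty = np.flatnonzero(state.occupant.ravel() == EMPTY)
    hit = empty[rng.random(empty.size) < config.p_immigration]
    if hit.size:
        species = rng.integers(0, config.n_resident_species, size=hit.size)
        _place(state, hit, species.astype(np.int16), config, table, _values)
    return state


def step_recruitment(
    state: GridState,
    config: SimConfig,
    table: InteractionTable,
    rng: np.random.Generator,
    _values: np.ndarray | None = None,
) -> GridState:
    """Fill every remaining empty cell with an offspring of the standing
    community; species are drawn independently with probability proportional
    to current total species biomass (global dispersal).  No recruitment
    happens while the community has zero biomass."""
    empty = np.flatnonzero(state.occupant.ravel() == EMPTY)
    if empty.size == 0:
        return state
    n_sp = table.invader + 1
    totals = state.species_biomass(n_sp)
    grand = totals.sum()
    if grand <= 0.0:
        return state
    # inverse-CDF draw, proportional to species biomass
    cdf = np.cumsum(totals)
    species = np.searchsorted(cdf, rng.random(empty.size) * grand, side="right")
    np.clip(species, 0, n_sp - 1, out=species)
    _place(state, empty, species.astype(np.int16), config, table, _values)
    return state


def _neighbour_sum(biomass: np.ndarray, toroidal: bool) -> np.ndarray:
    """Combined biomass of the four von Neumann neighbours of each cell."""
    if toroidal:
        return (
            np.roll(biomass, 1, axis=0)
            + np.roll(biomass, -1, axis=0)
            + np.roll(biomass, 1, axis=1)
            + np.roll(biomass, -1, axis=1)
        )
    out = np.zeros_like(biomass)
    out[1:, :] += biomass[:-1, :]
    out[:-1, :] += biomass[1:, :]
    out[:, 1:] += biomass[:, :-1]
    out[:, :-1] += biomass[:, 1:]
    return out


def _neighbour_min(factor: np.ndarray, toroidal: bool) -> np.ndarray:
    """Minimum of a cell's own value and its four von Neumann neighbours'."""
    if toroidal:
        out = np.minimum(factor, np.roll(factor, 1, axis=0))
        np.minimum(out, np.roll(factor, -1, axis=0), out=out)
        np.minimum(out, np.roll(factor, 1, axis=1), out=out)
        np.minimum(out, np.roll(factor, -1, axis=1), out=out)
        return out
    out = factor.copy()
    np.minimum(out[1:, :], factor[:-1, :], out=out[1:, :])
    np.minimum(out[:-1, :], factor[1:, :], out=out[:-1, :])
    np.minimum(out[:, 1:], factor[:, :-1], out=out[:, 1:])
    np.minimum(out[:, :-1], factor[:, 1:], out=out[:, :-1])
    return out


def step_growth(
    state: GridState,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> GridState:
    """Multiply every plant's biomass by its fixed growth rate, then enforce
    the neighbourhood cap: the combined biomass of a focal plant and its four
    von Neumann neighbours (five individuals) may not exceed
    ``neighbourhood_cap``.

    Two cap mechanics are available:

    * ``rescale`` (default) — every over-cap neighbourhood is shrunk back to
      the cap: each plant is scaled by the most restrictive
      ``cap / neighbourhood-sum`` factor among the five neighbourhoods it
      belongs to, computed on the freshly grown biomass field.  Plants can
      therefore lose biomass to faster-growing neighbours, so the cap acts
      as zero-sum local competition and growth-rate differences compound
      into biomass differences over a plant's lifetime.  Every
      neighbourhood sum is at or below the cap after the step.
    * ``share`` — plants never shrink; instead the biomass *increments*
      ``b * (r - 1)`` contest the room left in each neighbourhood
      (``cap`` minus the pre-step five-cell sum) and are scaled down
      proportionally wherever the combined demand exceeds it, so faster
      growers take a proportionally larger share of every slack window.
      Every neighbourhood sum stays at or below the cap.
    * ``clip`` — a plant's growth is truncated at the room left by its
      pre-step neighbours (``cap - neighbour sum``) and never drops below
      its pre-step biomass; biomass is then set mainly by vacancy timing
      rather than by growth rate.

    All updates are synchronous and independent of cell order.
    """
    b = state.biomass
    grown = b * state.growth_rate  # 0 for empty cells (rate 0)
    cap = config.neighbourhood_cap
    if config.cap_mode == "clip":
        nsum = _neighbour_sum(b, config.toroidal)
        state.biomass = np.maximum(b, np.minimum(grown, cap - nsum))
        return state
    if config.cap_mode == "share":
        delta = grown - b  # demanded increment, 0 for empty cells
        demand = delta + _neighbour_sum(delta, config.toroidal)
        room = np.maximum(cap - (b + _neighbour_sum(b, config.toroidal)), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(demand > room, room / demand, 1.0)
        state.biomass = b + delta * _neighbour_min(factor, config.toroidal)
        return state
    s5 = grown + _neighbour_sum(grown, config.toroidal)  # 5-cell sums
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(s5 > cap, cap / s5, 1.0)
    state.biomass = grown * _neighbour_min(factor, config.toroidal)
    return state


def step_mortality(
    state: GridState,
    config: SimConfig,
    rng: np.random.Generator,
) -> GridState:
    """Each plant (including same-step recruits) dies independently with
    probability ``p_mortality``; its cell becomes empty but keeps the dead
    plant's species as soil conditioning."""
    if config.p_mortality == 0.0:
        return state
    occ = state.occupant != EMPTY
    dead = occ & (rng.random(state.occupant.shape) < config.p_mortality)
    # soil already records the occupant's species; only clear the plant
    state.occupant[dead] = EMPTY
    state.biomass[dead] = 0.0
    state.growth_rate[dead] = 0.0
    return state


def introduce_invader(
    state: GridState,
    config: SimConfig,
    table: InteractionTable,
    rng: np.random.Generator,
    _values: np.ndarray | None = None,
) -> GridState:
    """Place ``n_invaders`` invader individuals into distinct randomly chosen
    empty cells (fewer if the grid is nearly full) at initial biomass; their
    growth rates follow the establishment rule, so invaders start at the
    standard rate except on invader-conditioned soil."""
    empty = np.flatnonzero(state.occupant.ravel() == EMPTY)
    n = min(config.n_invaders, empty.size)
    if n < config.n_invaders:
        log.warning(
            "only %d empty cells available for %d invaders", empty.size,
            config.n_invaders,
        )
    if n == 0:
        return state
    cells = rng.choice(empty, size=n, replace=False)
    species = np.full(n, table.invader, dtype=np.int16)
    _place(state, cells, species, config, table, _values)
    return state


@dataclass
class SimulationResult:
    """Recorded species biomass/abundance time series of one replicate."""

    scenario: ScenarioSpec
    config: SimConfig
    steps: np.ndarray  # recorded step indices
    biomass: np.ndarray  # (n_recorded, n_resident + 1)
    abundance: np.ndarray  # (n_recorded, n_resident + 1)

    def index_of(self, step: int) -> int:
        hits = np.flatnonzero(self.steps == step)
        if hits.size == 0:
            raise KeyError(f"step {step} was not recorded")
        return int(hits[0])

    def summary_at(self, step: int):
        from .metrics import CommunitySummary

        i = self.index_of(step)
        return CommunitySummary(
            step=step,
            biomass_by_species=self.biomass[i],
            abundance_by_species=self.abundance[i],
            n_resident=self.config.n_resident_species,
        )

    @property
    def final(self):
        return self.summary_at(int(self.steps[-1]))

    def to_frame(self):
        """Long-form recorded time series: step, species, biomass, abundance.

        Species are 0-based residents with the invader last; zero rows are
        kept so every recorded step carries the full vector.
        """
        import pandas as pd

        n_steps, n_sp = self.biomass.shape
        return pd.DataFrame(
            {
                "step": np.repeat(self.steps, n_sp),
                "species": np.tile(np.arange(n_sp), n_steps),
                "biomass": self.biomass.ravel(),
                "abundance": self.abundance.ravel(),
            }
        )


def run_simulation(
    scenario: ScenarioSpec,
    config: SimConfig,
    table: InteractionTable | None = None,
) -> SimulationResult:
    """Run one replicate of a scenario and record its community time series.

    Per step the processes run in order immigration, recruitment, growth,
    mortality; recruitment is skipped on the first step so that the very
    first immigrants can establish.  If the scenario has an invasion, the
    invaders are placed at the start of ``invasion_step``, before that
    step's immigration.  Summaries are recorded after all four processes,
    every ``record_every`` steps and always at steps 5,000, 10,000 and the
    final step.  Fully reproducible from ``rng_seed``.
    """
    if table is None:
        table = build_scenario_table(
            scenario, config.n_resident_species, config.rates
        )
    if scenario.invasion and config.invasion_step > config.n_steps:
        raise ValueError("invasion_step must not exceed n_steps")
    rng = np.random.default_rng(config.rng_seed)
    state = initialise(config, table)
    n_sp = table.invader + 1
    values = table.values  # growth-factor matrix, fixed for the whole run

    mandatory = {s for s in (5_000, 10_000, config.n_steps)
                 if s <= config.n_steps}
    record_steps = sorted(
        set(range(config.record_every, config.n_steps + 1,
                  config.record_every)) | mandatory
    )
    rec_bio = np.zeros((len(record_steps), n_sp))
    rec_abund = np.zeros((len(record_steps), n_sp), dtype=np.int64)
    rec_i = 0

    for step in range(1, config.n_steps + 1):
        if scenario.invasion and step == config.invasion_step:
            introduce_invader(state, config, table, rng, values)
        step_immigration(state, config, table, rng, values)
        if step > 1:
            step_recruitment(state, config, table, rng, values)
        step_growth(state, config, rng)
        step_mortality(state, config, rng)
        if rec_i < len(record_steps) and step == record_steps[rec_i]:
            rec_bio[rec_i] = state.species_biomass(n_sp)
            rec_abund[rec_i] = state.species_abundance(n_sp)
            rec_i += 1

    return SimulationResult(
        scenario=scenario,
        config=config,
        steps=np.asarray(record_steps),
        biomass=rec_bio,
        abundance=rec_abund,
    )
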
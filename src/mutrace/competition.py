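"""One competition among subpopulations, run to fixation.

A competition iterates the generation cycle (mutation, then fitness-weighted
reproduction) until every individual carries the same subpopulation label.
The mutation rate of the surviving subpopulation is the competition's
*fixed* rate, and the number of elapsed generation cycles its competition
time.  A ``(config, seed)`` pair fully determines the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .effects import MutationModel
from .errors import ExtinctionError, InvalidParameterError
from .population import (
    FertilitySpec,
    InitialFitnessSpec,
    PopulationState,
    SubpopulationRateSet,
    check_fixation,
    initialize_population,
    mutate_generation,
    reproduce,
)

__all__ = ["CompetitionConfig", "CompetitionResult", "run_competition", "run_generations"]

ORDERS = ("mutate-first", "reproduce-first")


@dataclass(frozen=True)
class CompetitionConfig:
    """Everything needed to run one competition deterministically from a seed.

    ``order`` selects whether mutation precedes reproduction within a cycle
    (the default, so offspring are sampled by post-mutation fitness) or
    follows it.  ``label_counts`` overrides the default even N/K split of
    founders among subpopulations.
    """

    population_size: int
    rate_set: SubpopulationRateSet
    model: MutationModel
    init_fitness: InitialFitnessSpec = field(default_factory=InitialFitnessSpec)
    fertility: FertilitySpec = field(default_factory=FertilitySpec)
    max_generations: int = 1_000_000
    seed: int = 0
    order: str = "mutate-first"
    label_counts: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.max_generations < 1:
            raise InvalidParameterError(
                f"max_generations must be >= 1, got {self.max_generations}"
            )
        if self.order not in ORDERS:
            raise InvalidParameterError(
                f"order must be one of {ORDERS}, got {self.order!r}"
            )
        if self.population_size < 1:
            raise InvalidParameterError(
                f"population size must be >= 1, got {self.population_size}"
            )
        if self.label_counts is None and self.population_size % len(self.rate_set) != 0:
            raise InvalidParameterError(
                f"population size {self.population_size} is not divisible by "
                f"{len(self.rate_set)} subpopulations"
            )


@dataclass(frozen=True)
class CompetitionResult:
    """Outcome of one competition.

    ``status`` is ``"fixed"`` when a single subpopulation took over,
    ``"censored"`` when the generation safeguard was reached first, and
    ``"extinct"`` when total fitness collapsed to zero.  ``generations``
    counts reproduction events executed.
    """

    fixed_rate: Optional[float]
    fixed_label: Optional[int]
    generations: int
    status: str
    seed: int


def _initialize(config: CompetitionConfig, rng: np.random.Generator) -> PopulationState:
    return initialize_population(
        config.population_size,
        config.rate_set,
        config.init_fitness,
        rng,
        label_counts=config.label_counts,
    )


def run_competition(config: CompetitionConfig) -> CompetitionResult:
    """Iterate generation cycles until fixation, censoring or extinction.

    Fixation is checked after each reproduction step: mutation preserves
    labels, so a subpopulation can only be lost at reproduction.
    """
    rng = np.random.default_rng(config.seed)
    state = _initialize(config, rng)
    mutate_first = config.order == "mutate-first"
    try:
        while state.generation < config.max_generations:
            if mutate_first:
                state = mutate_generation(state, config.rate_set, config.model, rng)
                state = reproduce(state, config.fertility, rng)
                winner = check_fixation(state)
            else:
                state = reproduce(state, config.fertility, rng)
                winner = check_fixation(state)
                if winner is None:
                    state = mutate_generation(state, config.rate_set, config.model, rng)
            if winner is not None:
                return CompetitionResult(
                    fixed_rate=config.rate_set.rate_of(winner),
                    fixed_label=winner,
                    generations=state.generation,
                    status="fixed",
                    seed=config.seed,
                )
    except ExtinctionError:
        return CompetitionResult(
            fixed_rate=None,
            fixed_label=None,
            generations=state.generation,
            status="extinct",
            seed=config.seed,
        )
    return CompetitionResult(
        fixed_rate=None,
        fixed_label=None,
        generations=state.generation,
        status="censored",
        seed=config.seed,
    )


def run_generations(config: CompetitionConfig, n_generations: int) -> List[PopulationState]:
    """Run a fixed number of cycles and record every state (debugging aid).

    The draw sequence is identical to :func:`run_competition`; this variant
    simply ignores fixation and returns the trajectory, which is what the
    loop-based reference engine is compared against.
    """
    rng = np.random.default_rng(config.seed)
    state = _initialize(config, rng)
    states = [state]
    for _ in range(n_generations):
        if config.order == "mutate-first":
            state = mutate_generation(state, config.rate_set, config.model, rng)
            state = reproduce(state, config.fertility, rng)
        else:
            state = reproduce(state, config.fertility, rng)
            state = mutate_generation(state, config.rate_set, config.model, rng)
        states.append(state)
    return states
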
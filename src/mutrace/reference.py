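"""Loop-based reference engine for validating the vectorized simulator.

Every operation here is written as plain Python loops with *scalar* RNG
draws, following exactly the draw-order contract documented in
:mod:`mutrace.population`.  Because numpy's ``Generator`` consumes its
underlying bit stream identically for a vectorized draw of size ``n`` and
for ``n`` sequential scalar draws, a trajectory produced by this engine from
a given seed must be bit-identical to the vectorized engine's trajectory —
any divergence indicates a bookkeeping bug in one of the two.

This module is intentionally slow and is used only in tests and for
debugging small populations.
"""

from __future__ import annotations

from typing import List

import numpy as np

from .effects import MutationModel
from .errors import ExtinctionError, FertilityError, InconsistencyError
from .population import (
    FertilitySpec,
    InitialFitnessSpec,
    PopulationState,
    SubpopulationRateSet,
    initialize_population,
)

__all__ = ["naive_mutate", "naive_reproduce", "naive_run_generations"]


def naive_mutate(
    state: PopulationState,
    rate_set: SubpopulationRateSet,
    model: MutationModel,
    rng: np.random.Generator,
) -> PopulationState:
    """Per-generation mutation step, one explicit loop at a time."""
    labels = [int(x) for x in state.labels]
    fitness = [float(x) for x in state.fitness]

    members = {lab: [] for lab in rate_set.labels}
    for i, lab in enumerate(labels):
        if lab not in members:
            raise InconsistencyError(f"label {lab} has no assigned rate")
        members[lab].append(i)

    # 1. total mutation count per subpopulation, in label order
    totals = []
    for lab, rate in zip(rate_set.labels, rate_set.rates):
        lam = len(members[lab]) * rate
        totals.append(int(rng.poisson(lam)))

    # 2. assign each mutation to a member, in label order
    owners: List[int] = []
    for lab, m_k in zip(rate_set.labels, totals):
        group = members[lab]
        for _ in range(m_k):
            owners.append(group[int(rng.integers(0, len(group)))])

    m_total = len(owners)
    if m_total == 0:
        return PopulationState(
            fitness=np.array(fitness), labels=np.array(labels, dtype=state.labels.dtype),
            generation=state.generation,
        )

    # 3. direction of every mutation
    beneficial = [bool(rng.random() < model.beneficial_fraction) for _ in range(m_total)]

    # 4. magnitudes: all beneficial first, then deleterious in rejection rounds
    n_b = sum(beneficial)
    b_mags = [float(rng.exponential(model.beneficial.mean_effect)) for _ in range(n_b)]
    n_d = m_total - n_b
    spec = model.deleterious
    d_mags = [float(rng.gamma(spec.shape, spec.scale)) for _ in range(n_d)]
    if spec.truncation == "clamp":
        d_mags = [min(v, spec.truncation_bound) for v in d_mags]
    else:
        pending = [i for i, v in enumerate(d_mags) if v > spec.truncation_bound]
        while pending:
            for i in pending:
                d_mags[i] = float(rng.gamma(spec.shape, spec.scale))
            pending = [i for i in pending if d_mags[i] > spec.truncation_bound]

    bi, di = 0, 0
    factors = []
    for is_b in beneficial:
        if is_b:
            factors.append(1.0 + b_mags[bi])
            bi += 1
        else:
            factors.append(1.0 - d_mags[di])
            di += 1

    for owner, factor in zip(owners, factors):
        fitness[owner] *= factor

    return PopulationState(
        fitness=np.array(fitness),
        labels=np.array(labels, dtype=state.labels.dtype),
        generation=state.generation,
    )


def _draw_parents(cum: List[float], total: float, k: int, rng: np.random.Generator) -> List[int]:
    """``k`` weighted parent draws in ascending order, scalar draw by draw.

    Sorted uniforms on ``(0, total)`` are built from ``k + 1`` standard
    exponentials (normalized cumulative sums) and merged against the
    cumulative fitness; a parent is the smallest index with ``cum > u``.
    """
    exps = [float(rng.standard_exponential()) for _ in range(k + 1)]
    s: List[float] = []
    acc = 0.0
    for e in exps:
        acc += e
        s.append(acc)
    scale = total / s[k]
    parents: List[int] = []
    i = 0
    m = len(cum)
    for j in range(k):
        u = s[j] * scale
        while i < m and cum[i] <= u:
            i += 1
        if i == m:
            # u rounded up to the total: take the last positive-weight parent
            last = m - 1
            while last > 0 and cum[last - 1] == cum[last]:
                last -= 1
            parents.append(last)
            i = m - 1
        else:
            parents.append(i)
    return parents


def naive_reproduce(
    state: PopulationState,
    fertility: FertilitySpec,
    rng: np.random.Generator,
) -> PopulationState:
    """Fitness-weighted offspring sampling with explicit loops."""
    n = state.size
    cum: List[float] = []
    acc = 0.0
    for w in state.fitness:
        acc += float(w)
        cum.append(acc)
    total = cum[-1]
    if total <= 0.0:
        raise ExtinctionError(
            f"total fitness is zero at generation {state.generation}; "
            "the population is extinct"
        )

    if fertility.is_unlimited:
        parents = _draw_parents(cum, total, n, rng)
    else:
        cap = fertility.cap
        positive = sum(1 for w in state.fitness if w > 0)
        if cap * positive < n:
            raise FertilityError(
                f"fertility cap {cap} with {positive} positive-fitness parents "
                f"cannot produce {n} offspring"
            )
        parents = []
        used = [0] * n
        while len(parents) < n:
            for candidate in _draw_parents(cum, total, n - len(parents), rng):
                if used[candidate] < cap:
                    used[candidate] += 1
                    parents.append(candidate)

    return PopulationState(
        fitness=np.array([float(state.fitness[p]) for p in parents]),
        labels=np.array([int(state.labels[p]) for p in parents], dtype=state.labels.dtype),
        generation=state.generation + 1,
    )


def naive_run_generations(
    N: int,
    rate_set: SubpopulationRateSet,
    model: MutationModel,
    init_fitness: InitialFitnessSpec,
    fertility: FertilitySpec,
    seed: int,
    n_generations: int,
    order: str = "mutate-first",
) -> List[PopulationState]:
    """Run ``n_generations`` cycles with the loop engine; return all states.

    Founder sampling is shared with the vectorized engine
    (:func:`mutrace.population.initialize_population`); the reference
    reimplements the generation dynamics, which is where the two engines can
    disagree.
    """
    rng = np.random.default_rng(seed)
    state = initialize_population(N, rate_set, init_fitness, rng)
    states = [state]
    for _ in range(n_generations):
        if order == "mutate-first":
            state = naive_mutate(state, rate_set, model, rng)
            state = naive_reproduce(state, fertility, rng)
        else:
            state = naive_reproduce(state, fertility, rng)
            state = naive_mutate(state, rate_set, model, rng)
        states.append(state)
    return states
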
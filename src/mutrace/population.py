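"""Population state and the per-generation Wright-Fisher cycle.

A single well-mixed haploid population of constant size ``N`` is partitioned
into ``K`` labeled subpopulations (lineage classes).  The label is heritable,
never changes by mutation, and determines only one thing: the genome mutation
rate ``U`` of its carriers.  One generation cycle is

1. *mutation* — every individual receives a Poisson(``U_label``) number of
   new mutations whose effects multiply its fitness, and
2. *reproduction* — ``N`` offspring are sampled with replacement, each parent
   chosen with probability proportional to its (post-mutation) fitness, i.e.
   offspring counts are multinomial(``N``, ``w_i / sum w``).

Randomness contract
-------------------
All sampling for one competition comes from a single ``numpy`` Generator, and
the order of draws within a generation is fixed:

1. one Poisson draw of the *total* mutation count per subpopulation, in label
   order, with mean ``n_k * U_k`` (equivalent, by Poisson splitting, to
   per-individual Poisson(``U_k``) draws);
2. for each subpopulation in label order, one uniform-integer draw per
   mutation assigning it to a member (members enumerated in index order);
3. one uniform draw per mutation (in the same order) deciding its direction
   (beneficial with probability ``p_b``);
4. the beneficial magnitudes, then the deleterious magnitudes (the latter in
   rejection rounds, see :mod:`mutrace.effects`);
5. reproduction: one uniform draw per offspring slot, mapped to a parent by
   inversion of the cumulative fitness distribution.

A naive loop-based engine (:mod:`mutrace.reference`) replays the same stream
with scalar draws and must produce bit-identical trajectories.

The fertility cap (upper limit on offspring per parent per generation) is
realized by sequential weighted sampling with rejection: candidate parents
are repeatedly drawn from the *fixed* fitness distribution and a draw of an
already-saturated parent is discarded, which is equivalent to removing the
parent and renormalizing.  Candidates are drawn in rounds of the number of
unfilled slots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .effects import (
    MutationModel,
    draw_beneficial_magnitudes,
    draw_deleterious_magnitudes,
)
from .errors import (
    ExtinctionError,
    FertilityError,
    InconsistencyError,
    InvalidParameterError,
)

__all__ = [
    "SubpopulationRateSet",
    "InitialFitnessSpec",
    "FertilitySpec",
    "PopulationState",
    "initialize_population",
    "mutate_generation",
    "reproduce",
    "check_fixation",
]


@dataclass(frozen=True)
class SubpopulationRateSet:
    """Ordered set of genome mutation rates, one per subpopulation label.

    Rates must be sorted in non-decreasing order.  Distinct rates are the
    normal case; equal rates (in particular, all zero) are admitted so that
    selectively neutral control experiments can be expressed.
    """

    rates: Tuple[float, ...]
    labels: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.rates)
        object.__setattr__(self, "rates", rates)
        if len(rates) < 2:
            raise InvalidParameterError("a rate set needs at least 2 subpopulations")
        if any(r < 0 for r in rates):
            raise InvalidParameterError(f"mutation rates must be >= 0: {rates}")
        if any(b < a for a, b in zip(rates, rates[1:])):
            raise InvalidParameterError(f"rates must be sorted non-decreasing: {rates}")
        labels = self.labels or tuple(range(1, len(rates) + 1))
        if len(labels) != len(rates):
            raise InvalidParameterError("labels and rates must have equal length")
        if len(set(labels)) != len(labels):
            raise InvalidParameterError("labels must be unique")
        object.__setattr__(self, "labels", tuple(int(x) for x in labels))

    def __len__(self) -> int:
        return len(self.rates)

    def rate_of(self, label: int) -> float:
        try:
            return self.rates[self.labels.index(label)]
        except ValueError:
            raise InconsistencyError(f"label {label} has no assigned mutation rate")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.rates, dtype=float)


@dataclass(frozen=True)
class InitialFitnessSpec:
    """How founder fitness values are assigned.

    kinds
    -----
    ``uniform_one``
        Every founder starts at fitness 1.0 (no parameters).
    ``normal``
        params = (mean, variance).  Non-positive draws are rejected and
        redrawn, so the realized mean sits slightly above the nominal one.
    ``gamma``
        params = (shape, beta).  ``beta_is_rate`` selects whether ``beta``
        is a rate (default; mean = shape/beta) or a scale (mean =
        shape*beta).
    ``per_label``
        params = one fitness value per subpopulation label, in label order;
        used for constructed test scenarios such as a two-class selection
        experiment.
    """

    kind: str = "uniform_one"
    params: Tuple[float, ...] = ()
    beta_is_rate: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.kind == "uniform_one":
            if self.params:
                raise InvalidParameterError("uniform_one takes no parameters")
        elif self.kind == "normal":
            if len(self.params) != 2 or self.params[1] <= 0:
                raise InvalidParameterError(
                    "normal initial fitness needs params (mean, variance>0)"
                )
        elif self.kind == "gamma":
            if len(self.params) != 2 or min(self.params) <= 0:
                raise InvalidParameterError(
                    "gamma initial fitness needs positive params (shape, beta)"
                )
        elif self.kind == "per_label":
            if not self.params or any(p < 0 for p in self.params):
                raise InvalidParameterError(
                    "per_label initial fitness needs one value >= 0 per label"
                )
        else:
            raise InvalidParameterError(f"unknown initial-fitness kind {self.kind!r}")

    def sample(self, n: int, labels: np.ndarray | None, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform_one":
            return np.ones(n, dtype=float)
        if self.kind == "normal":
            mean, var = self.params
            sd = float(np.sqrt(var))
            w = rng.normal(mean, sd, size=n)
            bad = w <= 0.0
            while bad.any():
                w[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                bad = w <= 0.0
            return w
        if self.kind == "gamma":
            shape, beta = self.params
            scale = 1.0 / beta if self.beta_is_rate else beta
            return rng.gamma(shape, scale, size=n)
        # per_label: deterministic given labels
        if labels is None:
            raise InvalidParameterError("per_label initial fitness requires labels")
        values = np.asarray(self.params, dtype=float)
        label_index = np.searchsorted(np.unique(labels), labels)
        if values.size <= label_index.max():
            raise InvalidParameterError(
                "per_label initial fitness needs one value per label"
            )
        return values[label_index]


@dataclass(frozen=True)
class FertilitySpec:
    """Upper limit on offspring per individual per generation.

    ``cap=None`` means unlimited fertility (pure multinomial sampling).
    """

    cap: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cap is not None:
            if int(self.cap) != self.cap or self.cap < 1:
                raise InvalidParameterError(
                    f"fertility cap must be a positive integer or None, got {self.cap}"
                )
            object.__setattr__(self, "cap", int(self.cap))

    @classmethod
    def unlimited(cls) -> "FertilitySpec":
        return cls(cap=None)

    @property
    def is_unlimited(self) -> bool:
        return self.cap is None


@dataclass
class PopulationState:
    """Per-individual fitness and subpopulation label at one generation."""

    fitness: np.ndarray
    labels: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.fitness = np.asarray(self.fitness, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.fitness.shape != self.labels.shape or self.fitness.ndim != 1:
            raise InvalidParameterError(
                "fitness and labels must be 1-d arrays of equal length"
            )
        # non-negativity of fitness is guaranteed by construction (initial
        # fitness specs produce w >= 0 and deleterious magnitudes are <= 1),
        # so it is checked at founding rather than on every generation

    @property
    def size(self) -> int:
        return self.fitness.size

    def copy(self) -> "PopulationState":
        return PopulationState(
            fitness=self.fitness.copy(),
            labels=self.labels.copy(),
            generation=self.generation,
        )


def initialize_population(
    N: int,
    rate_set: SubpopulationRateSet,
    init_fitness: InitialFitnessSpec,
    rng: np.random.Generator,
    label_counts: Optional[Sequence[int]] = None,
) -> PopulationState:
    """Found a population of ``N`` individuals split across the labels.

    By default every subpopulation is founded with ``N / K`` individuals
    (``N`` must be divisible by ``K``); explicit ``label_counts`` override
    the even split for constructed scenarios.
    """
    K = len(rate_set)
    if label_counts is None:
        if N <= 0 or N % K != 0:
            raise InvalidParameterError(
                f"population size {N} is not divisible by the {K} subpopulations"
            )
        label_counts = [N // K] * K
    else:
        label_counts = [int(c) for c in label_counts]
        if len(label_counts) != K or any(c < 0 for c in label_counts):
            raise InvalidParameterError("label_counts needs one count >= 0 per label")
        if sum(label_counts) != N:
            raise InvalidParameterError(
                f"label_counts sum to {sum(label_counts)}, expected N={N}"
            )
    labels = np.repeat(np.asarray(rate_set.labels, dtype=np.int64), label_counts)
    fitness = init_fitness.sample(N, labels, rng)
    return PopulationState(fitness=fitness, labels=labels, generation=0)


def _group_members(labels: np.ndarray, label: int) -> np.ndarray:
    return np.flatnonzero(labels == label)


def mutate_generation(
    state: PopulationState,
    rate_set: SubpopulationRateSet,
    model: MutationModel,
    rng: np.random.Generator,
) -> PopulationState:
    """Apply one generation of mutational input to every individual.

    Labels, population size and the generation counter are unchanged; only
    fitness values move.  See the module docstring for the draw order.
    """
    labels = state.labels
    label_array = np.asarray(rate_set.labels, dtype=labels.dtype)
    # Offspring are produced in ascending parent order, so a population
    # founded in contiguous label blocks stays sorted by label forever;
    # exploit that to find each subpopulation as an index range.  The
    # general path handles arbitrarily arranged labels.
    sorted_labels = bool(
        np.all(label_array[:-1] <= label_array[1:]) and np.all(labels[:-1] <= labels[1:])
    )
    if sorted_labels:
        starts = np.searchsorted(labels, label_array, side="left")
        ends = np.searchsorted(labels, label_array, side="right")
        counts_per_label = ends - starts
    elif labels.min(initial=0) >= 0:
        bins = np.bincount(labels, minlength=int(label_array.max()) + 1)
        counts_per_label = bins[label_array]
    else:
        counts_per_label = np.array(
            [np.count_nonzero(labels == lab) for lab in rate_set.labels],
            dtype=np.int64,
        )
    if counts_per_label.sum() != labels.size:
        bad = np.unique(labels[~np.isin(labels, rate_set.labels)])
        raise InconsistencyError(f"labels {bad.tolist()} have no assigned rate")
    lam = counts_per_label * rate_set.as_array()
    totals = rng.poisson(lam)  # draw 1: total mutations per subpopulation
    m_total = int(totals.sum())
    if m_total == 0:
        return PopulationState(
            fitness=state.fitness, labels=labels, generation=state.generation
        )

    owner_chunks = []
    for k, (lab, n_k, m_k) in enumerate(zip(rate_set.labels, counts_per_label, totals)):
        if m_k == 0:
            continue
        positions = rng.integers(0, n_k, size=int(m_k))  # draw 2
        if sorted_labels:
            owner_chunks.append(starts[k] + positions)
        else:
            owner_chunks.append(_group_members(labels, lab)[positions])
    owners = np.concatenate(owner_chunks)

    beneficial = rng.random(m_total) < model.beneficial_fraction  # draw 3
    n_b = int(beneficial.sum())
    factors = np.empty(m_total, dtype=float)
    factors[beneficial] = 1.0 + draw_beneficial_magnitudes(model.beneficial, n_b, rng)
    factors[~beneficial] = 1.0 - draw_deleterious_magnitudes(
        model.deleterious, m_total - n_b, rng
    )

    fitness = state.fitness.copy()
    np.multiply.at(fitness, owners, factors)
    return PopulationState(
        fitness=fitness, labels=labels, generation=state.generation
    )


def _merge_parents_numpy(cum: np.ndarray, u: np.ndarray) -> np.ndarray:
    parents = np.searchsorted(cum, u, side="right")
    # u can round up to exactly the total; map such draws to the last
    # positive-weight parent instead of falling off the array
    if parents.max(initial=-1) >= cum.size:
        last = int(np.searchsorted(cum, np.nextafter(cum[-1], 0.0), side="right"))
        parents[parents >= cum.size] = min(last, cum.size - 1)
    return parents


def _sample_parents_python(w: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Reference arithmetic for the fused sampler (see `_sample_parents`)."""
    s = np.cumsum(e)
    cum = np.cumsum(w)
    u = s[: e.size - 1] * (cum[-1] / s[-1])
    return _merge_parents_numpy(cum, u)


try:  # an O(N) fused pass; numba only accelerates, never changes results
    from numba import njit

    @njit(cache=True)
    def _sample_parents(w, e):  # pragma: no cover - exercised via reproduce
        m = w.size
        n = e.size - 1
        tot = 0.0
        for i in range(m):
            tot += w[i]
        se = 0.0
        for j in range(n + 1):
            se += e[j]
        scale = tot / se
        parents = np.empty(n, np.int64)
        i = 0
        cum = w[0]
        sj = 0.0
        for j in range(n):
            sj += e[j]
            u = sj * scale
            while i < m and cum <= u:
                i += 1
                if i < m:
                    cum += w[i]
            # u rounded up to the total: use the last positive-weight parent
            if i == m:
                k = m - 1
                while k > 0 and w[k] == 0.0:
                    k -= 1
                parents[j] = k
                i = m - 1
                cum = tot
            else:
                parents[j] = i
        return parents

except ImportError:  # pragma: no cover
    _sample_parents = _sample_parents_python


def _pick_parents_unlimited(
    w: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` fitness-weighted parent draws, returned in ascending index order.

    Sorted uniforms on ``(0, sum w)`` are generated as normalized cumulative
    sums of ``n + 1`` standard exponentials (the classical order-statistics
    construction), then mapped through the inverse of the cumulative fitness
    distribution.  Offspring counts per parent are exactly
    multinomial(``n``, ``w_i / sum w``); only the order of the returned
    parents differs from an unsorted scheme, and offspring order carries no
    meaning.  A parent index is the smallest ``i`` with ``cum[i] > u``, so
    zero-fitness parents are never selected.
    """
    e = rng.standard_exponential(n + 1)
    return _sample_parents(w, e)


def _pick_parents_capped(
    w: np.ndarray, n: int, cap: int, rng: np.random.Generator
) -> np.ndarray:
    weights_positive = int(np.count_nonzero(w > 0))
    if cap * weights_positive < n:
        raise FertilityError(
            f"fertility cap {cap} with {weights_positive} positive-fitness parents "
            f"cannot produce {n} offspring"
        )
    accepted = np.empty(n, dtype=np.int64)
    used = np.zeros(w.size, dtype=np.int64)
    filled = 0
    while filled < n:
        candidates = _pick_parents_unlimited(w, n - filled, rng)
        # sequential acceptance within the batch: a candidate is accepted iff
        # its parent has remaining capacity counting earlier batch accepts
        order = np.argsort(candidates, kind="stable")
        occurrence = np.empty(candidates.size, dtype=np.int64)
        sorted_c = candidates[order]
        first = np.concatenate(([True], sorted_c[1:] != sorted_c[:-1]))
        idx = np.arange(candidates.size)
        occurrence[order] = idx - np.maximum.accumulate(np.where(first, idx, -1))
        keep = used[candidates] + occurrence < cap
        kept = candidates[keep]
        accepted[filled : filled + kept.size] = kept
        np.add.at(used, kept, 1)
        filled += kept.size
    return accepted


def reproduce(
    state: PopulationState,
    fertility: FertilitySpec,
    rng: np.random.Generator,
) -> PopulationState:
    """Sample ``N`` offspring weighted by parental fitness; advance one generation.

    Offspring counts follow a multinomial(``N``, ``w_i / sum w``) law under
    unlimited fertility; each offspring inherits its parent's fitness and
    subpopulation label unchanged (mutation happens in the mutation step,
    never here).
    """
    w = state.fitness
    if float(np.sum(w)) <= 0.0:
        raise ExtinctionError(
            f"total fitness is zero at generation {state.generation}; "
            "the population is extinct"
        )
    n = state.size
    if fertility.is_unlimited:
        parents = _pick_parents_unlimited(w, n, rng)
    else:
        parents = _pick_parents_capped(w, n, fertility.cap, rng)
    return PopulationState(
        fitness=w[parents],
        labels=state.labels[parents],
        generation=state.generation + 1,
    )


def check_fixation(state: PopulationState) -> Optional[int]:
    """Return the fixed label if every individual carries it, else ``None``."""
    labels = state.labels
    first = labels[0]
    if labels[-1] != first:  # cheap reject; labels are typically grouped
        return None
    if (labels == first).all():
        return int(first)
    return None
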
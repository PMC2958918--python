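"""Initialization, mutation, reproduction and fixation detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mutrace.effects import resolve_model, truncated_gamma_mean
from mutrace.errors import (
    ExtinctionError,
    FertilityError,
    InconsistencyError,
    InvalidParameterError,
)
from mutrace.population import (
    FertilitySpec,
    InitialFitnessSpec,
    PopulationState,
    SubpopulationRateSet,
    check_fixation,
    initialize_population,
    mutate_generation,
    reproduce,
)


def _two_rate_set():
    return SubpopulationRateSet(rates=(0.0, 0.0), labels=(1, 2))


class TestRateSet:
    def test_table_order_enforced(self):
        with pytest.raises(InvalidParameterError):
            SubpopulationRateSet(rates=(0.01, 0.001, 0.1))
        with pytest.raises(InvalidParameterError):
            SubpopulationRateSet(rates=(0.01,))
        with pytest.raises(InvalidParameterError):
            SubpopulationRateSet(rates=(-0.1, 0.01))

    def test_rate_lookup(self):
        rs = SubpopulationRateSet(rates=(0.001, 0.01), labels=(3, 9))
        assert rs.rate_of(9) == 0.01
        with pytest.raises(InconsistencyError):
            rs.rate_of(1)


class TestInitialize:
    def test_even_split_uniform_fitness(self, ru1, rng):
        state = initialize_population(20, ru1, InitialFitnessSpec(), rng)
        assert state.generation == 0
        assert (state.fitness == 1.0).all()
        counts = np.bincount(state.labels)[1:]
        assert counts.tolist() == [2] * 10

    def test_indivisible_size_rejected(self, ru1, rng):
        with pytest.raises(InvalidParameterError):
            initialize_population(15, ru1, InitialFitnessSpec(), rng)

    def test_normal_founders_positive_with_truncation_shift(self, ru1, rng):
        # rejection of non-positive draws shifts the mean above the nominal 0.5;
        # scipy's truncated normal supplies the expected value
        spec = InitialFitnessSpec(kind="normal", params=(0.5, 0.1))
        state = initialize_population(20000, ru1, spec, rng)
        assert (state.fitness > 0).all()
        sd = math.sqrt(0.1)
        expected = stats.truncnorm(-0.5 / sd, np.inf, loc=0.5, scale=sd).mean()
        assert state.fitness.mean() == pytest.approx(expected, abs=4 * sd / math.sqrt(20000))

    @pytest.mark.parametrize("beta_is_rate, mean", [(True, 1.0), (False, 400.0)])
    def test_gamma_founder_conventions(self, ru1, rng, beta_is_rate, mean):
        spec = InitialFitnessSpec(kind="gamma", params=(20.0, 20.0), beta_is_rate=beta_is_rate)
        state = initialize_population(20000, ru1, spec, rng)
        assert state.fitness.mean() == pytest.approx(mean, rel=0.05)

    def test_custom_label_counts(self, rng):
        state = initialize_population(
            10, _two_rate_set(), InitialFitnessSpec(), rng, label_counts=(9, 1)
        )
        assert (state.labels == 2).sum() == 1


class TestMutate:
    def test_zero_rates_leave_fitness_unchanged(self, baseline_model, rng):
        rs = SubpopulationRateSet(rates=(0.0,) * 10)
        state = initialize_population(100, rs, InitialFitnessSpec(), rng)
        out = mutate_generation(state, rs, baseline_model, rng)
        assert np.array_equal(out.fitness, state.fitness)
        assert out.generation == state.generation

    def test_unknown_label_inconsistency(self, baseline_model, rng):
        rs = _two_rate_set()
        state = PopulationState(fitness=np.ones(4), labels=np.array([1, 2, 2, 7]))
        with pytest.raises(InconsistencyError):
            mutate_generation(state, rs, baseline_model, rng)

    def test_mean_fitness_loss_matches_independent_oracle(self, rng):
        # one generation of deleterious-only mutation at U = 0.02, replicated
        # over many individuals; oracle: brute-force Monte Carlo with scipy
        # samplers, plus the closed form E[w] = exp(-U * E[s_trunc])
        n = 2 * 10**5
        u, shape, scale = 0.02, 0.6, 0.5
        model = resolve_model(0.0, 0.01, shape, 0.3)
        rs = SubpopulationRateSet(rates=(u, u), labels=(1, 2))
        state = initialize_population(n, rs, InitialFitnessSpec(), rng)
        out = mutate_generation(state, rs, model, rng)

        oracle_rng = np.random.default_rng(987)
        m = oracle_rng.poisson(u, size=n)
        w = np.ones(n)
        total = int(m.sum())
        s = oracle_rng.gamma(shape, scale, size=total)
        while (s > 1).any():
            s[s > 1] = oracle_rng.gamma(shape, scale, size=int((s > 1).sum()))
        np.multiply.at(w, np.repeat(np.arange(n), m), 1.0 - s)

        closed_form = math.exp(-u * truncated_gamma_mean(shape, scale))
        se = w.std() / math.sqrt(n)
        assert w.mean() == pytest.approx(closed_form, abs=4 * se)
        assert out.fitness.mean() == pytest.approx(closed_form, abs=4 * se)

    def test_beneficial_only_never_decreases_fitness(self, rng):
        model = resolve_model(1.0, 0.01, 0.6, 0.3)
        rs = SubpopulationRateSet(rates=(0.5, 1.0), labels=(1, 2))
        state = initialize_population(200, rs, InitialFitnessSpec(), rng)
        out = mutate_generation(state, rs, model, rng)
        assert (out.fitness >= state.fitness).all()

    def test_labels_and_size_preserved(self, baseline_model, ru1, rng):
        state = initialize_population(100, ru1, InitialFitnessSpec(), rng)
        out = mutate_generation(state, ru1, baseline_model, rng)
        assert out.size == 100
        assert np.array_equal(out.labels, state.labels)


class TestReproduce:
    def test_equal_fitness_offspring_counts_are_uniform_multinomial(self, rng):
        n = 10**5
        # label each parent uniquely so offspring labels identify parents
        state = PopulationState(fitness=np.ones(n), labels=np.arange(n))
        out = reproduce(state, FertilitySpec(), rng)
        assert out.size == n and out.generation == 1
        counts = np.bincount(out.labels, minlength=n)
        assert counts.sum() == n
        chi = stats.chisquare(counts)
        assert chi.pvalue > 0.01

    def test_zero_fitness_parent_leaves_no_offspring(self, rng):
        fitness = np.ones(50)
        fitness[7] = 0.0
        state = PopulationState(fitness=fitness, labels=np.arange(50))
        for _ in range(50):
            out = reproduce(state, FertilitySpec(), rng)
            assert (out.labels != 7).all()

    def test_fitter_class_expected_offspring_fraction(self, rng):
        # w = 1 and w = 3 at equal numbers: expected fraction of the fitter
        # class is 3/4
        n, reps = 100, 10**4
        fitness = np.concatenate([np.ones(n // 2), np.full(n // 2, 3.0)])
        labels = np.concatenate([np.ones(n // 2, dtype=int), np.full(n // 2, 2)])
        state = PopulationState(fitness=fitness, labels=labels)
        frac = np.mean(
            [(reproduce(state, FertilitySpec(), rng).labels == 2).mean() for _ in range(reps)]
        )
        se = math.sqrt(0.75 * 0.25 / (n * reps))
        assert frac == pytest.approx(0.75, abs=4 * se)

    def test_cap_one_returns_each_parent_exactly_once(self, rng):
        n = 50
        state = PopulationState(
            fitness=rng.random(n) + 0.1, labels=np.arange(n)
        )
        out = reproduce(state, FertilitySpec(cap=1), rng)
        assert sorted(out.labels.tolist()) == list(range(n))

    def test_cap_respected(self, rng):
        n = 60
        state = PopulationState(fitness=rng.random(n) + 0.1, labels=np.arange(n))
        for cap in (2, 5):
            out = reproduce(state, FertilitySpec(cap=cap), rng)
            assert np.bincount(out.labels, minlength=n).max() <= cap

    def test_infeasible_cap_raises(self, rng):
        fitness = np.ones(10)
        fitness[:5] = 0.0
        state = PopulationState(fitness=fitness, labels=np.arange(10))
        with pytest.raises(FertilityError):
            reproduce(state, FertilitySpec(cap=1), rng)

    def test_total_fitness_zero_is_extinction(self, rng):
        state = PopulationState(fitness=np.zeros(10), labels=np.arange(10))
        with pytest.raises(ExtinctionError):
            reproduce(state, FertilitySpec(), rng)


class TestFixation:
    def test_unanimous_label(self):
        state = PopulationState(fitness=np.ones(5), labels=np.full(5, 7))
        assert check_fixation(state) == 7

    def test_one_dissenter(self):
        state = PopulationState(fitness=np.ones(5), labels=np.array([1, 1, 1, 1, 2]))
        assert check_fixation(state) is None

    def test_single_individual(self):
        state = PopulationState(fitness=np.ones(1), labels=np.array([3]))
        assert check_fixation(state) == 3


@given(seed=st.integers(0, 10**6))
@settings(max_examples=20, deadline=None)
def test_population_size_conserved_through_cycle(seed):
    rng = np.random.default_rng(seed)
    rs = SubpopulationRateSet(rates=(0.01, 0.1), labels=(1, 2))
    model = resolve_model(0.1, 0.01, 0.6, 0.3)
    state = initialize_population(30, rs, InitialFitnessSpec(), rng)
    mutated = mutate_generation(state, rs, model, rng)
    assert mutated.size == 30
    assert np.array_equal(mutated.labels, state.labels)  # mutation never relabels
    offspring = reproduce(mutated, FertilitySpec(), rng)
    assert offspring.size == 30
    assert offspring.generation == state.generation + 1
    assert set(np.unique(offspring.labels)) <= {1, 2}
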
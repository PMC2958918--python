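"""Distribution moments, the fitness update, and model construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from mutrace.effects import (
    BeneficialEffectSpec,
    DeleteriousEffectSpec,
    MutationModel,
    SignedEffect,
    apply_mutations,
    draw_effect,
    draw_beneficial_magnitudes,
    draw_deleterious_magnitudes,
    draw_mutation_count,
    resolve_model,
    truncated_gamma_mean,
)
from mutrace.errors import InvalidParameterError

N_DRAWS = 10**6


def _truncated_mean_quadrature(shape, scale, bound=1.0):
    """Independent oracle: mean of the conditioned gamma by numeric integration."""
    pdf = stats.gamma(shape, scale=scale).pdf
    num, _ = integrate.quad(lambda x: x * pdf(x), 0, bound)
    den, _ = integrate.quad(pdf, 0, bound)
    return num / den


class TestMutationCounts:
    def test_zero_rate_is_always_zero(self, rng):
        assert all(draw_mutation_count(0.0, rng) == 0 for _ in range(100))

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            draw_mutation_count(-0.1, rng)

    def test_zero_fraction_matches_poisson_pmf(self, rng):
        # P(m = 0) = e^{-U} for U = 0.1
        u = 0.1
        draws = rng.poisson(u, size=N_DRAWS)
        p0 = math.exp(-u)
        se = math.sqrt(p0 * (1 - p0) / N_DRAWS)
        assert abs(np.mean(draws == 0) - p0) < 3 * se

    def test_sample_mean_matches_rate(self, rng):
        u = 0.01
        draws = rng.poisson(u, size=N_DRAWS)
        assert abs(draws.mean() - u) < 3 * math.sqrt(u / N_DRAWS)


class TestEffectDraws:
    def test_all_deleterious_when_pb_zero(self, rng):
        model = resolve_model(0.0, 0.01, 0.6, 0.3)
        effects = [draw_effect(model, rng) for _ in range(200)]
        assert all(not e.beneficial for e in effects)
        assert all(0 < e.magnitude <= 1 for e in effects)

    def test_beneficial_mean_is_inverse_lambda(self, rng):
        # lambda = 100 gives mean s_b = 0.01
        spec = BeneficialEffectSpec(rate_parameter=100.0)
        s = draw_beneficial_magnitudes(spec, N_DRAWS, rng)
        se = spec.mean_effect / math.sqrt(N_DRAWS)  # exponential sd = mean
        assert abs(s.mean() - 0.01) < 3 * se

    def test_truncated_gamma_mean_matches_quadrature_oracle(self, rng):
        spec = DeleteriousEffectSpec(shape=0.6, scale=0.5)
        expected = _truncated_mean_quadrature(0.6, 0.5)
        assert expected < 0.3  # truncation pulls the nominal mean 0.3 down
        s = draw_deleterious_magnitudes(spec, N_DRAWS, rng)
        assert s.max() <= 1.0 and s.min() > 0.0
        assert abs(s.mean() - expected) < 4 * s.std() / math.sqrt(N_DRAWS)
        # closed-form helper agrees with the quadrature oracle
        assert truncated_gamma_mean(0.6, 0.5) == pytest.approx(expected, rel=1e-8)

    def test_clamp_mode_places_atom_at_one(self, rng):
        spec = DeleteriousEffectSpec(shape=0.6, scale=0.5, truncation="clamp")
        s = draw_deleterious_magnitudes(spec, 10**5, rng)
        p_above = stats.gamma(0.6, scale=0.5).sf(1.0)
        frac_at_one = np.mean(s == 1.0)
        se = math.sqrt(p_above * (1 - p_above) / 10**5)
        assert abs(frac_at_one - p_above) < 4 * se


class TestApplyMutations:
    def test_empty_product_is_identity(self):
        assert apply_mutations(1.0, []) == 1.0

    def test_vsv_means_product(self):
        # beneficial 0.042 and deleterious 0.24: 1 * 1.042 * 0.76
        effects = [
            SignedEffect(0.042, beneficial=True),
            SignedEffect(0.24, beneficial=False),
        ]
        assert apply_mutations(1.0, effects) == pytest.approx(0.79192)

    def test_lethal_mutation_zeroes_fitness(self):
        assert apply_mutations(0.5, [SignedEffect(1.0, beneficial=False)]) == 0.0

    def test_deleterious_magnitude_above_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            SignedEffect(1.2, beneficial=False)

    @given(
        w=st.floats(0.01, 10.0),
        mags=st.lists(st.floats(0.001, 0.999), min_size=0, max_size=8),
        flags=st.lists(st.booleans(), min_size=8, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_order_independent_and_composable(self, w, mags, flags):
        effects = [SignedEffect(m, beneficial=b) for m, b in zip(mags, flags)]
        forward = apply_mutations(w, effects)
        backward = apply_mutations(w, effects[::-1])
        assert forward == pytest.approx(backward, rel=1e-12)
        split = len(effects) // 2
        chained = apply_mutations(apply_mutations(w, effects[:split]), effects[split:])
        assert chained == pytest.approx(forward, rel=1e-12)
        assert forward >= 0.0


class TestResolveModel:
    @pytest.mark.parametrize(
        "args, lam, beta",
        [
            ((0.03, 0.01, 0.6, 0.3), 100.0, 0.5),
            ((0.03, 0.02, 0.6, 0.3), 50.0, 0.5),
            ((0.0, 0.01, 1.0, 0.3), 100.0, 0.3),
        ],
    )
    def test_mean_identities(self, args, lam, beta):
        model = resolve_model(*args)
        assert model.beneficial.rate_parameter == pytest.approx(lam)
        assert model.deleterious.scale == pytest.approx(beta)
        assert model.beneficial.mean_effect * model.beneficial.rate_parameter == pytest.approx(1.0)
        assert model.deleterious.mean_effect == pytest.approx(args[3])

    @pytest.mark.parametrize(
        "args",
        [
            (0.03, 0.0, 0.6, 0.3),
            (0.03, -0.01, 0.6, 0.3),
            (0.03, 0.01, 0.6, 0.0),
            (0.03, 0.01, -1.0, 0.3),
            (1.5, 0.01, 0.6, 0.3),
        ],
    )
    def test_invalid_parameters_rejected(self, args):
        with pytest.raises(InvalidParameterError):
            resolve_model(*args)

    def test_fraction_invariant(self):
        model = resolve_model(0.25, 0.01, 0.6, 0.3)
        assert model.beneficial_fraction + model.deleterious_fraction == 1.0
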
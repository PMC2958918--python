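"""Mutation-effect distributions and the multiplicative fitness update.

The model of mutational input is a two-component mixture: a new mutation is
beneficial with probability ``p_b`` and deleterious with probability
``1 - p_b``.  Beneficial selection coefficients ``s_b`` are exponential with
rate ``lambda`` (mean ``1/lambda``); deleterious coefficients ``s_d`` follow a
gamma distribution with shape ``alpha`` and scale ``beta``, truncated at 1.0
so that the fitness factor ``1 - s_d`` can never become negative.  Mutations
act multiplicatively and independently on fitness (no epistasis):

    w_n = w_{n-1} * prod_j (1 + s_j)   (beneficial j)
                  * prod_j (1 - s_j)   (deleterious j)

The number of new mutations per individual per generation is Poisson with
mean equal to that individual's genome mutation rate ``U``.

Truncation of the deleterious gamma is implemented by *rejection* (redraw
until the value is <= 1), i.e. the conditional distribution given
``s_d <= 1``.  A ``clamp`` mode (mass at exactly 1.0, a lethal mutation) is
available for sensitivity checks.  For parameter values of practical
interest the truncated mean is only slightly below the nominal
``alpha * beta``; :func:`truncated_gamma_mean` computes it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import special

from .errors import InvalidParameterError

__all__ = [
    "BeneficialEffectSpec",
    "DeleteriousEffectSpec",
    "MutationModel",
    "SignedEffect",
    "draw_mutation_count",
    "draw_effect",
    "apply_mutations",
    "resolve_model",
    "truncated_gamma_mean",
]

TruncationMode = Literal["reject", "clamp"]


@dataclass(frozen=True)
class BeneficialEffectSpec:
    """Exponential distribution of beneficial selection coefficients.

    Parameters
    ----------
    rate_parameter
        The exponential rate ``lambda`` (per unit effect).  The mean
        beneficial effect is ``1 / lambda``.
    """

    rate_parameter: float

    def __post_init__(self) -> None:
        if not self.rate_parameter > 0:
            raise InvalidParameterError(
                f"beneficial rate parameter must be > 0, got {self.rate_parameter}"
            )

    @property
    def mean_effect(self) -> float:
        """Mean beneficial selection coefficient, ``1 / lambda``."""
        return 1.0 / self.rate_parameter

    @classmethod
    def from_mean(cls, mean_effect: float) -> "BeneficialEffectSpec":
        if not mean_effect > 0:
            raise InvalidParameterError(
                f"mean beneficial effect must be > 0, got {mean_effect}"
            )
        return cls(rate_parameter=1.0 / mean_effect)


@dataclass(frozen=True)
class DeleteriousEffectSpec:
    """Gamma distribution of deleterious selection coefficients, truncated at 1.

    Parameters
    ----------
    shape
        Gamma shape ``alpha``.  Empirical fitness-effect distributions are
        strongly skewed, which corresponds to ``alpha <= 1``; larger values
        are accepted.
    scale
        Gamma scale ``beta``.  The untruncated mean effect is
        ``alpha * beta``.
    truncation
        ``"reject"`` (default) redraws values above 1 so the effect follows
        the conditional distribution given ``s_d <= 1``; ``"clamp"`` maps
        them to exactly 1 (a lethal mutation).
    """

    shape: float
    scale: float
    truncation: TruncationMode = "reject"
    truncation_bound: float = field(default=1.0, init=False)

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise InvalidParameterError(f"gamma shape must be > 0, got {self.shape}")
        if not self.scale > 0:
            raise InvalidParameterError(f"gamma scale must be > 0, got {self.scale}")
        if self.truncation not in ("reject", "clamp"):
            raise InvalidParameterError(
                f"truncation must be 'reject' or 'clamp', got {self.truncation!r}"
            )

    @property
    def mean_effect(self) -> float:
        """Nominal (untruncated) mean deleterious effect ``alpha * beta``."""
        return self.shape * self.scale

    @property
    def truncated_mean(self) -> float:
        """Exact mean of the rejection-truncated distribution on (0, 1]."""
        return truncated_gamma_mean(self.shape, self.scale, self.truncation_bound)


def truncated_gamma_mean(shape: float, scale: float, bound: float = 1.0) -> float:
    """Mean of a Gamma(shape, scale) variate conditioned on being <= ``bound``.

    Uses the identity ``E[X; X <= c] = shape * scale * P(shape + 1, c / scale)``
    where ``P`` is the regularized lower incomplete gamma function.
    """
    x = bound / scale
    num = shape * scale * special.gammainc(shape + 1.0, x)
    den = special.gammainc(shape, x)
    return num / den


@dataclass(frozen=True)
class MutationModel:
    """Mixture model for the fitness effect of a single new mutation."""

    beneficial_fraction: float
    beneficial: BeneficialEffectSpec
    deleterious: DeleteriousEffectSpec

    def __post_init__(self) -> None:
        if not 0.0 <= self.beneficial_fraction <= 1.0:
            raise InvalidParameterError(
                f"beneficial fraction must lie in [0, 1], got {self.beneficial_fraction}"
            )

    @property
    def deleterious_fraction(self) -> float:
        """Probability that a new mutation is deleterious (``1 - p_b``)."""
        return 1.0 - self.beneficial_fraction


@dataclass(frozen=True)
class SignedEffect:
    """A single mutation's selection coefficient with its direction."""

    magnitude: float
    beneficial: bool

    def __post_init__(self) -> None:
        if not self.magnitude > 0:
            raise InvalidParameterError(
                f"effect magnitude must be > 0, got {self.magnitude}"
            )
        if not self.beneficial and self.magnitude > 1.0:
            raise InvalidParameterError(
                f"deleterious magnitude must be <= 1, got {self.magnitude}"
            )

    @property
    def direction(self) -> str:
        return "beneficial" if self.beneficial else "deleterious"

    @property
    def fitness_factor(self) -> float:
        """Multiplicative factor applied to fitness: ``1 + s`` or ``1 - s``."""
        return 1.0 + self.magnitude if self.beneficial else 1.0 - self.magnitude


def draw_mutation_count(genome_rate: float, rng: np.random.Generator) -> int:
    """Number of new mutations in one individual: a Poisson(``genome_rate``) draw."""
    if genome_rate < 0:
        raise InvalidParameterError(f"genome mutation rate must be >= 0, got {genome_rate}")
    return int(rng.poisson(genome_rate))


def draw_beneficial_magnitudes(
    spec: BeneficialEffectSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` beneficial selection coefficients (exponential, mean 1/lambda)."""
    return rng.exponential(scale=spec.mean_effect, size=n)


def draw_deleterious_magnitudes(
    spec: DeleteriousEffectSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` deleterious selection coefficients from the truncated gamma.

    Rejection proceeds in rounds: an initial vector of ``n`` gamma draws,
    then repeated redraws of the positions still above the bound, each round
    consuming one vectorized draw of the pending size.  This round structure
    is part of the reproducibility contract (the naive reference engine
    replays the identical stream with scalar draws).
    """
    values = rng.gamma(spec.shape, spec.scale, size=n)
    if spec.truncation == "clamp":
        return np.minimum(values, spec.truncation_bound)
    bad = values > spec.truncation_bound
    while bad.any():
        values[bad] = rng.gamma(spec.shape, spec.scale, size=int(bad.sum()))
        bad = values > spec.truncation_bound
    return values


def draw_effect(model: MutationModel, rng: np.random.Generator) -> SignedEffect:
    """Draw one mutation effect: direction first, then its magnitude."""
    beneficial = rng.random() < model.beneficial_fraction
    if beneficial:
        magnitude = float(draw_beneficial_magnitudes(model.beneficial, 1, rng)[0])
    else:
        magnitude = float(draw_deleterious_magnitudes(model.deleterious, 1, rng)[0])
    return SignedEffect(magnitude=magnitude, beneficial=beneficial)


def apply_mutations(parent_fitness: float, effects: Iterable[SignedEffect]) -> float:
    """Update fitness multiplicatively: ``w * prod (1 + s_b) * prod (1 - s_d)``."""
    if parent_fitness < 0:
        raise InvalidParameterError(
            f"fitness must be >= 0, got {parent_fitness}"
        )
    w = float(parent_fitness)
    for effect in effects:
        if not effect.beneficial and effect.magnitude > 1.0:
            raise InvalidParameterError(
                f"deleterious magnitude {effect.magnitude} exceeds 1"
            )
        w *= effect.fitness_factor
    return w


def resolve_model(
    p_b: float,
    mean_beneficial: float,
    shape: float,
    mean_deleterious: float,
    truncation: TruncationMode = "reject",
) -> MutationModel:
    """Build a :class:`MutationModel` from reported mean effects.

    Maps the mean beneficial effect to the exponential rate
    ``lambda = 1 / mean_beneficial`` and the mean deleterious effect to the
    gamma scale ``beta = mean_deleterious / shape``, so the nominal means of
    the returned model match the arguments exactly.
    """
    if not 0.0 <= p_b <= 1.0:
        raise InvalidParameterError(f"p_b must lie in [0, 1], got {p_b}")
    if not mean_beneficial > 0:
        raise InvalidParameterError(
            f"mean beneficial effect must be > 0, got {mean_beneficial}"
        )
    if not mean_deleterious > 0:
        raise InvalidParameterError(
            f"mean deleterious effect must be > 0, got {mean_deleterious}"
        )
    if not shape > 0:
        raise InvalidParameterError(f"gamma shape must be > 0, got {shape}")
    return MutationModel(
        beneficial_fraction=p_b,
        beneficial=BeneficialEffectSpec.from_mean(mean_beneficial),
        deleterious=DeleteriousEffectSpec(
            shape=shape, scale=mean_deleterious / shape, truncation=truncation
        ),
    )
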
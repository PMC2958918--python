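"""Replicate competitions and estimation of the optimum mutation rate.

An *experiment* repeats one competition configuration over many independent
replicates (seeded deterministically from a master seed), tabulates which
mutation rate fixed in each, and reports

* the frequency of fixation of every rate,
* the optimum mutation rate ``U_opt`` — the mode of the fixed-rate
  distribution, and
* ``G`` — the mean number of generations a competition took, averaged over
  the replicates that reached fixation.

Named presets reproduce the published simulation scenarios (population-size
sweep, beneficial-fraction sweep, DFE-parameter sweeps, beneficial-effect
sweep, rate-range / initial-fitness / fertility robustness checks) at their
original parameter values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .competition import CompetitionConfig, CompetitionResult, run_competition
from .effects import resolve_model
from .errors import InvalidParameterError
from .population import FertilitySpec, InitialFitnessSpec, SubpopulationRateSet

__all__ = [
    "RU_SETS",
    "ExperimentConfig",
    "ExperimentResult",
    "FixationSummary",
    "replicate_seed",
    "run_experiment",
    "summarize",
    "preset",
    "available_presets",
]

logger = logging.getLogger(__name__)

#: The five initial mutation-rate ranges assigned to the ten subpopulations.
#: lg(U) is roughly uniform on [-4, -1] for R_u = 1..3; R_u = 4 and 5 shift
#: or stretch the range to probe its influence.
RU_SETS: Dict[str, Tuple[float, ...]] = {
    "Ru1": (0.0001, 0.0003, 0.001, 0.003, 0.01, 0.02, 0.03, 0.04, 0.06, 0.1),
    "Ru2": (0.0001, 0.0003, 0.001, 0.002, 0.004, 0.006, 0.01, 0.02, 0.05, 0.1),
    "Ru3": (0.0001, 0.0002, 0.0005, 0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1),
    "Ru4": (0.0002, 0.0005, 0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2),
    "Ru5": (0.00005, 0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0),
}


def rate_set(name: str = "Ru1") -> SubpopulationRateSet:
    """The named ten-rate set (``"Ru1"`` .. ``"Ru5"``)."""
    try:
        return SubpopulationRateSet(rates=RU_SETS[name])
    except KeyError:
        raise InvalidParameterError(
            f"unknown rate set {name!r}; choose from {sorted(RU_SETS)}"
        )


@dataclass(frozen=True)
class ExperimentConfig:
    """A competition configuration replicated ``n_competitions`` times."""

    base: CompetitionConfig
    n_competitions: int = 300
    master_seed: int = 0
    preset_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_competitions < 1:
            raise InvalidParameterError(
                f"n_competitions must be >= 1, got {self.n_competitions}"
            )


@dataclass(frozen=True)
class FixationSummary:
    """Aggregate of an experiment's replicate outcomes."""

    frequency: Dict[float, float]
    optimum_rate: float
    mean_generations: float
    n_fixed: int
    n_censored: int
    n_extinct: int

    @property
    def n_competitions(self) -> int:
        return self.n_fixed + self.n_censored + self.n_extinct


@dataclass(frozen=True)
class ExperimentResult:
    summary: FixationSummary
    records: pd.DataFrame


def replicate_seed(master_seed: int, index: int) -> int:
    """Deterministic per-replicate seed: 31 bits of SeedSequence(master, spawn_key=(index,)).

    Counter-based, so replicates can be computed in any order or in parallel
    without changing any outcome.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def summarize(
    results: Sequence[CompetitionResult], rate_set: SubpopulationRateSet
) -> FixationSummary:
    """Mode and mean over the fixed replicates of an experiment.

    ``optimum_rate`` is the most frequently fixed rate; ties are broken
    toward the smallest rate (the full frequency table is always reported,
    so the tie-break hides nothing).  ``mean_generations`` averages over
    fixed replicates only; censored and extinct replicates are counted but
    excluded.
    """
    fixed = [r for r in results if r.status == "fixed"]
    n_censored = sum(1 for r in results if r.status == "censored")
    n_extinct = sum(1 for r in results if r.status == "extinct")
    if not fixed:
        raise InvalidParameterError(
            "no replicate reached fixation; nothing to summarize"
        )
    if n_censored:
        logger.warning(
            "%d replicate(s) censored at the generation safeguard; "
            "excluded from U_opt and G",
            n_censored,
        )
    counts: Dict[float, int] = {rate: 0 for rate in rate_set.rates}
    for r in fixed:
        counts[r.fixed_rate] = counts.get(r.fixed_rate, 0) + 1
    n_fixed = len(fixed)
    frequency = {rate: c / n_fixed for rate, c in counts.items()}
    best = max(counts.values())
    optimum = min(rate for rate, c in counts.items() if c == best)
    mean_g = float(np.mean([r.generations for r in fixed]))
    return FixationSummary(
        frequency=frequency,
        optimum_rate=optimum,
        mean_generations=mean_g,
        n_fixed=n_fixed,
        n_censored=n_censored,
        n_extinct=n_extinct,
    )


def run_experiment(config: ExperimentConfig, progress: bool = False) -> ExperimentResult:
    """Run all replicates and aggregate them.

    Replicate ``i`` runs the base competition with seed
    ``replicate_seed(master_seed, i)``; the base config's own ``seed`` field
    is ignored.
    """
    results: List[CompetitionResult] = []
    rows = []
    for i in range(config.n_competitions):
        seed = replicate_seed(config.master_seed, i)
        result = run_competition(replace(config.base, seed=seed))
        results.append(result)
        rows.append(
            {
                "replicate_id": i,
                "seed": seed,
                "fixed_rate": result.fixed_rate,
                "fixed_label": result.fixed_label,
                "generations": result.generations,
                "status": result.status,
            }
        )
        if progress and (i + 1) % 10 == 0:
            logger.info("replicate %d/%d done", i + 1, config.n_competitions)
    summary = summarize(results, config.base.rate_set)
    return ExperimentResult(summary=summary, records=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Preset registry
# ---------------------------------------------------------------------------

_BASELINE = dict(p_b=0.03, mean_beneficial=0.01, shape=0.6, mean_deleterious=0.3)


def _config(
    N: int,
    ru: str = "Ru1",
    p_b: float = 0.03,
    mean_beneficial: float = 0.01,
    shape: float = 0.6,
    scale: Optional[float] = None,
    mean_deleterious: float = 0.3,
    init: Optional[InitialFitnessSpec] = None,
    cap: Optional[int] = None,
    n: int = 300,
) -> ExperimentConfig:
    if scale is not None:
        mean_deleterious = shape * scale
    base = CompetitionConfig(
        population_size=N,
        rate_set=rate_set(ru),
        model=resolve_model(p_b, mean_beneficial, shape, mean_deleterious),
        init_fitness=init or InitialFitnessSpec(),
        fertility=FertilitySpec(cap=cap),
    )
    return ExperimentConfig(base=base, n_competitions=n)


def _build_presets() -> Dict[str, ExperimentConfig]:
    p: Dict[str, ExperimentConfig] = {}
    # population-size sweep (rate range Ru1; p_b = 3%, mean s_d 0.3, mean s_b 0.01)
    for exp in (4, 5, 6, 7):
        p[f"fig2_N1e{exp}"] = _config(N=10**exp)
    # beneficial-fraction sweep at N = 1e5
    for pb in (1, 3, 5, 10):
        p[f"fig3_pb{pb}"] = _config(N=10**5, p_b=pb / 100)
    # gamma scale-parameter sweep (null result expected)
    for tag, scale in (("1_3", 1 / 3), ("1_2", 0.5), ("1", 1.0)):
        p[f"fig4a_beta{tag}"] = _config(N=10**5, p_b=0.05, shape=0.6, scale=scale)
        p[f"fig4b_beta{tag}"] = _config(N=10**5, p_b=0.01, shape=0.3, scale=scale)
    # gamma shape-parameter sweep (null result expected)
    for tag, alpha in (("03", 0.3), ("06", 0.6)):
        p[f"fig5a_alpha{tag}"] = _config(N=10**5, p_b=0.01, shape=alpha, scale=0.5)
        p[f"fig5b_alpha{tag}"] = _config(N=10**5, p_b=0.01, shape=alpha, scale=1 / 3)
    # beneficial-effect sweep at the shifted rate range Ru4
    for sb in (0.005, 0.01, 0.02, 0.03):
        p[f"fig6_sb{sb}"] = _config(N=10**5, ru="Ru4", mean_beneficial=sb)
    # robustness to the initial rate range
    for ru in RU_SETS:
        p[f"fig7_{ru}"] = _config(N=10**5, ru=ru)
    # robustness to rugged founder fitness
    p["fig8_uniform"] = _config(N=10**5)
    p["fig8_normal"] = _config(
        N=10**5, init=InitialFitnessSpec(kind="normal", params=(0.5, 0.1))
    )
    p["fig8_gamma"] = _config(
        N=10**5, init=InitialFitnessSpec(kind="gamma", params=(20.0, 20.0))
    )
    # robustness to fertility limitation
    p["fig9_unlimited"] = _config(N=10**5)
    for cap in (2, 4):
        p[f"fig9_cap{cap}"] = _config(N=10**5, cap=cap)
    # empirical DFE of vesicular stomatitis virus (Table of microbial
    # estimates): p_d = 29.2%, mean s_d = 0.24, p_b = 4.2%, mean s_b = 0.042.
    # The model has no neutral class, so the beneficial fraction is taken
    # conditional on a mutation being non-neutral: 4.2 / (4.2 + 29.2).
    p["table1_VSV"] = _config(
        N=10**5,
        p_b=4.2 / (4.2 + 29.2),
        mean_beneficial=0.042,
        mean_deleterious=0.24,
    )
    return p


_PRESETS = _build_presets()


def available_presets() -> List[str]:
    """Names of all registered scenario presets."""
    return sorted(_PRESETS)


def preset(name: str) -> ExperimentConfig:
    """A fully populated experiment configuration for a named scenario."""
    try:
        cfg = _PRESETS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown preset {name!r}; see available_presets()"
        )
    return replace(cfg, preset_name=name)
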
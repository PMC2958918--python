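"""Configuration files, result files and run manifests.

Configuration is plain TOML with the sections ``population``, ``rates``,
``dfe``, ``init_fitness``, ``fertility`` and ``experiment`` plus an optional
top-level ``preset`` key; a named preset provides defaults and any section
given alongside it overrides the preset field-wise.  Unknown keys are
errors — a misspelled key never silently falls back to a default.

Mutation rates are carried through all file formats as exact decimal
strings (``"0.0003"``, never ``"0.00029999..."``); Python's shortest-repr
float formatting guarantees the round trip is lossless.

A run emits three files: ``replicates.csv`` (one row per competition),
``summary.json`` (frequency table, U_opt, G, counts, config echo) and
``manifest.json`` (config echo + provenance), from which the run can be
re-executed bit-identically.
"""

from __future__ import annotations

import datetime
import json
import os
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._version import __version__
from .competition import CompetitionConfig
from .effects import (
    BeneficialEffectSpec,
    DeleteriousEffectSpec,
    MutationModel,
)
from .errors import ConfigError, InvalidParameterError
from .experiment import (
    ExperimentConfig,
    ExperimentResult,
    FixationSummary,
    preset,
    rate_set,
    run_experiment,
)
from .population import FertilitySpec, InitialFitnessSpec, SubpopulationRateSet

__all__ = [
    "RunManifest",
    "parse_config",
    "config_to_dict",
    "config_from_dict",
    "write_outputs",
    "rerun_manifest",
    "generate_fixture",
    "rate_key",
]


def rate_key(rate: float) -> str:
    """Exact decimal string for a mutation rate (``5e-05`` -> ``"0.00005"``)."""
    return np.format_float_positional(float(rate), trim="-")


@dataclass(frozen=True)
class RunManifest:
    """Provenance record sufficient to reproduce a run exactly."""

    config: Dict[str, Any]
    version: str
    master_seed: int
    created: str
    replicates_path: str
    summary_path: str


# ---------------------------------------------------------------------------
# config <-> dict
# ---------------------------------------------------------------------------

_SECTIONS = ("population", "rates", "dfe", "init_fitness", "fertility", "experiment")


def config_to_dict(config: ExperimentConfig) -> Dict[str, Any]:
    """Schema-shaped plain dict echo of an experiment configuration."""
    base = config.base
    d: Dict[str, Any] = {}
    if config.preset_name:
        d["preset"] = config.preset_name
    d["population"] = {"size": base.population_size}
    if base.label_counts is not None:
        d["population"]["label_counts"] = list(base.label_counts)
    d["rates"] = {
        "values": [rate_key(r) for r in base.rate_set.rates],
        "labels": list(base.rate_set.labels),
    }
    model = base.model
    d["dfe"] = {
        "p_b": model.beneficial_fraction,
        "mean_beneficial": model.beneficial.mean_effect,
        "shape": model.deleterious.shape,
        "scale": model.deleterious.scale,
        "truncation": model.deleterious.truncation,
    }
    init = base.init_fitness
    d["init_fitness"] = {"kind": init.kind}
    if init.params:
        d["init_fitness"]["params"] = list(init.params)
    if init.kind == "gamma":
        d["init_fitness"]["beta_is_rate"] = init.beta_is_rate
    d["fertility"] = {
        "cap": "unlimited" if base.fertility.is_unlimited else base.fertility.cap
    }
    d["experiment"] = {
        "n_competitions": config.n_competitions,
        "master_seed": config.master_seed,
        "max_generations": base.max_generations,
        "order": base.order,
    }
    return d


def _require(mapping: Dict[str, Any], key: str, section: str) -> Any:
    if key not in mapping:
        raise ConfigError(f"missing required key '{section}.{key}'")
    return mapping[key]


def _number(value: Any, key: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float, str)):
        raise ConfigError(f"key '{key}' must be numeric, got {value!r}")
    try:
        return float(value)
    except ValueError:
        raise ConfigError(f"key '{key}' must be numeric, got {value!r}")


def _check_keys(mapping: Dict[str, Any], allowed: Sequence[str], section: str) -> None:
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{section}]: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def config_from_dict(data: Dict[str, Any]) -> ExperimentConfig:
    """Validate a schema-shaped dict and build the experiment configuration."""
    _check_keys(data, ("preset", *_SECTIONS), "top level")
    base_dict: Dict[str, Any] = {}
    preset_name = data.get("preset")
    if preset_name is not None:
        base_dict = config_to_dict(preset(preset_name))
        base_dict.pop("preset", None)
    for section in _SECTIONS:
        if section in data:
            override = data[section]
            if not isinstance(override, dict):
                raise ConfigError(f"section [{section}] must be a table")
            base_dict.setdefault(section, {}).update(override)

    pop = base_dict.get("population", {})
    _check_keys(pop, ("size", "label_counts"), "population")
    size = int(_number(_require(pop, "size", "population"), "population.size"))

    rates_sec = base_dict.get("rates", {})
    _check_keys(rates_sec, ("ru", "values", "labels"), "rates")
    if "ru" in rates_sec and "values" in rates_sec:
        raise ConfigError("[rates] must give either 'ru' or 'values', not both")
    if "ru" in rates_sec:
        rset = rate_set(rates_sec["ru"])
    elif "values" in rates_sec:
        values = tuple(_number(v, "rates.values") for v in rates_sec["values"])
        labels = tuple(int(x) for x in rates_sec.get("labels", ()))
        rset = SubpopulationRateSet(rates=values, labels=labels)
    else:
        raise ConfigError("missing required key 'rates.ru' or 'rates.values'")

    dfe = base_dict.get("dfe", {})
    _check_keys(
        dfe,
        ("p_b", "mean_beneficial", "shape", "scale", "mean_deleterious", "truncation"),
        "dfe",
    )
    p_b = _number(_require(dfe, "p_b", "dfe"), "dfe.p_b")
    if not 0.0 <= p_b <= 1.0:
        raise ConfigError(f"dfe.p_b must lie in [0, 1], got {p_b}")
    mean_b = _number(_require(dfe, "mean_beneficial", "dfe"), "dfe.mean_beneficial")
    shape = _number(_require(dfe, "shape", "dfe"), "dfe.shape")
    if "scale" in dfe and "mean_deleterious" in dfe:
        raise ConfigError("[dfe] must give either 'scale' or 'mean_deleterious', not both")
    if "scale" in dfe:
        scale = _number(dfe["scale"], "dfe.scale")
    elif "mean_deleterious" in dfe:
        scale = _number(dfe["mean_deleterious"], "dfe.mean_deleterious") / shape
    else:
        raise ConfigError("missing required key 'dfe.scale' or 'dfe.mean_deleterious'")
    truncation = dfe.get("truncation", "reject")
    model = MutationModel(
        beneficial_fraction=p_b,
        beneficial=BeneficialEffectSpec.from_mean(mean_b),
        deleterious=DeleteriousEffectSpec(shape=shape, scale=scale, truncation=truncation),
    )

    init_sec = base_dict.get("init_fitness", {"kind": "uniform_one"})
    _check_keys(init_sec, ("kind", "params", "beta_is_rate"), "init_fitness")
    init = InitialFitnessSpec(
        kind=init_sec.get("kind", "uniform_one"),
        params=tuple(init_sec.get("params", ())),
        beta_is_rate=bool(init_sec.get("beta_is_rate", True)),
    )

    fert_sec = base_dict.get("fertility", {"cap": "unlimited"})
    _check_keys(fert_sec, ("cap",), "fertility")
    cap_raw = fert_sec.get("cap", "unlimited")
    cap = None if cap_raw in ("unlimited", None) else int(_number(cap_raw, "fertility.cap"))

    exp_sec = base_dict.get("experiment", {})
    _check_keys(
        exp_sec, ("n_competitions", "master_seed", "max_generations", "order"), "experiment"
    )
    label_counts = pop.get("label_counts")
    base = CompetitionConfig(
        population_size=size,
        rate_set=rset,
        model=model,
        init_fitness=init,
        fertility=FertilitySpec(cap=cap),
        max_generations=int(exp_sec.get("max_generations", 1_000_000)),
        order=exp_sec.get("order", "mutate-first"),
        label_counts=tuple(int(c) for c in label_counts) if label_counts else None,
    )
    return ExperimentConfig(
        base=base,
        n_competitions=int(exp_sec.get("n_competitions", 300)),
        master_seed=int(exp_sec.get("master_seed", 0)),
        preset_name=preset_name,
    )


def parse_config(source: Union[str, Path]) -> ExperimentConfig:
    """Parse a TOML configuration file (or inline TOML text).

    ``source`` is treated as a file path if such a file exists, otherwise as
    TOML text itself.
    """
    text: str
    path = Path(source)
    try:
        is_file = path.is_file()
    except OSError:
        is_file = False
    if is_file:
        text = path.read_text()
    elif "=" in str(source) or str(source).strip() == "":
        text = str(source)
    else:
        raise ConfigError(f"config file not found: {source}")
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"invalid TOML configuration: {exc}")
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------


def summary_to_dict(summary: FixationSummary, config: ExperimentConfig) -> Dict[str, Any]:
    return {
        "frequency": {rate_key(r): f for r, f in summary.frequency.items()},
        "optimum_rate": summary.optimum_rate,
        "mean_generations": summary.mean_generations,
        "n_fixed": summary.n_fixed,
        "n_censored": summary.n_censored,
        "n_extinct": summary.n_extinct,
        "config": config_to_dict(config),
    }


def _records_frame(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["fixed_rate"] = [
        rate_key(r) if r is not None and not (isinstance(r, float) and np.isnan(r)) else ""
        for r in out["fixed_rate"]
    ]
    return out


def write_outputs(
    summary: FixationSummary,
    records: pd.DataFrame,
    manifest: RunManifest,
    out_dir: Union[str, Path],
) -> Dict[str, Path]:
    """Write ``replicates.csv``, ``summary.json`` and ``manifest.json``."""
    if len(records) == 0:
        raise InvalidParameterError("refusing to write outputs for an empty record set")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "replicates": out / "replicates.csv",
        "summary": out / "summary.json",
        "manifest": out / "manifest.json",
    }
    _records_frame(records).to_csv(paths["replicates"], index=False)
    summary_payload = {
        "frequency": {rate_key(r): f for r, f in summary.frequency.items()},
        "optimum_rate": summary.optimum_rate,
        "mean_generations": summary.mean_generations,
        "n_fixed": summary.n_fixed,
        "n_censored": summary.n_censored,
        "n_extinct": summary.n_extinct,
        "config": manifest.config,
    }
    paths["summary"].write_text(json.dumps(summary_payload, indent=2))
    paths["manifest"].write_text(json.dumps(asdict(manifest), indent=2))
    return paths


def make_manifest(config: ExperimentConfig, out_dir: Union[str, Path]) -> RunManifest:
    out = Path(out_dir)
    return RunManifest(
        config=config_to_dict(config),
        version=__version__,
        master_seed=config.master_seed,
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        replicates_path=str(out / "replicates.csv"),
        summary_path=str(out / "summary.json"),
    )


def rerun_manifest(manifest_path: Union[str, Path]) -> ExperimentResult:
    """Re-execute the run a manifest describes (bit-identical replicates)."""
    data = json.loads(Path(manifest_path).read_text())
    config = config_from_dict(data["config"])
    return run_experiment(config)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def generate_fixture(kind: str, seed: int = 0, **options: Any) -> ExperimentConfig:
    """Small deterministic experiment configurations for tests and examples.

    kinds
    -----
    ``tiny_neutral``
        N = 100, ten labels, all mutation rates zero: pure drift, each
        subpopulation should fix with frequency 1/10.
    ``two_class_selection``
        Two labels, no mutation, founder fitness 1 and ``1 + s`` with the
        fitter class at initial frequency ``p`` (defaults s=0.05, p=0.1,
        N=200): the classical diffusion fixation-probability scenario.
    ``fig_preset_scaled``
        A named preset with the replicate count (and optionally N) reduced
        to desk scale; options: ``name``, ``reps``, ``N``.
    """
    if kind == "tiny_neutral":
        N = int(options.pop("N", 100))
        reps = int(options.pop("reps", 200))
        _no_extra(options, kind)
        rset = SubpopulationRateSet(rates=(0.0,) * 10)
        base = CompetitionConfig(
            population_size=N,
            rate_set=rset,
            model=MutationModel(
                beneficial_fraction=0.0,
                beneficial=BeneficialEffectSpec(rate_parameter=100.0),
                deleterious=DeleteriousEffectSpec(shape=0.6, scale=0.5),
            ),
        )
        return ExperimentConfig(base=base, n_competitions=reps, master_seed=seed)
    if kind == "two_class_selection":
        N = int(options.pop("N", 200))
        s = float(options.pop("s", 0.05))
        p = float(options.pop("p", 0.1))
        reps = int(options.pop("reps", 200))
        _no_extra(options, kind)
        n_fit = int(round(p * N))
        base = CompetitionConfig(
            population_size=N,
            rate_set=SubpopulationRateSet(rates=(0.0, 0.0), labels=(1, 2)),
            model=MutationModel(
                beneficial_fraction=0.0,
                beneficial=BeneficialEffectSpec(rate_parameter=100.0),
                deleterious=DeleteriousEffectSpec(shape=0.6, scale=0.5),
            ),
            init_fitness=InitialFitnessSpec(kind="per_label", params=(1.0, 1.0 + s)),
            label_counts=(N - n_fit, n_fit),
        )
        return ExperimentConfig(base=base, n_competitions=reps, master_seed=seed)
    if kind == "fig_preset_scaled":
        name = options.pop("name", "fig2_N1e4")
        reps = int(options.pop("reps", 100))
        N = options.pop("N", None)
        _no_extra(options, kind)
        cfg = preset(name)
        base = cfg.base if N is None else replace(cfg.base, population_size=int(N))
        return ExperimentConfig(
            base=base, n_competitions=reps, master_seed=seed, preset_name=name
        )
    raise InvalidParameterError(f"unknown fixture kind {kind!r}")


def _no_extra(options: Dict[str, Any], kind: str) -> None:
    if options:
        raise InvalidParameterError(
            f"unknown option(s) for fixture {kind!r}: {sorted(options)}"
        )
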
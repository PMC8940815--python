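"""Declarative YAML/JSON configuration for models, designs and studies.

A model config names the absorption variant and gives the parameter values:

.. code-block:: yaml

    variant: II
    parameters:
      cl: 50.0
      v1: 30.0
      f_pul: 0.4
      f_fast: 0.7
      k_fast: 1.5
      f_slow: 0.3
      k_slow: 0.1

A study config adds the trial design (arms with routes, doses, sampling),
the variability model and the estimation arms; see
``load_study_config`` for the full schema.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .models import AbsorptionVariant, ConfigurationError, ParameterSet, Route
from .nlme import Strategy
from .simulate import Occasion, StudyArm, TrialDesign, VariabilityModel
from .workflow import EstimationArm, GridConfig, StudyConfig

__all__ = [
    "load_model_config",
    "load_grid_config",
    "load_study_config",
    "parse_model",
    "parse_design",
    "parse_variability",
]


def _read(path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return dict(data)


def parse_model(data: Mapping[str, Any]) -> tuple[AbsorptionVariant, ParameterSet]:
    try:
        name = data["variant"]
        raw = dict(data["parameters"])
    except KeyError as exc:
        raise ConfigurationError(f"model config missing key {exc}") from None
    variant = AbsorptionVariant.from_name(name, n_transit=int(data.get("n_transit", 3)))
    try:
        params = ParameterSet(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"unknown parameter in config: {exc}") from None
    return variant, params


def load_model_config(path) -> tuple[AbsorptionVariant, ParameterSet]:
    return parse_model(_read(path))


def parse_design(data: Mapping[str, Any]) -> TrialDesign:
    arms = []
    for arm in data["arms"]:
        occasions = []
        for occ in arm.get("occasions", [{"doses": [[0.0, arm.get("dose")]],
                                          "sampling_times": arm.get("sampling_times")}]):
            occasions.append(
                Occasion(
                    doses=tuple((float(t), float(a)) for t, a in occ["doses"]),
                    sampling_times=tuple(float(t) for t in occ["sampling_times"]),
                )
            )
        arms.append(StudyArm(Route(arm["route"]), int(arm["n_subjects"]), tuple(occasions)))
    return TrialDesign(arms=tuple(arms), crossover=bool(data.get("crossover", False)))


def parse_variability(data: Mapping[str, Any]) -> VariabilityModel:
    return VariabilityModel(
        iiv={k: float(v) for k, v in (data.get("iiv") or {}).items()},
        iov={k: float(v) for k, v in (data.get("iov") or {}).items()},
        residual_proportional_sd=float(data.get("residual_proportional_sd", 0.0)),
    )


def load_grid_config(path) -> GridConfig:
    data = _read(path)
    parameters = None
    if "models" in data and isinstance(data["models"], Mapping):
        parameters = {name: parse_model(spec) for name, spec in data["models"].items()}
        names = tuple(n for n in parameters if n != "SemiMechanistic")
    else:
        names = tuple(data.get("models", GridConfig.models))
    return GridConfig(
        models=names,
        include_semimechanistic=bool(data.get("include_semimechanistic", False)),
        parameters=parameters,
        dose=float(data.get("dose", GridConfig.dose)),
        horizon_h=float(data.get("horizon_h", GridConfig.horizon_h)),
        dt_h=float(data.get("dt_h", GridConfig.dt_h)),
        fit_subsample=int(data.get("fit_subsample", GridConfig.fit_subsample)),
        n_retries=int(data.get("n_retries", GridConfig.n_retries)),
        seed=int(data.get("seed", GridConfig.seed)),
    )


def load_study_config(path) -> StudyConfig:
    data = _read(path)
    sim_variant, sim_params = parse_model(data["simulation"])
    arms = []
    for arm in data["estimation_arms"]:
        variant, params = parse_model(arm)
        arms.append(EstimationArm(str(arm.get("name", variant.name.value)), variant, params))
    strategies = tuple(str(s).upper() for s in data.get("strategies", [Strategy.PPP]))
    return StudyConfig(
        simulation_variant=sim_variant,
        simulation_params=sim_params,
        design=parse_design(data["design"]),
        variability=parse_variability(data.get("variability", {})),
        arms=arms,
        strategies=strategies,
        iiv=tuple(data.get("iiv", list((data.get("variability") or {}).get("iiv", {})))),
        iov=tuple(data.get("iov", list((data.get("variability") or {}).get("iov", {})))),
        n_replicates=int(data.get("n_replicates", 500)),
        master_seed=int(data.get("seed", 1234)),
        sigma_init=float(data.get("sigma_init", 0.15)),
        max_retries=int(data.get("max_retries", 2)),
    )
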
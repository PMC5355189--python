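"""YAML configuration for simulation scenarios, fits, and pipelines.

A scenario file describes one or two simulated populations; a fit file
sets MCMC lengths and priors; a pipeline file combines both for the
end-to-end run (simulate two populations, fit each, emit all report
tables).  Every run must carry an explicit seed so artifacts are exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .data import DemographicParams, ValidationError
from .ipm import FitConfig, PriorConfig
from .simulate import SimulationConfig

__all__ = [
    "PipelineConfig",
    "load_yaml",
    "sim_config_from_dict",
    "fit_config_from_dict",
    "prior_config_from_dict",
    "pipeline_config_from_dict",
    "load_pipeline_config",
]

_PARAM_KEYS = ("mu_phi_j", "mu_phi_a", "mu_p", "mu_f", "sigma_phi_j",
               "sigma_phi_a", "sigma_p", "sigma_f")


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValidationError(f"{path}: expected a mapping at top level")
    return out


def sim_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    pdict = d.pop("params", {})
    unknown = set(pdict) - set(_PARAM_KEYS)
    if unknown:
        raise ValidationError(f"unknown demographic parameters: {unknown}")
    base = SimulationConfig().params
    params = DemographicParams(**{
        k: pdict.get(k, getattr(base, k)) for k in _PARAM_KEYS})
    allowed = {"T", "n1_init", "nad_init", "nimm_init", "m",
               "tag_loss_prob", "unsexed_prob", "second_brood_prob",
               "start_year", "seed"}
    unknown = set(d) - allowed
    if unknown:
        raise ValidationError(f"unknown simulation keys: {unknown}")
    return SimulationConfig(params=params, **d)


def fit_config_from_dict(d: dict) -> FitConfig:
    allowed = {"chains", "iterations", "burnin", "thin", "seed",
               "rhat_threshold"}
    unknown = set(d) - allowed
    if unknown:
        raise ValidationError(f"unknown fit keys: {unknown}")
    return FitConfig(**d)


def prior_config_from_dict(d: dict) -> PriorConfig:
    d = dict(d)
    if "m_bounds" in d:
        d["m_bounds"] = tuple(float(v) for v in d["m_bounds"])
    allowed = {"m_bounds", "sigma_upper", "muf_prior_sd", "init_mean",
               "init_sd"}
    unknown = set(d) - allowed
    if unknown:
        raise ValidationError(f"unknown prior keys: {unknown}")
    return PriorConfig(**d)


@dataclass
class PipelineConfig:
    """Everything needed for one simulate -> fit -> analyse run."""

    seed: int
    sim_a: SimulationConfig
    sim_b: SimulationConfig
    coupling: float = 0.0
    fit: FitConfig = field(default_factory=FitConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("pipeline seed must be set explicitly")


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    if "seed" not in d:
        raise ValidationError("pipeline config requires an explicit seed")
    sim = d.get("simulate", {})
    sim_a = sim_config_from_dict(sim.get("a", {}))
    sim_b = sim_config_from_dict(sim.get("b", {}))
    return PipelineConfig(
        seed=int(d["seed"]),
        sim_a=sim_a,
        sim_b=sim_b,
        coupling=float(sim.get("coupling", 0.0)),
        fit=fit_config_from_dict(d.get("fit", {})),
        priors=prior_config_from_dict(d.get("priors", {})),
    )


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    return pipeline_config_from_dict(load_yaml(path))
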
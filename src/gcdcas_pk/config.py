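"""Run configuration: YAML serialisation of population parameters, constants,
solver settings and seeds.  Field names are stable and documented here; a run
writes its resolved config next to its outputs for reproducibility."""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .population import PopulationParameters, ResidualSpec, default_population

__all__ = ["RunConfig", "population_to_dict", "population_from_dict",
           "load_config", "save_config"]


@dataclass
class RunConfig:
    population: PopulationParameters
    seed: int = 0
    solver_dt: float = 0.02          # grid step, h
    iiv_convention: str = "direct"   # how IIV % maps to omega

    @classmethod
    def default(cls, seed: int = 0) -> "RunConfig":
        return cls(population=default_population(), seed=seed)


def population_to_dict(pop: PopulationParameters) -> dict:
    return {
        "fixed": dict(pop.fixed),
        "iiv": dict(pop.iiv),
        "residual": {
            k: {"prop": v.prop, "add": v.add, "add_fixed": v.add_fixed}
            for k, v in pop.residual.items()
        },
        "constants": dict(pop.constants),
        "not_estimated": list(pop.not_estimated),
    }


def population_from_dict(d: dict) -> PopulationParameters:
    return PopulationParameters(
        fixed=dict(d["fixed"]),
        iiv=dict(d["iiv"]),
        residual={k: ResidualSpec(**v) for k, v in d["residual"].items()},
        constants=dict(d.get("constants", {})),
        not_estimated=tuple(d.get("not_estimated", ("Vc",))),
    )


def save_config(cfg: RunConfig, path) -> None:
    doc = {
        "population": population_to_dict(cfg.population),
        "seed": cfg.seed,
        "solver_dt": cfg.solver_dt,
        "iiv_convention": cfg.iiv_convention,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return RunConfig(
        population=population_from_dict(doc["population"]),
        seed=int(doc["seed"]),
        solver_dt=float(doc["solver_dt"]),
        iiv_convention=doc.get("iiv_convention", "direct"),
    )
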
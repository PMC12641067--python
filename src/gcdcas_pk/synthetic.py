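"""Synthetic stand-ins for the clinical studies.

The individual-level clinical datasets behind the model are not deposited
anywhere, so every estimation and design exercise in this package runs on
synthetic data generated under the final model: the three cross-over
designs, log-normal IIV, and proportional(+additive) residual error at the
reported magnitudes.  A truth sidecar (generator parameters, seed, design)
is always written next to the dataset so downstream analyses never rely on
remembering generator settings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .config import population_to_dict
from .datasets import records_to_dataset, write_dataset
from .population import PopulationParameters, default_population
from .trial_sim import StudyDesign, builtin_designs, simulate_trial

__all__ = ["GenerationSpec", "generate_study", "generate_ensemble"]


@dataclass(frozen=True)
class GenerationSpec:
    design: str | StudyDesign = "study1"
    truth: PopulationParameters | None = None   # defaults to the final estimates
    seed: int = 0
    with_residual: bool = True
    dt: float = 0.02

    def resolve_design(self) -> StudyDesign:
        if isinstance(self.design, StudyDesign):
            return self.design
        designs = builtin_designs()
        if self.design not in designs:
            raise ValueError(f"unknown design {self.design!r}; "
                             f"available: {sorted(designs)}")
        return designs[self.design]

    def resolve_truth(self) -> PopulationParameters:
        return self.truth if self.truth is not None else default_population()


def generate_study(spec: GenerationSpec, out_dir) -> dict:
    """Generate one synthetic dataset: ``dataset.csv`` + ``truth.json``.

    Returns the paths of the written files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = spec.resolve_design()
    truth = spec.resolve_truth()
    rng = np.random.default_rng(spec.seed)
    records = simulate_trial(design, truth, rng,
                             with_residual=spec.with_residual, dt=spec.dt)
    doses = {i: occ.doses for i, occ in enumerate(design.occasions, start=1)}
    df = records_to_dataset(records, doses)
    data_path = out / "dataset.csv"
    write_dataset(df, data_path)
    sidecar = {
        "design": design.name,
        "seed": int(spec.seed),
        "with_residual": bool(spec.with_residual),
        "dt": spec.dt,
        "truth": population_to_dict(truth),
        "package_version": __version__,
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return {"dataset": data_path, "truth": truth_path}


def generate_ensemble(seeds, spec: GenerationSpec, out_dir) -> dict:
    """One replicate dataset per seed, plus a manifest listing them all."""
    seeds = list(seeds)
    if not seeds:
        raise ValueError("need at least one seed")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for seed in seeds:
        sub = out / f"seed{seed}"
        paths = generate_study(
            GenerationSpec(design=spec.design, truth=spec.truth, seed=seed,
                           with_residual=spec.with_residual, dt=spec.dt),
            sub,
        )
        entries.append({"seed": int(seed),
                        "dataset": str(paths["dataset"].relative_to(out)),
                        "truth": str(paths["truth"].relative_to(out))})
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps({"replicates": entries}, indent=1))
    return {"manifest": manifest_path, "entries": entries}
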
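"""Statistical layer: inter-individual variability and residual error.

Individual parameters are log-normal around the typical value,
``theta_i = theta * exp(eta_i)`` with ``eta_i ~ N(0, omega^2)``.  The
reported IIV percentages are interpreted as ``100 * omega`` (the usual
reporting convention of NLME software); the exact-CV convention
``omega = sqrt(ln(1 + cv^2))`` is available via ``cv_to_omega``.

Residual error is a combined proportional + additive Gaussian model,
``y = f * (1 + eps_p) + eps_a``; negative draws are floored at zero (a
concentration or amount cannot be negative) and the flooring is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model_core import BiomarkerParams, ProbenecidParams, RifampicinParams

__all__ = [
    "ResidualSpec",
    "PopulationParameters",
    "IndividualParameters",
    "default_population",
    "sample_individual",
    "sample_etas",
    "individual_from_etas",
    "apply_residual",
    "cv_to_omega",
    "OBSERVABLES",
]

logger = logging.getLogger(__name__)

OBSERVABLES = (
    "biomarker_plasma",   # µM
    "biomarker_urine",    # µmol per collection interval
    "rifampicin_plasma",  # µM
    "probenecid_plasma",  # µM
)


@dataclass(frozen=True)
class ResidualSpec:
    """Residual error for one observable: proportional SD (fraction) and
    additive SD (observable units).  ``add_fixed`` marks the additive
    component as not estimated."""

    prop: float
    add: float = 0.0
    add_fixed: bool = False

    def __post_init__(self):
        if self.prop < 0 or self.add < 0:
            raise ValueError("residual SDs must be non-negative")
        if self.prop == 0 and self.add == 0:
            raise ValueError("at least one residual component must be > 0")

    def sd(self, prediction):
        return np.sqrt((self.prop * np.asarray(prediction)) ** 2 + self.add**2)


@dataclass(frozen=True)
class PopulationParameters:
    """Typical values, IIV magnitudes and residual error of the coupled models.

    ``fixed`` maps parameter name -> typical value; ``iiv`` maps parameter
    name -> omega (log-scale SD; parameters without IIV are omitted);
    ``residual`` maps observable name -> ResidualSpec.  ``constants`` holds
    the unit-conversion assumptions (unbound fractions, molecular weights).
    ``not_estimated`` lists structural parameters held fixed in estimation.
    """

    fixed: dict
    iiv: dict
    residual: dict
    constants: dict = field(default_factory=dict)
    not_estimated: tuple = ("Vc",)

    def __post_init__(self):
        for k, v in self.iiv.items():
            if v < 0:
                raise ValueError(f"iiv[{k!r}] must be >= 0")
            if k not in self.fixed:
                raise ValueError(f"iiv refers to unknown parameter {k!r}")
        for k in self.residual:
            if k not in OBSERVABLES:
                raise ValueError(f"unknown observable {k!r} in residual spec")

    # --- structural parameter views -------------------------------------
    def rifampicin(self, values: dict | None = None) -> RifampicinParams:
        v = values or self.fixed
        return RifampicinParams(
            Tlag=v["Tlag_RIF"], Tk0=v["Tk0_RIF"], V=v["V_RIF"], CL=v["CL_RIF"],
            fu=self.constants.get("fu_RIF", 0.10),
            MW=self.constants.get("MW_RIF", 822.94),
            Ki_u_OATP1B3=v["Ki_u_OATP1B3"],
        )

    def probenecid(self, values: dict | None = None) -> ProbenecidParams:
        v = values or self.fixed
        return ProbenecidParams(
            ka=v["ka_PROB"], V=v["V_PROB"], CL=v["CL_PROB"],
            fu=self.constants.get("fu_PROB", 0.10),
            MW=self.constants.get("MW_PROB", 285.36),
            Ki_u_OAT3=v["Ki_u_OAT3"], X=v["X"],
        )

    def biomarker(self, values: dict | None = None) -> BiomarkerParams:
        v = values or self.fixed
        return BiomarkerParams(ksyn=v["ksyn"], Vc=v["Vc"], CLh=v["CLh"], CLR=v["CLR"])


@dataclass(frozen=True)
class IndividualParameters:
    """Realised structural parameters for one subject (occasion-constant)."""

    values: dict
    etas: dict

    def __post_init__(self):
        for k, v in self.values.items():
            if v <= 0:
                raise ValueError(f"individual parameter {k!r} must be positive")


def cv_to_omega(cv_percent: float, convention: str = "direct") -> float:
    """Convert a reported IIV percentage to a log-scale SD omega.

    ``direct``: omega = cv/100 (the value printed IS 100*omega).
    ``exact``:  omega = sqrt(ln(1 + (cv/100)^2)) (printed value is the
    log-normal coefficient of variation).
    """
    if cv_percent < 0:
        raise ValueError("cv must be >= 0")
    c = cv_percent / 100.0
    if convention == "direct":
        return c
    if convention == "exact":
        return float(np.sqrt(np.log1p(c**2)))
    raise ValueError(f"unknown convention {convention!r}")


def default_population(iiv_convention: str = "direct") -> PopulationParameters:
    """Final population estimates of the coupled rifampicin, probenecid and
    GCDCA-S models (typical values, IIV, residual error)."""
    w = lambda cv: cv_to_omega(cv, iiv_convention)
    return PopulationParameters(
        fixed={
            # probenecid
            "ka_PROB": 1.1, "V_PROB": 17.0, "CL_PROB": 0.95,
            "Ki_u_OAT3": 2.7, "X": 1.7,
            # rifampicin
            "Tlag_RIF": 0.56, "Tk0_RIF": 0.84, "V_RIF": 35.0, "CL_RIF": 6.7,
            "Ki_u_OATP1B3": 0.009,
            # biomarker
            "ksyn": 1.0, "Vc": 4.8, "CLR": 0.31, "CLh": 15.0,
        },
        iiv={
            "V_PROB": w(31), "CL_PROB": w(27), "Ki_u_OAT3": w(32),
            "Tlag_RIF": w(46), "Tk0_RIF": w(77), "CL_RIF": w(18),
            "ksyn": w(61), "CLR": w(24),
        },
        residual={
            "probenecid_plasma": ResidualSpec(prop=0.23, add=0.001, add_fixed=True),
            "rifampicin_plasma": ResidualSpec(prop=0.20, add=0.2, add_fixed=True),
            "biomarker_plasma": ResidualSpec(prop=0.45),
            "biomarker_urine": ResidualSpec(prop=0.29),
        },
        constants={
            "fu_RIF": 0.10, "fu_PROB": 0.10,
            "MW_RIF": 822.94, "MW_PROB": 285.36,
        },
        not_estimated=("Vc",),
    )


def sample_etas(pop: PopulationParameters, rng: np.random.Generator, n: int = 1) -> dict:
    """Draw eta ~ N(0, omega^2) for every parameter with IIV; (n,)-arrays."""
    return {k: rng.normal(0.0, om, size=n) for k, om in pop.iiv.items()}


def individual_from_etas(pop: PopulationParameters, etas: dict) -> IndividualParameters:
    values = dict(pop.fixed)
    for k, e in etas.items():
        values[k] = pop.fixed[k] * float(np.exp(e))
    return IndividualParameters(values=values, etas={k: float(e) for k, e in etas.items()})


def sample_individual(pop: PopulationParameters, rng: np.random.Generator) -> IndividualParameters:
    """One subject: each parameter with IIV drawn log-normally, others copied."""
    etas = {k: rng.normal(0.0, om) for k, om in pop.iiv.items()}
    return individual_from_etas(pop, etas)


def apply_residual(prediction, observable: str, residual: dict, rng: np.random.Generator):
    """Add combined proportional + additive error; floor negatives at zero.

    ``residual`` is the ``PopulationParameters.residual`` mapping.  Works
    elementwise on arrays.
    """
    if observable not in residual:
        raise ValueError(f"unknown observable {observable!r}")
    spec = residual[observable]
    pred = np.asarray(prediction, dtype=float)
    if np.any(pred < 0):
        raise ValueError("predictions must be >= 0")
    obs = pred * (1.0 + rng.normal(0.0, spec.prop, size=pred.shape)) if spec.prop > 0 else pred.copy()
    if spec.add > 0:
        obs = obs + rng.normal(0.0, spec.add, size=pred.shape)
    n_neg = int(np.sum(obs < 0))
    if n_neg:
        logger.warning("floored %d negative simulated %s observation(s) at 0", n_neg, observable)
        obs = np.maximum(obs, 0.0)
    return obs if np.ndim(prediction) else float(obs)
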
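"""Power calculation for transporter-DDI study designs, and the synthesis-rate
sensitivity analysis.

Hypothetical OATP1B3 (OAT3) inhibitors are assumed to follow rifampicin
(probenecid) PK with the unbound-concentration-to-Ki ratio scaled by a
potency factor Y relative to the reference inhibitor; Y = 1 reproduces the
fitted drug.  For each simulated trial of n subjects, every subject is
simulated on a control and a treatment occasion with shared random effects
(cross-over) and residual error on; the detection metric is the
within-subject ratio of plasma AUC(0-24 h) (OATP1B3) or of observed renal
clearance Ae/AUC over the collection window (OAT3).  Power is the fraction
of replicate trials in which a two-sided one-sample t-test on the
log-ratios rejects the null of no change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .population import PopulationParameters, apply_residual, default_population, sample_etas
from .trial_sim import (
    OccasionDesign,
    StudyDesign,
    builtin_designs,
    simulate_occasion,
    _individual_arrays,
)

__all__ = ["PowerScenario", "PowerGrid", "subject_metric_ratio",
           "simulate_metric_ratios", "power_curve", "ksyn_perturbation"]

_TARGETS = {"OATP1B3": "auc", "OAT3": "clr"}
_DEFAULT_DESIGN = {"OATP1B3": "study1", "OAT3": "study3"}


@dataclass(frozen=True)
class PowerScenario:
    """One point of the power analysis.

    ``y``: potency scale (I/Ki multiplier relative to rifampicin for
    OATP1B3, probenecid for OAT3).  ``metric`` defaults to the
    target-appropriate one: plasma AUCR for OATP1B3, CLR ratio for OAT3.
    """

    target: str = "OATP1B3"
    y: float = 1.0
    metric: str | None = None      # "auc" | "clr"; None = target default
    design: str | StudyDesign | None = None
    sample_sizes: tuple = (5, 10, 15, 20, 25, 30)
    alphas: tuple = (0.01, 0.05)
    replicates: int = 1000
    power_threshold: float = 0.8
    with_residual: bool = True
    dt: float = 0.05

    def __post_init__(self):
        if self.target not in _TARGETS:
            raise ValueError(f"target must be one of {sorted(_TARGETS)}")
        if self.y < 0:
            raise ValueError("potency scale y must be >= 0")
        if any(n < 2 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 2")
        if any(not 0 < a < 1 for a in self.alphas):
            raise ValueError("alpha must be in (0, 1)")
        if self.metric is not None and self.metric not in ("auc", "clr"):
            raise ValueError("metric must be 'auc' or 'clr'")

    @property
    def resolved_metric(self) -> str:
        return self.metric if self.metric is not None else _TARGETS[self.target]

    def resolve_design(self) -> StudyDesign:
        d = self.design if self.design is not None else _DEFAULT_DESIGN[self.target]
        if isinstance(d, StudyDesign):
            return d
        return builtin_designs()[d]


@dataclass
class PowerGrid:
    """Power estimates indexed by (target, Y, n, alpha) with Monte-Carlo SE."""

    table: pd.DataFrame    # columns: target, y, n, alpha, power, mc_se, replicates

    def power(self, y, n, alpha) -> float:
        t = self.table
        row = t[(t["y"] == y) & (t["n"] == n) & (t["alpha"] == alpha)]
        if row.empty:
            raise KeyError((y, n, alpha))
        return float(row["power"].iloc[0])

    def minimal_n(self, alpha, y=None, threshold=0.8):
        """Smallest tested n with power >= threshold, or None (not reached)."""
        t = self.table[self.table["alpha"] == alpha]
        if y is not None:
            t = t[t["y"] == y]
        ok = t[t["power"] >= threshold].sort_values("n")
        return int(ok["n"].iloc[0]) if len(ok) else None


def _collection_window(occ: OccasionDesign, metric: str) -> tuple:
    """0-24 h AUC window for the plasma metric; for the renal metric the
    first 24 h of urine collection (the interval edges of the design)."""
    if metric == "auc":
        t0 = float(min(occ.biomarker_times))
        return (t0, t0 + 24.0)
    edges = np.asarray(occ.urine_intervals, dtype=float)
    t0 = float(edges[0, 0])
    keep = edges[edges[:, 1] <= t0 + 24.0 + 1e-9]
    return (t0, float(keep[-1, 1]))


def simulate_metric_ratios(
    scenario: PowerScenario,
    n_subjects: int,
    pop: PopulationParameters,
    rng: np.random.Generator,
) -> np.ndarray:
    """Within-subject treatment/control metric ratios for ``n_subjects``
    independent subjects (vectorised; shared etas across occasions)."""
    design = scenario.resolve_design()
    control, treated = design.occasions[0], design.occasions[-1]
    window = _collection_window(treated, scenario.resolved_metric)
    scales = {"scale_oatp1b3": scenario.y if scenario.target == "OATP1B3" else 0.0,
              "scale_oat3": scenario.y if scenario.target == "OAT3" else 0.0}
    # control occasion: both scales off regardless of target
    etas = sample_etas(pop, rng, n_subjects)
    values = _individual_arrays(pop, etas, n_subjects)

    out = {}
    for label, occ, sc in (("control", control, {"scale_oatp1b3": 0.0, "scale_oat3": 0.0}),
                           ("treated", treated, scales)):
        sim = simulate_occasion(occ, pop, values, dt=scenario.dt, **sc)
        bt = np.asarray(occ.biomarker_times, dtype=float)
        in_win = (bt >= window[0] - 1e-9) & (bt <= window[1] + 1e-9)
        plasma = sim["biomarker_plasma"][:, in_win]
        if scenario.with_residual:
            plasma = apply_residual(plasma, "biomarker_plasma", pop.residual, rng)
        auc = np.trapezoid(plasma, bt[in_win], axis=1)
        if scenario.resolved_metric == "clr":
            edges = np.asarray(occ.urine_intervals, dtype=float)
            keep = (edges[:, 0] >= window[0] - 1e-9) & (edges[:, 1] <= window[1] + 1e-9)
            urine = sim["biomarker_urine"][:, keep]
            if scenario.with_residual:
                urine = apply_residual(urine, "biomarker_urine", pop.residual, rng)
            ae = urine.sum(axis=1)
            out[label] = np.where(auc > 0, ae / np.where(auc > 0, auc, 1.0), np.nan)
        else:
            out[label] = auc
    ratio = out["treated"] / out["control"]
    bad = ~np.isfinite(ratio) | (ratio <= 0)
    if np.any(bad):  # resample degenerate subjects (zero denominators)
        ratio[bad] = simulate_metric_ratios(scenario, int(bad.sum()), pop, rng)
    return ratio


def subject_metric_ratio(scenario: PowerScenario, pop: PopulationParameters,
                         rng: np.random.Generator) -> float:
    """Treatment/control metric ratio for a single simulated subject."""
    return float(simulate_metric_ratios(scenario, 1, pop, rng)[0])


def power_curve(scenario: PowerScenario, rng: np.random.Generator,
                pop: PopulationParameters | None = None) -> PowerGrid:
    """Estimate power over the scenario's sample-size grid.

    For each replicate trial: draw n subjects, compute log metric ratios,
    two-sided one-sample t-test of mean log-ratio against 0; power is the
    rejection fraction over replicates.
    """
    pop = pop if pop is not None else default_population()
    R = scenario.replicates
    rows = []
    chunk = 6000   # subjects per batched solve; bounds peak memory
    for n in scenario.sample_sizes:
        total = n * R
        parts = [
            simulate_metric_ratios(scenario, min(chunk, total - i), pop, rng)
            for i in range(0, total, chunk)
        ]
        ratios = np.concatenate(parts).reshape(R, n)
        logs = np.log(ratios)
        mean = logs.mean(axis=1)
        sd = logs.std(axis=1, ddof=1)
        tstat = mean / (sd / np.sqrt(n))
        pvals = 2.0 * scipy.stats.t.sf(np.abs(tstat), df=n - 1)
        for alpha in scenario.alphas:
            p = float(np.mean(pvals < alpha))
            rows.append({
                "target": scenario.target, "y": scenario.y, "n": n,
                "alpha": alpha, "power": p,
                "mc_se": float(np.sqrt(p * (1 - p) / R)), "replicates": R,
            })
    return PowerGrid(table=pd.DataFrame(rows))


def ksyn_perturbation(
    folds: Sequence[float],
    scenario: PowerScenario | None = None,
    pop: PopulationParameters | None = None,
    dt: float = 0.02,
) -> pd.DataFrame:
    """Typical-individual AUC and CLR_obs when the synthesis rate is scaled.

    Simulates the treated occasion of the scenario's design for the typical
    subject with ``ksyn`` multiplied by each fold (alongside the scenario's
    transporter inhibition) and reports plasma AUC and CLR_obs = Ae/AUC over
    the collection window.  Because the turnover model is linear in
    ``ksyn``, AUC scales with the fold while CLR_obs is invariant.
    """
    pop = pop if pop is not None else default_population()
    scenario = scenario or PowerScenario(target="OAT3", y=0.0)
    if any(f <= 0 for f in folds):
        raise ValueError("fold changes must be > 0")
    design = scenario.resolve_design()
    treated = design.occasions[-1]
    if not treated.urine_intervals:
        raise ValueError("the scenario design must collect urine for CLR_obs")
    window = _collection_window(treated, "clr")
    scales = {"scale_oatp1b3": scenario.y if scenario.target == "OATP1B3" else 0.0,
              "scale_oat3": scenario.y if scenario.target == "OAT3" else 0.0}
    rows = []
    for fold in folds:
        values = {k: np.full(1, v) for k, v in pop.fixed.items()}
        values["ksyn"] = np.full(1, pop.fixed["ksyn"] * fold)
        sim = simulate_occasion(treated, pop, values, dt=dt, **scales)
        bt = np.asarray(treated.biomarker_times, dtype=float)
        in_win = (bt >= window[0] - 1e-9) & (bt <= window[1] + 1e-9)
        auc = float(np.trapezoid(sim["biomarker_plasma"][0, in_win], bt[in_win]))
        edges = np.asarray(treated.urine_intervals, dtype=float)
        keep = (edges[:, 0] >= window[0] - 1e-9) & (edges[:, 1] <= window[1] + 1e-9)
        ae = float(sim["biomarker_urine"][0, keep].sum())
        rows.append({"fold": fold, "auc": auc, "ae": ae, "clr_obs": ae / auc})
    return pd.DataFrame(rows)
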
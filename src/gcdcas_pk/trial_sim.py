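"""Clinical-trial simulation: study designs, observation generation, NCA, VPC.

The three model-development designs are paired cross-over studies: every
subject is simulated with one set of random effects shared across both
occasions, so within-subject ratios (AUCR, CLR ratio) cancel the IIV.

Exact per-study sampling clock times are not published; the default grids
are chosen to reproduce the published observation counts and are
configurable through :class:`OccasionDesign`.  Probenecid occasions start
at the first evening dose (6 pm day 0 = t 0 h); plasma/urine collection
begins the next morning (7 am day 1 = t 13 h), so the sampling day carries
realistic carry-over from the evening doses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import (
    DoseEvent,
    PROBENECID,
    RIFAMPICIN,
    build_grid,
    probenecid_conc_batch,
    rifampicin_conc_batch,
    solve_biomarker_batch,
)
from .population import PopulationParameters, apply_residual, sample_etas

__all__ = [
    "OccasionDesign",
    "StudyDesign",
    "NCAMetrics",
    "builtin_designs",
    "probenecid_regimen",
    "simulate_trial",
    "nca",
    "vpc",
    "PROBENECID_SAMPLING_START",
]

# 6 pm day-0 first dose -> 7 am day-1 sampling start
PROBENECID_SAMPLING_START = 13.0


@dataclass(frozen=True)
class OccasionDesign:
    """One occasion of a cross-over study arm."""

    label: str
    duration: float                      # h, occasion time span
    doses: tuple = ()                    # DoseEvent sequence
    biomarker_times: tuple = ()          # plasma sampling times, h
    inhibitor_times: tuple = ()          # inhibitor plasma sampling times, h
    urine_intervals: tuple = ()          # ((start, end), ...) h

    def __post_init__(self):
        for ts in (self.biomarker_times, self.inhibitor_times):
            if any(t < 0 or t > self.duration for t in ts):
                raise ValueError("sampling times must lie within [0, duration]")
        last = -np.inf
        for s, e in self.urine_intervals:
            if not (0 <= s < e <= self.duration):
                raise ValueError("urine intervals must be ordered within [0, duration]")
            if s < last:
                raise ValueError("urine intervals must be non-overlapping and ordered")
            last = e

    @property
    def inhibitor(self) -> str | None:
        drugs = {d.drug for d in self.doses}
        if len(drugs) > 1:
            raise ValueError("an occasion administers at most one inhibitor")
        return drugs.pop() if drugs else None


@dataclass(frozen=True)
class StudyDesign:
    name: str
    n_subjects: int
    occasions: tuple
    duration: float

    def occasion(self, label_or_index) -> OccasionDesign:
        if isinstance(label_or_index, int):
            return self.occasions[label_or_index]
        for occ in self.occasions:
            if occ.label == label_or_index:
                return occ
        raise KeyError(label_or_index)


def probenecid_regimen(duration: float, dose_mg: float = 500.0, n_days: int = 7) -> tuple:
    """500 mg at 6 pm and 11 pm on day 0, then 7 am / 1 pm / 6 pm / 11 pm on
    days 1..n_days, truncated to dose times strictly inside ``duration``."""
    times = [0.0, 5.0]
    for day in range(n_days):
        base = 13.0 + 24.0 * day
        times.extend([base, base + 6.0, base + 11.0, base + 16.0])
    return tuple(
        DoseEvent(PROBENECID, t, dose_mg) for t in sorted(times) if t < duration
    )


def _probenecid_study(name: str, n_subjects: int, sampling_hours: float,
                      biomarker_offsets, inhibitor_offsets, urine_offsets) -> StudyDesign:
    t0 = PROBENECID_SAMPLING_START
    duration = t0 + sampling_hours
    bt = tuple(t0 + o for o in biomarker_offsets)
    it = tuple(t0 + o for o in inhibitor_offsets)
    ui = tuple((t0 + a, t0 + b) for a, b in urine_offsets)
    control = OccasionDesign(
        label="control", duration=duration,
        biomarker_times=bt, urine_intervals=ui,
    )
    treated = OccasionDesign(
        label="probenecid", duration=duration,
        doses=probenecid_regimen(duration),
        biomarker_times=bt, inhibitor_times=it, urine_intervals=ui,
    )
    return StudyDesign(name=name, n_subjects=n_subjects,
                       occasions=(control, treated), duration=duration)


def _rifampicin_study(name: str, n_subjects: int, dose_mg: float,
                      biomarker_times, inhibitor_times) -> StudyDesign:
    control = OccasionDesign(label="control", duration=24.0,
                             biomarker_times=tuple(biomarker_times))
    treated = OccasionDesign(
        label="rifampicin", duration=24.0,
        doses=(DoseEvent(RIFAMPICIN, 0.0, dose_mg),),
        biomarker_times=tuple(biomarker_times),
        inhibitor_times=tuple(inhibitor_times),
    )
    return StudyDesign(name=name, n_subjects=n_subjects,
                       occasions=(control, treated), duration=24.0)


def builtin_designs() -> dict:
    """The three model-development designs plus the single-dose rifampicin
    verification designs (300 and 600 mg)."""
    designs = {}
    designs["study1"] = _rifampicin_study(
        "study1", 6, 600.0,
        biomarker_times=(0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0),
        inhibitor_times=(0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0),
    )
    designs["study2"] = _probenecid_study(
        "study2", 6, 168.0,
        biomarker_offsets=(0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0, 96.0, 168.0),
        inhibitor_offsets=(0.0, 1.0, 2.0, 4.0, 8.0, 12.0),
        urine_offsets=((0, 6), (6, 12), (12, 24), (24, 48), (48, 72),
                       (72, 96), (96, 120), (120, 144), (144, 168)),
    )
    designs["study3"] = _probenecid_study(
        "study3", 12, 24.0,
        biomarker_offsets=(0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 24.0),
        inhibitor_offsets=(0.0, 1.0, 2.0, 4.0, 8.0, 12.0),
        urine_offsets=((0, 6), (6, 12), (12, 24)),
    )
    verif_times = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 24.0)
    designs["rif300"] = _rifampicin_study("rif300", 6, 300.0, verif_times,
                                          (0.5, 1.0, 2.0, 4.0, 8.0, 12.0))
    designs["rif600"] = _rifampicin_study("rif600", 6, 600.0, verif_times,
                                          (0.5, 1.0, 2.0, 4.0, 8.0, 12.0))
    return designs


def _individual_arrays(pop: PopulationParameters, etas: dict, n: int) -> dict:
    """Per-subject structural parameter arrays, typical * exp(eta)."""
    vals = {}
    for name, typ in pop.fixed.items():
        e = etas.get(name)
        vals[name] = typ * np.exp(e) if e is not None else np.full(n, typ)
    return vals


def simulate_occasion(
    occ: OccasionDesign,
    pop: PopulationParameters,
    values: dict,
    dt: float = 0.02,
    scale_oatp1b3: float = 1.0,
    scale_oat3: float = 1.0,
    use_numba: bool = True,
):
    """Model-predicted observations for every subject on one occasion.

    ``values`` maps parameter name -> (n,) array of individual values.
    Returns dict with keys among ``biomarker_plasma`` (n, P),
    ``biomarker_urine`` (n, U), ``rifampicin_plasma``/``probenecid_plasma``
    (n, Q), plus the dense grid and trajectories.
    """
    n = len(next(iter(values.values())))
    rif = pop.rifampicin()
    prob = pop.probenecid()
    extra = list(occ.biomarker_times)
    for s, e in occ.urine_intervals:
        extra += [s, e]
    grid = build_grid(occ.duration, occ.doses, rif, dt=dt, extra=extra)

    rif_doses = tuple(d for d in occ.doses if d.drug == RIFAMPICIN)
    prob_doses = tuple(d for d in occ.doses if d.drug == PROBENECID)
    if rif_doses:
        cu_rif = rif.fu * rifampicin_conc_batch(
            grid, rif_doses, values["Tlag_RIF"], values["Tk0_RIF"],
            values["V_RIF"], values["CL_RIF"], rif.MW)
    else:
        cu_rif = np.zeros((n, grid.size))
    if prob_doses:
        cu_prob = prob.fu * probenecid_conc_batch(
            grid, prob_doses, values["ka_PROB"], values["V_PROB"],
            values["CL_PROB"], prob.MW)
    else:
        cu_prob = np.zeros((n, grid.size))

    # per-subject Ki: rescale the concentration/Ki ratio via cu / (Ki_i/Ki_typ)
    ki1 = values["Ki_u_OATP1B3"] / pop.fixed["Ki_u_OATP1B3"]
    ki3 = values["Ki_u_OAT3"] / pop.fixed["Ki_u_OAT3"]
    C, A, Ah, _, _ = solve_biomarker_batch(
        grid, occ.doses,
        values["ksyn"], values["CLh"], values["CLR"], pop.fixed["Vc"],
        rif, prob,
        Cu_rif=cu_rif / ki1[:, None], Cu_prob=cu_prob / ki3[:, None],
        scale_oatp1b3=scale_oatp1b3, scale_oat3=scale_oat3,
        probenecid_occasion=bool(prob_doses), use_numba=use_numba,
    )
    out = {"grid": grid, "conc": C, "urine_cum": A, "hepatic_cum": Ah}
    if occ.biomarker_times:
        idx = np.searchsorted(grid, occ.biomarker_times)
        out["biomarker_plasma"] = C[:, idx]
    if occ.urine_intervals:
        edges = np.asarray(occ.urine_intervals, dtype=float)
        i0 = np.searchsorted(grid, edges[:, 0])
        i1 = np.searchsorted(grid, edges[:, 1])
        out["biomarker_urine"] = A[:, i1] - A[:, i0]
    if occ.inhibitor_times:
        it = np.asarray(occ.inhibitor_times, dtype=float)
        if rif_doses:
            out["rifampicin_plasma"] = rifampicin_conc_batch(
                it, rif_doses, values["Tlag_RIF"], values["Tk0_RIF"],
                values["V_RIF"], values["CL_RIF"], rif.MW)
        if prob_doses:
            out["probenecid_plasma"] = probenecid_conc_batch(
                it, prob_doses, values["ka_PROB"], values["V_PROB"],
                values["CL_PROB"], prob.MW)
    return out


def simulate_trial(
    design: StudyDesign,
    pop: PopulationParameters,
    rng: np.random.Generator,
    with_residual: bool = True,
    n_subjects: int | None = None,
    dt: float = 0.02,
    scale_oatp1b3: float = 1.0,
    scale_oat3: float = 1.0,
) -> pd.DataFrame:
    """Simulate observation records for a study.

    One eta vector per subject, shared across occasions (cross-over).
    Returns a tidy frame with columns ID, OCC, TIME, OBS, DV, USTART.
    """
    n = int(n_subjects if n_subjects is not None else design.n_subjects)
    etas = sample_etas(pop, rng, n)
    values = _individual_arrays(pop, etas, n)
    frames = []
    for occ_idx, occ in enumerate(design.occasions, start=1):
        sim = simulate_occasion(occ, pop, values, dt=dt,
                                scale_oatp1b3=scale_oatp1b3, scale_oat3=scale_oat3)
        for obs_name, times, ustart in _observation_layout(occ):
            pred = sim[obs_name]
            dv = apply_residual(pred, obs_name, pop.residual, rng) if with_residual else pred
            P = len(times)
            frames.append(pd.DataFrame({
                "ID": np.repeat(np.arange(1, n + 1), P),
                "OCC": occ_idx,
                "TIME": np.tile(times, n),
                "OBS": obs_name,
                "DV": np.asarray(dv, dtype=float).ravel(),
                "USTART": np.tile(ustart, n),
            }))
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["ID", "OCC", "TIME"], kind="stable").reset_index(drop=True)
    return df


def _observation_layout(occ: OccasionDesign):
    """Yield (observable, times, ustart) blocks defined by an occasion."""
    out = []
    if occ.biomarker_times:
        out.append(("biomarker_plasma", np.asarray(occ.biomarker_times, dtype=float),
                    np.full(len(occ.biomarker_times), np.nan)))
    if occ.urine_intervals:
        edges = np.asarray(occ.urine_intervals, dtype=float)
        out.append(("biomarker_urine", edges[:, 1], edges[:, 0]))
    if occ.inhibitor_times:
        inh = occ.inhibitor
        name = "rifampicin_plasma" if inh == RIFAMPICIN else "probenecid_plasma"
        out.append((name, np.asarray(occ.inhibitor_times, dtype=float),
                    np.full(len(occ.inhibitor_times), np.nan)))
    return out


@dataclass(frozen=True)
class NCAMetrics:
    """Non-compartmental metrics over a stated window (linear trapezoid)."""

    auc: float                 # µM·h
    ae: float | None           # µmol; None if no urine data in window
    clr_obs: float | None      # L/h; None when undefined (AUC == 0 or no urine)
    window: tuple

    @property
    def clr_defined(self) -> bool:
        return self.clr_obs is not None


def nca(records: pd.DataFrame, window: tuple) -> NCAMetrics:
    """NCA for one subject-occasion's records over ``window = (t0, t1)``.

    AUC: linear trapezoid on the plasma biomarker points inside the window
    (at least two required).  Ae: sum of urine interval amounts fully inside
    the window.  CLR_obs = Ae / AUC, undefined when AUC is 0.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("empty NCA window")
    pl = records[(records["OBS"] == "biomarker_plasma")
                 & (records["TIME"] >= t0) & (records["TIME"] <= t1)]
    if len(pl) < 2:
        raise ValueError("need at least two plasma points in the NCA window")
    pl = pl.sort_values("TIME")
    auc = float(np.trapezoid(pl["DV"].to_numpy(), pl["TIME"].to_numpy()))
    ur = records[(records["OBS"] == "biomarker_urine")
                 & (records["USTART"] >= t0) & (records["TIME"] <= t1)]
    ae = float(ur["DV"].sum()) if len(ur) else None
    clr = None
    if ae is not None and auc > 0:
        clr = ae / auc
    return NCAMetrics(auc=auc, ae=ae, clr_obs=clr, window=(float(t0), float(t1)))


def vpc(
    design: StudyDesign,
    pop: PopulationParameters,
    n_sim: int,
    rng: np.random.Generator,
    with_residual: bool = True,
    percentiles: tuple = (5.0, 50.0, 95.0),
    dt: float = 0.02,
) -> pd.DataFrame:
    """Simulated percentile bands per occasion/observable/time.

    ``n_sim`` individuals are simulated under the design's sampling grid
    (residual error included by default) and pointwise percentiles (default
    5th/50th/95th: the median and the 90% prediction interval) are returned.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for stable percentile bands")
    df = simulate_trial(design, pop, rng, with_residual=with_residual,
                        n_subjects=n_sim, dt=dt)
    rows = []
    for (occ, obs, time), g in df.groupby(["OCC", "OBS", "TIME"], sort=True):
        vals = g["DV"].to_numpy()
        row = {"OCC": occ, "OBS": obs, "TIME": time}
        for p in percentiles:
            row[f"p{p:g}"] = float(np.percentile(vals, p))
        rows.append(row)
    return pd.DataFrame(rows)
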
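"""Nonlinear mixed-effects estimation for the coupled inhibitor–biomarker models.

Estimator: Laplace-approximate marginal likelihood.  For each subject the
conditional joint density of the data and the random effects is maximised
over eta (a damped Gauss–Newton inner optimisation, vectorised across
subjects), and the marginal likelihood is approximated with the curvature
at the conditional mode:

    -log L_i  ~=  g_i(eta_hat) + 1/2 log det H_i - d/2 log(2 pi),

where ``g_i`` is the penalised data negative log-likelihood (combined
proportional/additive Gaussian residuals, diagonal log-normal random
effects) and ``H_i`` its Gauss–Newton Hessian.  Fixed effects, omegas and
sigmas are then optimised by L-BFGS-B on log-transformed coordinates
(``X`` uses ``log(X - 1)`` to respect ``X >= 1``).

Strategy: sequential (IPP).  The inhibitor PK models are fitted first to
the inhibitor plasma data (which identify them on their own); the biomarker
model is then fitted conditional on each subject's empirical-Bayes
inhibitor concentration curve.  The strategy is declared in
``FitResult.strategy``.

Relative standard errors come from the inverse observed Fisher information
(central finite differences of the outer objective).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .datasets import dataset_to_records, doses_from_dataset, validate_dataset
from .model_core import (
    PROBENECID,
    RIFAMPICIN,
    build_grid,
    probenecid_conc_batch,
    rifampicin_conc_batch,
)
from ._solver import integrate_turnover
from .population import PopulationParameters, ResidualSpec

__all__ = ["FitSpec", "FitResult", "fit_population", "individual_nll",
           "empirical_bayes", "gof"]

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
_VFLOOR = 1e-12

# parameters governed by each stage
_RIF_FIXED = ("Tlag_RIF", "Tk0_RIF", "V_RIF", "CL_RIF")
_RIF_IIV = ("Tlag_RIF", "Tk0_RIF", "CL_RIF")
_PROB_FIXED = ("ka_PROB", "V_PROB", "CL_PROB")
_PROB_IIV = ("V_PROB", "CL_PROB")
_BM_ETAS = ("ksyn", "CLR", "Ki_u_OAT3")


@dataclass
class FitSpec:
    """What to estimate and how.

    ``estimate_fixed`` / ``estimate_iiv`` / ``estimate_sigma`` override the
    data-driven defaults for the biomarker stage (None = derive from which
    observables and regimens are present).  ``fix`` holds hard parameter
    overrides applied before fitting; ``initials`` overrides starting
    values of estimated parameters.
    """

    estimate_fixed: tuple | None = None
    estimate_iiv: tuple | None = None
    estimate_sigma: tuple | None = None
    initials: dict = field(default_factory=dict)
    fix: dict = field(default_factory=dict)
    maxiter: int = 120
    inner_maxiter: int = 25
    dt: float = 0.1             # integration step used during fitting, h
    compute_rse: bool = False
    mode: str = "sequential"

    def __post_init__(self):
        for k, v in self.initials.items():
            if v <= 0:
                raise ValueError(f"initial value for {k!r} must be positive")


@dataclass
class FitResult:
    estimates: PopulationParameters
    rse: dict | None
    ofv: float
    ebes: dict                       # (dataset, subject) -> {param: eta}
    convergence: dict
    strategy: str
    estimated: dict                  # {"fixed": [...], "iiv": [...], "sigma": [...]}


# --------------------------------------------------------------------------
# generic Laplace machinery
# --------------------------------------------------------------------------

class _Block:
    """A group of subjects sharing an observation layout and predict function.

    ``predict_fn(row_values)`` maps a dict of per-row structural parameter
    arrays (length B = m * n_variants) to a list of ``(observable,
    predictions (B, P))`` blocks aligned with ``y_blocks``.
    """

    def __init__(self, name, ids, eta_names, y_blocks, predict_fn, all_params,
                 multistart=False):
        self.name = name
        self.multistart = multistart
        self.ids = list(ids)
        self.m = len(self.ids)
        self.eta_names = list(eta_names)
        self.y_blocks = y_blocks          # list of (observable, y (m, P))
        self.predict_fn = predict_fn
        self.all_params = all_params      # structural parameter names used
        self.warm_eta = np.zeros((self.m, len(self.eta_names)))
        # reference conditional modes: every outer-objective evaluation
        # starts the inner search here, so the objective is a reproducible
        # function of the outer parameters (no warm-start hysteresis)
        self.ref_eta = np.zeros((self.m, len(self.eta_names)))


def _row_values(theta: dict, block: _Block, etas: np.ndarray) -> dict:
    B = etas.shape[0]
    rv = {}
    for name in block.all_params:
        if name in block.eta_names:
            j = block.eta_names.index(name)
            rv[name] = theta[name] * np.exp(etas[:, j])
        else:
            rv[name] = np.full(B, theta[name])
    return rv


def _sigma_of(observable: str, sigmas: dict, residual: dict) -> tuple:
    spec = residual[observable]
    prop = sigmas.get(observable, spec.prop)
    return prop, spec.add


def _data_terms(preds, y_blocks, sigmas, residual):
    """Per-subject nll, d(nll)/d(pred) and GN weights for each obs block."""
    m = y_blocks[0][1].shape[0]
    g = np.zeros(m)
    dldf, wgn = [], []
    for (obs, y), (obs2, f) in zip(y_blocks, preds):
        prop, add = _sigma_of(obs, sigmas, residual)
        v = (prop * f) ** 2 + add**2 + _VFLOOR
        r = y - f
        g += 0.5 * np.sum(r * r / v + np.log(2.0 * np.pi * v), axis=1)
        dv = 2.0 * prop**2 * f
        dldf.append(-r / v + 0.5 * dv * (1.0 / v - (r * r) / (v * v)))
        wgn.append(1.0 / v + 0.5 * (dv / v) ** 2)
    return g, dldf, wgn


def _prior_terms(etas, omega_vec):
    if omega_vec.size == 0:
        return np.zeros(etas.shape[0])
    w2 = omega_vec**2
    return 0.5 * np.sum(etas**2 / w2 + np.log(2.0 * np.pi * w2), axis=1)


def _inner_laplace(block: _Block, theta, omegas, sigmas, residual,
                   maxiter=25, tol=1e-10):
    """Conditional-mode search for all subjects of a block at once.

    The conditional likelihood can be multimodal (the absorption-lag model
    has kinks where an individual lag crosses an observation time), so the
    damped Gauss-Newton search is run from two starts — the warm reference
    and the prior mode — and the better mode is kept per subject.

    Returns (g (m,), logdet (m,), eta_hat (m, d), H (m, d, d)).
    """
    d = len(block.eta_names)
    m = block.m
    if d > 0:
        start = block.warm_eta.copy()
        g1, ld1, e1, H1 = _inner_gn(block, theta, omegas, sigmas, residual,
                                    start, maxiter, tol)
        if block.multistart and np.max(np.abs(start)) > 1e-12:
            g0, ld0, e0, H0 = _inner_gn(block, theta, omegas, sigmas, residual,
                                        np.zeros((m, d)), maxiter, tol)
            better0 = g0 < g1 - 1e-12
            g1 = np.where(better0, g0, g1)
            ld1 = np.where(better0, ld0, ld1)
            e1 = np.where(better0[:, None], e0, e1)
            H1 = np.where(better0[:, None, None], H0, H1)
        block.warm_eta = e1.copy()
        return g1, ld1, e1, H1
    return _inner_gn(block, theta, omegas, sigmas, residual,
                     np.zeros((m, 0)), maxiter, tol)


def _inner_gn(block: _Block, theta, omegas, sigmas, residual, eta0,
              maxiter=25, tol=1e-10):
    d = len(block.eta_names)
    m = block.m
    if d == 0:
        preds = block.predict_fn(_row_values(theta, block, np.zeros((m, 0))))
        g, _, _ = _data_terms(preds, block.y_blocks, sigmas, residual)
        return g, np.zeros(m), np.zeros((m, 0)), np.zeros((m, 0, 0))

    omega_vec = np.array([omegas[n] for n in block.eta_names])
    omega_vec = np.maximum(omega_vec, 1e-8)
    prior_prec = 1.0 / omega_vec**2
    eta = np.asarray(eta0, dtype=float).copy()
    lam = np.full(m, 1e-3)
    fd = 1e-5

    def eval_g(etas_mat):
        preds = block.predict_fn(_row_values(theta, block, etas_mat))
        g, dldf, wgn = _data_terms(preds, block.y_blocks, sigmas, residual)
        return preds, g + _prior_terms(etas_mat, omega_vec), dldf, wgn

    _, g, _, _ = eval_g(eta)
    H = np.zeros((m, d, d))
    diag_idx = np.arange(d)
    for _it in range(maxiter):
        # batched predictions at eta and d forward perturbations
        big = np.concatenate([eta] + [eta + fd * np.eye(d)[j] for j in range(d)])
        preds_big = block.predict_fn(_row_values(theta, block, big))
        base = [(obs, p[:m]) for obs, p in preds_big]
        gb, dldf, wgn = _data_terms(base, block.y_blocks, sigmas, residual)
        g = gb + _prior_terms(eta, omega_vec)
        grad = eta * prior_prec
        H = np.zeros((m, d, d))
        H[:, diag_idx, diag_idx] = prior_prec
        for bi, (obs, p) in enumerate(preds_big):
            J = np.stack(
                [(p[(j + 1) * m:(j + 2) * m] - p[:m]) / fd for j in range(d)],
                axis=2,
            )  # (m, P, d)
            grad += np.einsum("mp,mpd->md", dldf[bi], J)
            H += np.einsum("mpd,mp,mpe->mde", J, wgn[bi], J)
        # Levenberg-damped Newton step (per-subject damping factor)
        Hd = H.copy()
        Hd[:, diag_idx, diag_idx] *= (1.0 + lam)[:, None]
        try:
            step = -np.linalg.solve(Hd, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:  # pragma: no cover - safeguarded fallback
            step = -grad / np.maximum(Hd[:, diag_idx, diag_idx], 1e-8)
        # trust bounds: eta lives on the log scale, so huge steps only ever
        # signal a flat likelihood; cap them instead of overflowing exp()
        step = np.clip(step, -2.0, 2.0)
        eta_try = np.clip(eta + step, -10.0, 10.0)
        step = eta_try - eta
        _, g_try, _, _ = eval_g(eta_try)
        improved = g_try <= g + 1e-12
        eta = np.where(improved[:, None], eta_try, eta)
        lam = np.where(improved, np.maximum(lam / 4.0, 1e-6), lam * 8.0)
        # a subject is done when its accepted step no longer moves eta or g;
        # a rejected step only raises its damping and earns another round
        dg_subj = np.where(improved, g - g_try, np.inf)
        step_size = np.where(improved, np.max(np.abs(step), axis=1), np.inf)
        g = np.where(improved, g_try, g)
        done = (dg_subj < tol) | (step_size < 1e-9)
        stuck = ~improved & (lam > 1e8)   # damping exhausted: local minimum
        if np.all(done | stuck):
            break

    sign, logdet = np.linalg.slogdet(H)
    if np.any(sign <= 0):
        # fall back to the damped matrix to keep the objective finite
        Hd = H.copy()
        Hd[:, np.arange(d), np.arange(d)] += 1e-6
        sign, logdet = np.linalg.slogdet(Hd)
    return g, logdet, eta, H


def _laplace_total(blocks, theta, omegas, sigmas, residual, inner_maxiter,
                   inner_tol=1e-9):
    total = 0.0
    for block in blocks:
        d = len(block.eta_names)
        g, logdet, _, _ = _inner_laplace(block, theta, omegas, sigmas, residual,
                                         maxiter=inner_maxiter, tol=inner_tol)
        total += float(np.sum(g + 0.5 * logdet - 0.5 * d * _LOG2PI))
    return total


# --------------------------------------------------------------------------
# parameter packing
# --------------------------------------------------------------------------

def _to_x(name, value, kind):
    if kind == "fixed" and name == "X":
        return np.log(max(value - 1.0, 1e-6))
    return np.log(value)


def _from_x(name, x, kind):
    if kind == "fixed" and name == "X":
        return 1.0 + np.exp(x)
    return float(np.exp(x))


class _Packing:
    def __init__(self, fixed_names, iiv_names, sigma_names, pop: PopulationParameters):
        self.fixed_names = list(fixed_names)
        self.iiv_names = list(iiv_names)
        self.sigma_names = list(sigma_names)
        self.pop = pop

    @property
    def n(self):
        return len(self.fixed_names) + len(self.iiv_names) + len(self.sigma_names)

    def x0(self, initials: dict):
        xs = []
        for n in self.fixed_names:
            xs.append(_to_x(n, initials.get(n, self.pop.fixed[n]), "fixed"))
        for n in self.iiv_names:
            xs.append(_to_x(n, initials.get(f"omega_{n}", self.pop.iiv[n]), "iiv"))
        for n in self.sigma_names:
            xs.append(_to_x(n, initials.get(f"sigma_{n}", self.pop.residual[n].prop), "sigma"))
        return np.array(xs)

    def bounds(self, x0):
        bounds = []
        i = 0
        for _ in self.fixed_names:
            bounds.append((x0[i] - np.log(50.0), x0[i] + np.log(50.0)))
            i += 1
        for _ in self.iiv_names:
            bounds.append((np.log(5e-3), np.log(2.5)))
            i += 1
        for _ in self.sigma_names:
            bounds.append((np.log(1e-2), np.log(1.5)))
            i += 1
        return bounds

    def unpack(self, x):
        theta = dict(self.pop.fixed)
        omegas = dict(self.pop.iiv)
        sigmas = {}
        i = 0
        for n in self.fixed_names:
            theta[n] = _from_x(n, x[i], "fixed")
            i += 1
        for n in self.iiv_names:
            omegas[n] = _from_x(n, x[i], "iiv")
            i += 1
        for n in self.sigma_names:
            sigmas[n] = _from_x(n, x[i], "sigma")
            i += 1
        return theta, omegas, sigmas

    def rse_from_cov(self, cov, x):
        rse = {}
        i = 0
        for n in self.fixed_names:
            se_x = np.sqrt(max(cov[i, i], 0.0))
            if n == "X":
                xval = 1.0 + np.exp(x[i])
                rse[n] = 100.0 * np.exp(x[i]) * se_x / xval
            else:
                rse[n] = 100.0 * se_x
            i += 1
        for n in self.iiv_names:
            rse[f"omega_{n}"] = 100.0 * np.sqrt(max(cov[i, i], 0.0))
            i += 1
        for n in self.sigma_names:
            rse[f"sigma_{n}"] = 100.0 * np.sqrt(max(cov[i, i], 0.0))
            i += 1
        return rse


_OBJ_SCALE = 0.02   # scales the nll so the first L-BFGS-B trial step stays local


def _optimize(blocks, packing, residual, spec: FitSpec):
    cache = {}
    best = [np.inf]

    def objective(x):
        key = x.tobytes()
        if key in cache:
            return cache[key]
        theta, omegas, sigmas = packing.unpack(x)
        for b in blocks:
            b.warm_eta = b.ref_eta.copy()
        val = _laplace_total(blocks, theta, omegas, sigmas, residual,
                             spec.inner_maxiter)
        if not np.isfinite(val):
            val = 1e12
        if val < best[0]:
            best[0] = val
            for b in blocks:
                b.ref_eta = b.warm_eta.copy()
        cache[key] = val
        return val

    def fresh(x):
        """Deterministic re-evaluation from the frozen reference modes
        (no cache, no reference update); used for the observed information."""
        theta, omegas, sigmas = packing.unpack(x)
        for b in blocks:
            b.warm_eta = b.ref_eta.copy()
        val = _laplace_total(blocks, theta, omegas, sigmas, residual,
                             spec.inner_maxiter)
        return val if np.isfinite(val) else 1e12

    def scaled(x):
        return _OBJ_SCALE * objective(x)

    x0 = packing.x0(spec.initials)
    opts = {"maxiter": spec.maxiter, "ftol": 1e-12, "gtol": 1e-6,
            "eps": 1e-4, "maxfun": 20000}
    res = scipy.optimize.minimize(scaled, x0, method="L-BFGS-B",
                                  bounds=packing.bounds(x0), options=opts)
    if not res.success and res.nit < max(10, spec.maxiter // 6):
        # a line-search stall this early means the search never left the
        # neighbourhood of the start; restart once with a fresh Hessian
        # (late stalls are near-converged and not worth a second pass)
        res2 = scipy.optimize.minimize(scaled, res.x, method="L-BFGS-B",
                                       bounds=packing.bounds(x0), options=opts)
        if res2.fun <= res.fun:
            res = res2
    res.fun = res.fun / _OBJ_SCALE
    return res, objective, fresh


def _fd_hessian(fun, x, h=5e-2):
    p = x.size
    H = np.empty((p, p))
    f0 = fun(x)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h
        fpp = fun(x + ei); fmm = fun(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h**2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = h
            fa = fun(x + ei + ej); fb = fun(x + ei - ej)
            fc = fun(x - ei + ej); fd_ = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fa - fb - fc + fd_) / (4.0 * h**2)
    return H


def _covariance(objective, x):
    H = _fd_hessian(objective, x)
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        return cov, True
    except np.linalg.LinAlgError:
        logger.warning("observed information not positive definite; RSE from pseudo-inverse")
        return np.linalg.pinv(H), False


# --------------------------------------------------------------------------
# dataset parsing into blocks
# --------------------------------------------------------------------------

class _StudyData:
    """Uniform-layout view of one dataset: per occasion, the regimen and the
    (subjects x times) observation matrices per observable."""

    def __init__(self, name: str, df: pd.DataFrame):
        df = validate_dataset(df)
        self.name = name
        records = dataset_to_records(df)
        self.ids = sorted(records["ID"].unique())
        self.m = len(self.ids)
        self.occasions = {}
        for occ in sorted(records["OCC"].unique()):
            occ = int(occ)
            doses = doses_from_dataset(df, occ)
            obs = {}
            sub = records[records["OCC"] == occ]
            for name_, g in sub.groupby("OBS"):
                times = np.sort(g[g["ID"] == self.ids[0]]["TIME"].unique())
                y = np.empty((self.m, times.size))
                ustart = None
                for i, sid in enumerate(self.ids):
                    gi = g[g["ID"] == sid].sort_values("TIME")
                    if not np.array_equal(gi["TIME"].to_numpy(), times):
                        raise ValueError(
                            f"{self.name}: observation times for subject {sid}, "
                            f"occasion {occ}, observable {name_} do not match the "
                            "shared layout; per-subject layouts are not supported")
                    y[i] = gi["DV"].to_numpy()
                    if name_ == "biomarker_urine":
                        ustart = gi["USTART"].to_numpy()
                obs[name_] = {"times": times, "y": y, "ustart": ustart}
            self.occasions[occ] = {"doses": doses, "obs": obs}

    @property
    def has_rif(self):
        return any(d.drug == RIFAMPICIN for o in self.occasions.values() for d in o["doses"])

    @property
    def has_prob(self):
        return any(d.drug == PROBENECID for o in self.occasions.values() for d in o["doses"])

    @property
    def has_urine(self):
        return any("biomarker_urine" in o["obs"] for o in self.occasions.values())

    def duration(self, occ) -> float:
        o = self.occasions[occ]
        t = [0.0]
        for ob in o["obs"].values():
            t.append(float(ob["times"].max()))
        t.extend(d.time for d in o["doses"])
        return max(t)


def _stage1_blocks(studies, pop, drug):
    """(study, block) pairs for every occasion with inhibitor plasma data."""
    blocks = []
    obs_name = "rifampicin_plasma" if drug == RIFAMPICIN else "probenecid_plasma"
    for st in studies:
        for occ, o in st.occasions.items():
            if obs_name not in o["obs"]:
                continue
            times = o["obs"][obs_name]["times"]
            y = o["obs"][obs_name]["y"]
            doses = tuple(d for d in o["doses"] if d.drug == drug)
            if drug == RIFAMPICIN:
                mw = pop.constants.get("MW_RIF", 822.94)

                def predict_fn(rv, times=times, doses=doses, mw=mw):
                    return [(obs_name, rifampicin_conc_batch(
                        times, doses, rv["Tlag_RIF"], rv["Tk0_RIF"],
                        rv["V_RIF"], rv["CL_RIF"], mw))]

                eta_names = [n for n in _RIF_IIV if pop.iiv.get(n, 0) > 0]
                all_params = list(_RIF_FIXED)
            else:
                mw = pop.constants.get("MW_PROB", 285.36)

                def predict_fn(rv, times=times, doses=doses, mw=mw):
                    return [(obs_name, probenecid_conc_batch(
                        times, doses, rv["ka_PROB"], rv["V_PROB"],
                        rv["CL_PROB"], mw))]

                eta_names = [n for n in _PROB_IIV if pop.iiv.get(n, 0) > 0]
                all_params = list(_PROB_FIXED)
            blocks.append((st, _Block(f"{st.name}/occ{occ}/{obs_name}", st.ids,
                                      eta_names, [(obs_name, y)], predict_fn,
                                      all_params, multistart=True)))
    return blocks


def _stage2_block(st: _StudyData, pop, inhibitor_values, dt):
    """Biomarker block for one study, conditional on per-subject inhibitor
    parameter values (stage-1 EBEs)."""
    rif_t = pop.rifampicin()
    prob_t = pop.probenecid()
    fu_rif = pop.constants.get("fu_RIF", 0.10)
    fu_prob = pop.constants.get("fu_PROB", 0.10)
    occ_data = []
    y_blocks = []
    for occ in sorted(st.occasions):
        o = st.occasions[occ]
        obs = o["obs"]
        bm_obs = [(k, v) for k, v in obs.items() if k.startswith("biomarker")]
        if not bm_obs:
            continue
        extra = []
        for k, v in bm_obs:
            extra.extend(v["times"].tolist())
            if v["ustart"] is not None:
                extra.extend(v["ustart"].tolist())
        dur = st.duration(occ)
        # long multi-day occasions evolve on the inhibitor PK timescale
        # (hours); a coarser grid there keeps the fit cost bounded
        grid = build_grid(dur, o["doses"], rif_t,
                          dt=(dt if dur <= 48 else 2.0 * dt), extra=extra)
        rif_doses = tuple(d for d in o["doses"] if d.drug == RIFAMPICIN)
        prob_doses = tuple(d for d in o["doses"] if d.drug == PROBENECID)
        G = grid.size
        if rif_doses:
            cu_rif = fu_rif * rifampicin_conc_batch(
                grid, rif_doses,
                inhibitor_values["Tlag_RIF"], inhibitor_values["Tk0_RIF"],
                inhibitor_values["V_RIF"], inhibitor_values["CL_RIF"], rif_t.MW)
        else:
            cu_rif = np.zeros((st.m, G))
        if prob_doses:
            cu_prob = fu_prob * probenecid_conc_batch(
                grid, prob_doses,
                inhibitor_values["ka_PROB"], inhibitor_values["V_PROB"],
                inhibitor_values["CL_PROB"], prob_t.MW)
        else:
            cu_prob = np.zeros((st.m, G))
        gather = []
        for k, v in bm_obs:
            if k == "biomarker_plasma":
                gather.append((k, np.searchsorted(grid, v["times"]), None))
            else:
                gather.append((k, np.searchsorted(grid, v["times"]),
                               np.searchsorted(grid, v["ustart"])))
            y_blocks.append((k, v["y"]))
        occ_data.append({
            "grid": grid, "cu_rif": cu_rif, "cu_prob": cu_prob,
            "prob_occ": bool(prob_doses), "gather": gather,
        })

    vc = pop.fixed["Vc"]
    ki3_typ = pop.fixed["Ki_u_OAT3"]
    m = st.m

    def predict_fn(rv):
        B = rv["ksyn"].shape[0]
        K = B // m
        out = []
        for od in occ_data:
            cu_r = np.tile(od["cu_rif"], (K, 1))
            cu_p = np.tile(od["cu_prob"], (K, 1))
            x_eff = rv["X"][:, None] if od["prob_occ"] else 1.0
            mh = 1.0 / (x_eff * (1.0 + cu_r / rv["Ki_u_OATP1B3"][:, None]))
            if od["prob_occ"]:
                mr = 1.0 / (1.0 + cu_p / rv["Ki_u_OAT3"][:, None])
            else:
                mr = np.ones_like(cu_p)
            C, A, _ = integrate_turnover(rv["ksyn"], rv["CLh"], rv["CLR"], vc,
                                         mh, mr, od["grid"])
            for k, idx, idx0 in od["gather"]:
                if k == "biomarker_plasma":
                    out.append((k, C[:, idx]))
                else:
                    out.append((k, A[:, idx] - A[:, idx0]))
        return out

    eta_names = []
    if pop.iiv.get("ksyn", 0) > 0:
        eta_names.append("ksyn")
    if pop.iiv.get("CLR", 0) > 0:
        eta_names.append("CLR")
    if pop.iiv.get("Ki_u_OAT3", 0) > 0 and any(od["prob_occ"] for od in occ_data):
        eta_names.append("Ki_u_OAT3")
    all_params = ["ksyn", "CLh", "CLR", "Ki_u_OATP1B3", "Ki_u_OAT3", "X"]
    return _Block(f"{st.name}/biomarker", st.ids, eta_names, y_blocks,
                  predict_fn, all_params)


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def _as_studies(datasets) -> list:
    if isinstance(datasets, pd.DataFrame):
        datasets = {"study": datasets}
    if isinstance(datasets, (list, tuple)):
        datasets = {f"study{i+1}": df for i, df in enumerate(datasets)}
    return [_StudyData(name, df) for name, df in datasets.items()]


def fit_population(datasets, pop: PopulationParameters, spec: FitSpec | None = None) -> FitResult:
    """Fit the coupled models to one or more datasets (sequential strategy).

    ``datasets``: a dataset frame, list of frames, or dict name -> frame in
    the dialect of :mod:`gcdcas_pk.datasets`.  ``pop`` supplies the model
    structure, constants, starting values and fixed (non-estimated) values.
    """
    spec = spec or FitSpec()
    studies = _as_studies(datasets)
    if not studies:
        raise ValueError("no datasets supplied")
    pop = _apply_overrides(pop, spec.fix)

    convergence = {}
    rse = {} if spec.compute_rse else None
    total_ofv = 0.0
    theta_hat = dict(pop.fixed)
    omega_hat = dict(pop.iiv)
    sigma_hat = {k: v.prop for k, v in pop.residual.items()}
    ebes = {}

    # ---- stage 1: inhibitor PK models --------------------------------
    inhibitor_values = {}   # study name -> per-subject structural values
    for st in studies:
        inhibitor_values[st.name] = {
            n: np.full(st.m, pop.fixed[n])
            for n in (*_RIF_FIXED, *_PROB_FIXED)
        }
    for drug, fixed_names, iiv_names, obs_name in (
        (RIFAMPICIN, _RIF_FIXED, _RIF_IIV, "rifampicin_plasma"),
        (PROBENECID, _PROB_FIXED, _PROB_IIV, "probenecid_plasma"),
    ):
        with_data = [st for st in studies
                     if any(obs_name in o["obs"] for o in st.occasions.values())]
        if not with_data:
            continue
        pairs = _stage1_blocks(with_data, pop, drug)
        blocks = [b for _, b in pairs]
        iiv_est = [n for n in iiv_names if pop.iiv.get(n, 0) > 0]
        packing = _Packing(fixed_names, iiv_est, [obs_name], pop)
        res, objective, fresh = _optimize(blocks, packing, pop.residual, spec)
        theta, omegas, sigmas = packing.unpack(res.x)
        for n in fixed_names:
            theta_hat[n] = theta[n]
        for n in iiv_est:
            omega_hat[n] = omegas[n]
        sigma_hat[obs_name] = sigmas[obs_name]
        total_ofv += 2.0 * res.fun
        convergence[f"stage1_{drug}"] = {
            "success": bool(res.success), "iterations": int(res.nit),
            "message": str(res.message),
        }
        if spec.compute_rse:
            cov, ok = _covariance(fresh, res.x)
            stage_rse = packing.rse_from_cov(cov, res.x)
            if not ok:
                stage_rse = {k: np.nan for k in stage_rse}
            rse.update(stage_rse)
        # EBEs at the optimum -> per-subject inhibitor parameter values
        for st, block in pairs:
            g, logdet, eta, H = _inner_laplace(block, theta, omegas,
                                               {obs_name: sigmas[obs_name]},
                                               pop.residual)
            for j, n in enumerate(block.eta_names):
                inhibitor_values[st.name][n] = theta[n] * np.exp(eta[:, j])
            for n in fixed_names:
                if n not in block.eta_names:
                    inhibitor_values[st.name][n] = np.full(st.m, theta[n])
            for i, sid in enumerate(st.ids):
                ebes.setdefault((st.name, sid), {}).update(
                    {n: float(eta[i, j]) for j, n in enumerate(block.eta_names)})

    # ---- stage 2: biomarker model -------------------------------------
    pop_s1 = _with_params(pop, theta_hat, omega_hat, sigma_hat)
    blocks2 = [
        _stage2_block(st, pop_s1, inhibitor_values[st.name], spec.dt)
        for st in studies
    ]
    any_rif = any(st.has_rif for st in studies)
    any_prob = any(st.has_prob for st in studies)
    any_urine = any(st.has_urine for st in studies)

    if spec.estimate_fixed is not None:
        fixed_names = list(spec.estimate_fixed)
    else:
        fixed_names = ["ksyn"]
        if any_rif:
            # CLh is identified by the hepatic-inhibition dynamics; without
            # an OATP1B3-inhibitor arm it is held at its configured value
            # (baseline and urine data only constrain ksyn/(CLh+CLR) and CLR)
            fixed_names += ["CLh", "Ki_u_OATP1B3"]
        if any_urine:
            fixed_names.append("CLR")
        if any_prob:
            fixed_names += ["Ki_u_OAT3", "X"]
    fixed_names = [n for n in fixed_names if n not in pop.not_estimated]
    if spec.estimate_iiv is not None:
        iiv_names = list(spec.estimate_iiv)
    else:
        iiv_names = [n for n in ("ksyn",) if pop.iiv.get(n, 0) > 0]
        if any_urine and pop.iiv.get("CLR", 0) > 0:
            iiv_names.append("CLR")
        if any_prob and pop.iiv.get("Ki_u_OAT3", 0) > 0:
            iiv_names.append("Ki_u_OAT3")
    if spec.estimate_sigma is not None:
        sigma_names = list(spec.estimate_sigma)
    else:
        sigma_names = ["biomarker_plasma"]
        if any_urine:
            sigma_names.append("biomarker_urine")

    packing2 = _Packing(fixed_names, iiv_names, sigma_names, pop_s1)
    res2, objective2, fresh2 = _optimize(blocks2, packing2, pop_s1.residual, spec)
    theta, omegas, sigmas = packing2.unpack(res2.x)
    theta_hat.update({n: theta[n] for n in fixed_names})
    omega_hat.update({n: omegas[n] for n in iiv_names})
    sigma_hat.update({n: sigmas[n] for n in sigma_names})
    total_ofv += 2.0 * res2.fun
    convergence["stage2_biomarker"] = {
        "success": bool(res2.success), "iterations": int(res2.nit),
        "message": str(res2.message),
    }
    if spec.compute_rse:
        cov, ok = _covariance(fresh2, res2.x)
        stage_rse = packing2.rse_from_cov(cov, res2.x)
        if not ok:
            stage_rse = {k: np.nan for k in stage_rse}
        rse.update(stage_rse)

    for block, st in zip(blocks2, studies):
        g, logdet, eta, H = _inner_laplace(block, theta, omegas, sigmas,
                                           pop_s1.residual)
        for i, sid in enumerate(st.ids):
            ebes.setdefault((st.name, sid), {}).update(
                {n: float(eta[i, j]) for j, n in enumerate(block.eta_names)})

    estimates = _with_params(pop, theta_hat, omega_hat, sigma_hat)
    ok_all = all(c["success"] for c in convergence.values())
    return FitResult(
        estimates=estimates,
        rse=rse,
        ofv=total_ofv,
        ebes=ebes,
        convergence={"status": "converged" if ok_all else "maxiter", **convergence},
        strategy=("sequential: inhibitor PK fitted to inhibitor plasma data, "
                  "biomarker model fitted conditional on individual inhibitor "
                  "concentration curves (EBEs)"),
        estimated={"fixed": fixed_names, "iiv": iiv_names, "sigma": sigma_names},
    )


def _apply_overrides(pop: PopulationParameters, fix: dict) -> PopulationParameters:
    if not fix:
        return pop
    fixed = dict(pop.fixed)
    iiv = dict(pop.iiv)
    for k, v in fix.items():
        if k.startswith("omega_"):
            name = k[len("omega_"):]
            if v == 0:
                iiv.pop(name, None)
            else:
                iiv[name] = v
        else:
            fixed[k] = v
    return PopulationParameters(fixed=fixed, iiv=iiv, residual=dict(pop.residual),
                                constants=dict(pop.constants),
                                not_estimated=pop.not_estimated)


def _with_params(pop: PopulationParameters, theta, omegas, sigmas) -> PopulationParameters:
    residual = {}
    for k, v in pop.residual.items():
        residual[k] = ResidualSpec(prop=float(sigmas.get(k, v.prop)), add=v.add,
                                   add_fixed=v.add_fixed)
    return PopulationParameters(
        fixed={k: float(theta.get(k, v)) for k, v in pop.fixed.items()},
        iiv={k: float(omegas.get(k, v)) for k, v in pop.iiv.items()},
        residual=residual, constants=dict(pop.constants),
        not_estimated=pop.not_estimated,
    )


def _single_subject_block(df: pd.DataFrame, pop: PopulationParameters, dt=0.05):
    studies = _as_studies(df)
    if len(studies) != 1 or studies[0].m != 1:
        raise ValueError("expected a dataset for exactly one subject")
    st = studies[0]
    vals = {n: np.full(1, pop.fixed[n]) for n in (*_RIF_FIXED, *_PROB_FIXED)}
    return _stage2_block(st, pop, vals, dt)


def individual_nll(df_subject: pd.DataFrame, eta: dict, pop: PopulationParameters,
                   dt: float = 0.05) -> float:
    """Penalised negative log-likelihood of one subject's biomarker data at a
    given eta (typical inhibitor PK)."""
    block = _single_subject_block(df_subject, pop, dt)
    etas = np.array([[eta.get(n, 0.0) for n in block.eta_names]])
    preds = block.predict_fn(_row_values(dict(pop.fixed), block, etas))
    sigmas = {k: v.prop for k, v in pop.residual.items()}
    g, _, _ = _data_terms(preds, block.y_blocks, sigmas, pop.residual)
    omega_vec = np.array([pop.iiv[n] for n in block.eta_names])
    return float(g[0] + _prior_terms(etas, omega_vec)[0])


def empirical_bayes(df_subject: pd.DataFrame, pop: PopulationParameters,
                    dt: float = 0.05) -> dict:
    """MAP estimate of one subject's biomarker random effects.

    With no observations the conditional posterior equals the prior, whose
    mode is eta = 0 (returned as an empty mapping)."""
    if (df_subject["EVID"] == 0).sum() == 0:
        return {}
    block = _single_subject_block(df_subject, pop, dt)
    if not block.y_blocks:
        return {}
    sigmas = {k: v.prop for k, v in pop.residual.items()}
    _, _, eta, _ = _inner_laplace(block, dict(pop.fixed), dict(pop.iiv),
                                  sigmas, pop.residual)
    return {n: float(eta[0, j]) for j, n in enumerate(block.eta_names)}


def gof(df: pd.DataFrame, fit: FitResult, dt: float = 0.05) -> pd.DataFrame:
    """Observation table with population/individual predictions and residuals.

    PRED: prediction at eta = 0; IPRED: at the subject's EBE; WRES/IWRES:
    residuals weighted by the residual-error SD at the respective
    prediction.  Covers every observable; the record count is preserved.
    """
    pop = fit.estimates
    studies = _as_studies(df)
    rows = []
    for st in studies:
        vals = {n: np.full(st.m, pop.fixed[n]) for n in (*_RIF_FIXED, *_PROB_FIXED)}
        # use inhibitor EBEs when available
        for i, sid in enumerate(st.ids):
            for n, e in fit.ebes.get((st.name, sid), {}).items():
                if n in vals:
                    vals[n][i] = pop.fixed[n] * np.exp(e)
        block = _stage2_block(st, pop, vals, dt)
        d = len(block.eta_names)
        eta0 = np.zeros((st.m, d))
        eta_hat = np.zeros((st.m, d))
        for i, sid in enumerate(st.ids):
            for j, n in enumerate(block.eta_names):
                eta_hat[i, j] = fit.ebes.get((st.name, sid), {}).get(n, 0.0)
        preds0 = block.predict_fn(_row_values(dict(pop.fixed), block, eta0))
        preds1 = block.predict_fn(_row_values(dict(pop.fixed), block, eta_hat))
        pairs = [(block.y_blocks, preds0, preds1)]

        # inhibitor plasma records: closed-form predictions at the typical
        # (PRED) and EBE-adjusted (IPRED) inhibitor parameters
        typ = {n: np.full(st.m, pop.fixed[n]) for n in (*_RIF_FIXED, *_PROB_FIXED)}
        for occ in sorted(st.occasions):
            o = st.occasions[occ]
            for obs_name, drug, fn, pnames in (
                ("rifampicin_plasma", RIFAMPICIN, rifampicin_conc_batch,
                 ("Tlag_RIF", "Tk0_RIF", "V_RIF", "CL_RIF")),
                ("probenecid_plasma", PROBENECID, probenecid_conc_batch,
                 ("ka_PROB", "V_PROB", "CL_PROB")),
            ):
                if obs_name not in o["obs"]:
                    continue
                ob = o["obs"][obs_name]
                doses = tuple(d for d in o["doses"] if d.drug == drug)
                mw = (pop.constants.get("MW_RIF", 822.94) if drug == RIFAMPICIN
                      else pop.constants.get("MW_PROB", 285.36))
                f0 = fn(ob["times"], doses, *(typ[n] for n in pnames), mw)
                f1 = fn(ob["times"], doses, *(vals[n] for n in pnames), mw)
                pairs.append(([(obs_name, ob["y"])], [(obs_name, f0)],
                              [(obs_name, f1)]))

        for y_blocks, p0, p1 in pairs:
            for (obs, y), (_, f0), (_, f1) in zip(y_blocks, p0, p1):
                spec = pop.residual[obs]
                sd0 = np.sqrt((spec.prop * f0) ** 2 + spec.add**2 + _VFLOOR)
                sd1 = np.sqrt((spec.prop * f1) ** 2 + spec.add**2 + _VFLOOR)
                for i, sid in enumerate(st.ids):
                    for p in range(y.shape[1]):
                        rows.append({
                            "dataset": st.name, "ID": sid, "OBS": obs,
                            "DV": y[i, p], "PRED": f0[i, p], "IPRED": f1[i, p],
                            "RES": y[i, p] - f0[i, p],
                            "WRES": (y[i, p] - f0[i, p]) / sd0[i, p],
                            "IWRES": (y[i, p] - f1[i, p]) / sd1[i, p],
                        })
    return pd.DataFrame(rows)
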
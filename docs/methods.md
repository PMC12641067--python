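# Methods

`gcdcas_pk` implements a population-pharmacokinetic analysis of
glycochenodeoxycholic acid 3-*O*-sulfate (GCDCA-S), an endogenous bile-acid
sulfate used as a plasma/urine biomarker of the hepatic uptake transporter
OATP1B3 and the renal secretory transporter OAT3.  The package covers the
full analysis cycle: the structural and statistical models, simulation of
the three clinical cross-over designs that inform the model, nonlinear
mixed-effects estimation on such data, verification simulations, and the
simulation-based power analysis for prospective DDI studies.

## Structural model

GCDCA-S disposition is a turnover (indirect-response) model: zero-order
synthesis `ksyn` (µmol/h) into a central volume `Vc` (L), with first-order
hepatobiliary (`CLh`, L/h) and renal (`CLR`, L/h) clearances:

    dC/dt = [ ksyn − C·CLh·mh(t) − C·CLR·mr(t) ] / Vc
    dA/dt = C·CLR·mr(t)

where `C` (µM) is the plasma concentration, `A` (µmol) the cumulative
amount in urine, and `mh`, `mr` competitive-inhibition multipliers driven
by the unbound inhibitor concentrations:

    mh(t) = 1 / [ X_eff · (1 + Y1·Cu_RIF(t)/Ki_u_OATP1B3) ]
    mr(t) = 1 / (1 + Y3·Cu_PROB(t)/Ki_u_OAT3)

Rifampicin (OATP1B3 inhibitor) follows a one-compartment model with lag
time, zero-order absorption and linear elimination; probenecid (OAT3
inhibitor) a one-compartment model with first-order absorption (Bateman
superposition over its multiple-dose regimen; the degenerate `ka = k` case
uses the analytic `t·e^{−kt}` limit).  Probenecid additionally reduces
hepatic clearance by a fixed fold `X ≥ 1` while on treatment (`X_eff = X`
on probenecid occasions, 1 otherwise), reflecting its weak OATP1B
inhibition.  `Y1`/`Y3` are hypothetical-inhibitor potency scales (1 for the
fitted drugs); scaling Y is equivalent to dividing Ki.

The pre-treatment initial condition is the steady state
`C(0) = ksyn/(CLh+CLR)` = 0.0653 µM at the default parameters, consistent
with the observed study baselines (64–87 nM).  The default parameter set
(`default_population()`) is the final estimate table of the source
analysis: `ksyn` 1.0 µmol/h, `Vc` 4.8 L (fixed), `CLh` 15 L/h, `CLR`
0.31 L/h, `Ki_u_OATP1B3` 0.009 µM, `Ki_u_OAT3` 2.7 µM, `X` 1.7, with the
inhibitor PK parameters listed in `population.py`.  The fraction excreted
in urine is `CLR/(CLh+CLR)` ≈ 2%, i.e. biliary elimination dominates
(~98%).  Enterohepatic recirculation, diurnal synthesis fluctuation and
precursor (GCDCA) kinetics are deliberately out of scope: bile-acid
sulfates undergo limited intestinal reabsorption, and diurnal/covariate
terms did not survive model selection in the source analysis.

### Unit-conversion assumptions

Doses in mg are converted to µmol with MW 822.94 (rifampicin) and 285.36
(probenecid) g/mol.  The unbound fractions that turn total plasma
concentrations into the `Cu` driving inhibition are not part of the
published estimate table and are package-level constants:

* `fu_PROB = 0.10` — a typical literature value for probenecid.
* `fu_RIF = 0.10` — calibrated, not assumed: with the published parameters
  the model's verification predictions (population-median AUCR(0–24 h)
  after single-dose rifampicin) are printed as 13 (600 mg) and 9.3
  (300 mg).  `fu_RIF` is the only unknown in reproducing those two numbers,
  and 0.10 matches both simultaneously (12.6 and 9.7 in this
  implementation), while lying inside the literature plasma-protein-binding
  range for rifampicin (~84–91% bound).  Sensitivity (median AUCR at
  600/300 mg, 1000 individuals):

  | fu_RIF | 0.05 | 0.10 | 0.15 | 0.20 |
  |--------|------|------|------|------|
  | 600 mg | 9.7  | 12.6 | 14.3 | 15.5 |
  | 300 mg | 7.0  | 9.7  | 11.4 | 12.6 |

  Both constants are config-overridable (`constants` in the population
  parameter set).

## Numerical solution of the turnover ODE

The ODE is linear with a time-varying elimination coefficient.  The solver
(`_solver.integrate_turnover`) freezes the coefficient at its interval mean
on each grid step and applies the exact exponential update, then splits the
per-step eliminated amount (which is exact by construction,
`ksyn·Δt − Vc·ΔC`) between the renal and hepatic routes in proportion to
their mean conductances.  Consequences:

* mass balance `ksyn·T = Vc·ΔC + A_hepatic + A_renal` holds to machine
  precision at any step size;
* an uninhibited run stays exactly at baseline (steady-state preservation);
* the trajectory is second-order accurate; against an adaptive
  `solve_ivp` oracle the error is ≲0.1% at the default steps.

Grids carry breakpoints at every dose time and at the zero-order absorption
window boundaries.  Because `Ki_u_OATP1B3` (0.009 µM) is ~3 orders of
magnitude below peak unbound rifampicin, the hepatic multiplier collapses
within milliseconds of absorption onset; the grid refines geometrically
inside the absorption window to resolve this.  Default steps: 0.02 h for
simulation, 0.1 h during estimation (0.2 h for the 168-h occasions, whose
dynamics evolve on the much slower inhibitor-PK timescale).  The integrator
is vectorised over individuals (and JIT-compiled when numba is available,
with an identical pure-numpy fallback), which is what makes the power
calculation (~10^5 subject-occasions) and the replicate re-estimation
studies desk-scale.

## Statistical model

Individual parameters are log-normal, `theta_i = theta·exp(eta_i)`,
`eta ~ N(0, ω²)`, with IIV on `V_PROB, CL_PROB, Ki_u_OAT3, Tlag_RIF,
Tk0_RIF, CL_RIF, ksyn, CLR` (between-subject only; occasions within a
subject share etas, matching the cross-over analyses).  Reported IIV
percentages are interpreted as `100·ω` — the common reporting convention of
NLME estimation software; the exact-CV convention
`ω = sqrt(ln(1+cv²))` is available through `cv_to_omega(..., "exact")`.
Residual error is proportional(+additive): 45% (biomarker plasma), 29%
(biomarker urine), 23% + 0.001 µM fixed (probenecid), 20% + 0.2 µM fixed
(rifampicin).  Simulated negative observations are floored at zero (logged);
at these error magnitudes flooring affects ~1% of biomarker plasma records.

## Study designs and synthetic data

Three cross-over designs drive model development, mirroring the published
study tables: study 1 (n=6, 24 h, single 600 mg rifampicin on occasion 2,
plasma only), study 2 (n=6, 168 h sampling, probenecid 500 mg at 6 pm/11 pm
on day 0 then 7 am/1 pm/6 pm/11 pm on days 1–7, plasma + interval urine)
and study 3 (n=12, 24 h, same regimen, plasma + urine); `rif300`/`rif600`
are the single-dose verification designs.  Probenecid occasions start at
the first evening dose; sampling begins 13 h later (7 am day 1), so the
sampling day carries realistic carry-over.  Exact clock times of the
plasma samples and urine intervals are not published; the defaults
reproduce the published record counts (e.g. 48 plasma records per occasion
in study 1, 108/36 plasma/urine in study 3) and are configurable per
`OccasionDesign`.  The synthetic generator writes the dataset in a
NONMEM-style CSV dialect plus a JSON sidecar holding the generating
parameters and seed.

What the generator emulates: the designs, log-normal IIV, shared etas
across occasions, proportional residual error, interval urine collection.
What it does not: diurnal baseline fluctuation (observed intra-individual
CV 34–43%), food effects, the probe-drug cocktail and NCE co-medication,
dropout/BLQ handling, or real assay error structure.  Passing tests
therefore demonstrate internal consistency of the method under the model's
own assumptions, not robustness to these real-data features.

## Estimation

`fit_population` maximises a Laplace-approximate marginal likelihood.
Inner problem: per-subject penalised least squares over eta, solved by a
damped Gauss–Newton iteration vectorised across subjects, with
finite-difference prediction Jacobians; the Laplace correction uses the
Gauss–Newton (expected-information) Hessian.  The conditional likelihood of
the rifampicin model is multimodal in eta (kinks where an individual lag
time crosses an observation time), so the inner search there runs from two
starts (warm reference and prior mode) and keeps the better mode.  Outer
problem: L-BFGS-B on log-transformed parameters (`X` via `log(X−1)`),
objective scaled so the first line-search step stays local; every
evaluation starts the inner search from a frozen reference to keep the
objective a reproducible function of the outer parameters.

The strategy is sequential (IPP): inhibitor PK models are fitted first to
the inhibitor plasma data, which identify them on their own; the biomarker
model is then fitted conditional on each subject's empirical-Bayes
inhibitor concentration curve.  This is declared in `FitResult.strategy`.
Estimated by default: `ksyn`, `CLh` + `Ki_u_OATP1B3` (when a rifampicin arm
is present), `CLR` (when urine is present), `Ki_u_OAT3` + `X` (when
probenecid is present), the corresponding omegas, and the proportional
sigmas; `Vc` is fixed at 4.8 L for identifiability, and the additive
inhibitor sigmas are fixed.  Without an OATP1B3-inhibition arm, `CLh` is
held at its configured value: baseline and urine data only constrain
`ksyn/(CLh+CLR)` and `CLR`, because the turnover time constant
(`Vc/(CLh+CLR)` ≈ 0.3 h) is far below the sampling resolution.

Uncertainty: relative standard errors from the inverse observed Fisher
information, central finite differences (step 0.05 on the log scale — wide
enough to average over the residual non-smoothness that the mode selection
induces) of the outer objective at the optimum, delta-method for `X`.
Degenerate information matrices are flagged and reported as unavailable
rather than silently pseudo-inverted.

Simulation–re-estimation at the default truth (10 replicates of the
three-study ensemble) recovers the disposition parameters with medians
within ~10% and the inhibition constants within their published
uncertainty; the acceptance script reproduces this end to end.

## Verification simulations and VPC

`vpc` returns the median and 90% prediction interval (5th/95th simulated
percentiles) of every observable on the design's sampling grid, following
the verification procedure of the source analysis (5000 simulated
individuals per group there; `n_sim` is caller-chosen here).  The
individual-level clinical observations and the digitized external
verification profiles are not redistributable, so the package verifies
against the *published summary predictions* instead: the population-median
AUCR(0–24 h) under 600/300 mg rifampicin (13 / 9.3).

## Power analysis

Hypothetical inhibitors follow rifampicin (OATP1B3) or probenecid (OAT3)
PK with the I/Ki ratio scaled by Y ∈ [0.001, 1] (OATP1B3) or [0.01, 1]
(OAT3).  Per replicate trial of n subjects (n = 5…30): simulate paired
control/treatment occasions with shared etas and residual error on; metric:
within-subject plasma AUCR(0–24 h) (OATP1B3, study-1-like design) or
CLR-ratio `Ae/AUC` over the 24-h collection window (OAT3, study-3-like
design); test: two-sided one-sample t-test of the mean log-ratio against 0
(the published description does not state sidedness; two-sided is the
conservative choice).  Power = rejection fraction over 1000 replicates at
α = 0.01 and 0.05.  The "required" sample size is the smallest tested n
with power ≥ 80% — the conventional threshold; none is printed in the
source.  Type-I error calibration (power ≈ α at Y = 0) is part of the test
suite.

One caveat the implementation makes explicit: with the unbound-exposure
scale pinned by the verification predictions, a Y = 0.05 OATP1B3 inhibitor
produces a median AUCR of ~2.9 — a moderate-magnitude interaction — and the
paired cross-over design (in which shared random effects cancel from the
within-subject ratio) detects it with 5 subjects.  Obtaining a larger
required sample size for this case would need either a substantially lower
unbound exposure (incompatible with the verification AUCRs) or
between-occasion variability that the published model does not contain.

The synthesis-rate sensitivity analysis (`ksyn_perturbation`) exploits the
linearity of the turnover model in `ksyn`: scaling `ksyn` scales plasma AUC
and urine amount by the same factor, so plasma AUC is maximally sensitive
to synthesis changes while `CLR_obs = Ae/AUC` is exactly invariant — the
in-model statement of why an inhibitor that also perturbs biomarker
synthesis biases AUCR-based DDI classification but not the renal-clearance
metric.

## Problem sizes and reproducibility

All randomness flows from explicit `numpy.random.Generator` seeds; the
acceptance script derives independent child streams from a single `--seed`
via `SeedSequence.spawn`.  Default problem sizes: 1000 individuals for the
verification medians, 1000 replicate trials per sample size for power,
10 replicate ensembles for simulation–re-estimation (medians), one
representative replicate for the RSE report.  The test suite runs scaled
versions of the same checks (300 power replicates, 4 re-estimation
replicates) with correspondingly widened Monte-Carlo tolerances.

## Known limitations

* The Laplace/Gauss–Newton estimator carries a small finite-sample bias at
  the large proportional-error magnitudes of this model (a few percent on
  the inhibition constants in the replicate studies); a stochastic-EM
  estimator would reduce it at substantially higher cost.
* Sequential (IPP) fitting ignores the (weak) information the biomarker
  data carry about inhibitor PK parameters, and conditions on shrunken
  inhibitor exposures.
* The rifampicin absorption model's likelihood is only piecewise smooth;
  its reported RSEs are averaged over that roughness and are the least
  reliable part of the uncertainty report.
* `fu_RIF` is a calibrated constant, not an estimate; all DDI magnitudes
  scale with it (sensitivity table above).
* Urine collection intervals and exact sampling clocks are reconstructed
  from record counts, not published protocols.
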
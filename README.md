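# gcdcas-pk

Population pharmacokinetics of **glycochenodeoxycholic acid 3-O-sulfate
(GCDCA-S)**, an endogenous bile-acid sulfate used as a biomarker of the
hepatic uptake transporter **OATP1B3** and the renal secretory transporter
**OAT3**.  The package is aimed at pharmacometricians and clinical
pharmacologists who want to simulate, fit, and design transporter
drug–drug-interaction (DDI) studies that monitor GCDCA-S in plasma and
urine instead of dosing a probe drug.

## The model

GCDCA-S follows a turnover model — zero-order synthesis, first-order
hepatobiliary and renal elimination — coupled to closed-form PK models of
two perpetrator drugs:

```
dC/dt = [ k_syn − C·CL_h·m_h(t) − C·CL_R·m_r(t) ] / V_c
dA/dt = C·CL_R·m_r(t)                      (amount in urine)

m_h = 1 / [ X_eff·(1 + C_u,RIF/K_i,u,OATP1B3) ]     (hepatic uptake)
m_r = 1 / (1 + C_u,PROB/K_i,u,OAT3)                 (renal secretion)
```

Rifampicin (single oral dose; one compartment, lagged zero-order
absorption) inhibits OATP1B3-mediated hepatic clearance; probenecid
(multiple 500 mg doses; one compartment, first-order absorption) inhibits
OAT3-mediated renal clearance and reduces hepatic clearance by a fixed
fold `X` while on treatment.  Baseline plasma concentration is
`k_syn/(CL_h+CL_R)`; at the default estimates (`k_syn` = 1.0 µmol/h,
`CL_h` = 15 L/h, `CL_R` = 0.31 L/h, `V_c` = 4.8 L) that is 0.065 µM, and
~98% of elimination is biliary.  Individual parameters are log-normal;
residual error is proportional(+additive).  See `docs/methods.md` for the
full account, including the calibrated rifampicin unbound-fraction
assumption.

Modules: `model_core` (structural models and ODE solver), `population`
(IIV and residual error), `trial_sim` (study designs, trial simulation,
NCA, VPC), `estimation` (Laplace NLME fitting), `power` (DDI power
calculation and synthesis-rate sensitivity), `synthetic` (study
generators), `datasets`/`config`/`cli` (NONMEM-style CSV dialect, YAML
config, command line).

## Worked example

Simulate the single-dose rifampicin verification design and predict the
biomarker's plasma AUC ratio, then size a DDI study for a weak inhibitor:

```python
import numpy as np
from gcdcas_pk import default_population, builtin_designs
from gcdcas_pk.population import sample_etas
from gcdcas_pk.trial_sim import simulate_occasion, _individual_arrays
from gcdcas_pk.power import PowerScenario, power_curve

pop = default_population()
rng = np.random.default_rng(1)
values = _individual_arrays(pop, sample_etas(pop, rng, 1000), 1000)

design = builtin_designs()["rif600"]
control, treated = design.occasions
t = np.asarray(treated.biomarker_times)
auc_c = np.trapezoid(simulate_occasion(control, pop, values)["biomarker_plasma"], t, axis=1)
auc_t = np.trapezoid(simulate_occasion(treated, pop, values)["biomarker_plasma"], t, axis=1)
print(f"median AUCR after 600 mg rifampicin: {np.median(auc_t/auc_c):.1f}")

grid = power_curve(PowerScenario(target="OATP1B3", y=0.05, sample_sizes=(5, 10, 15),
                                 alphas=(0.01,), replicates=500),
                   np.random.default_rng(2), pop)
print(grid.table[["n", "power"]].to_string(index=False))
print("subjects needed:", grid.minimal_n(alpha=0.01))
```

Output:

```
median AUCR after 600 mg rifampicin: 12.6
 n  power
 5  0.958
10  1.000
15  1.000
subjects needed: 5
```

A median AUCR of ~13 means a rifampicin-strength OATP1B3 inhibitor raises
GCDCA-S plasma exposure about thirteen-fold over 24 h — a large, easily
detected signal.  Even a 20-fold weaker inhibitor (`y = 0.05`, median AUCR
~2.9) is detected with 5 subjects in a paired cross-over at α = 0.01,
because the within-subject design cancels the large between-subject
baseline variability from the AUC ratio (see `docs/methods.md` for the
variability assumptions behind this).

The same workflows are available from the shell:

```bash
gcdcas-pk generate --design study3 --seed 1 --out data/
gcdcas-pk fit data/dataset.csv --seed 1 --out fit/
gcdcas-pk power --target OAT3 --y 1.0 --n 5 --n 10 --alpha 0.01 \
    --replicates 1000 --seed 7 --out power/
gcdcas-pk vpc --design rif600 --n-sim 5000 --seed 3 --out vpc/
```

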
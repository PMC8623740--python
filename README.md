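# dtmdd — double central–peripheral TMDD population pharmacokinetics

`dtmdd` is a Python package for population pharmacokinetic modelling of
infliximab, an anti-TNF-α monoclonal antibody, in inflammatory bowel disease
(IBD). Its core is a two-compartment model with **target-mediated drug
disposition (TMDD) in both the central and the peripheral compartment**
under the quasi-steady-state (QSS) approximation: in each compartment the
unbound drug concentration is the non-negative root of

```
C² + (R_T + K_SS − C_T)·C − K_SS·C_T = 0,
```

and the four ODE states (total drug C_T, C_PT and total target R_TC, R_TP,
all in nM) evolve with linear two-compartment disposition plus
first-order elimination of the drug–target complex (k_int per compartment)
and target turnover (k_in = R₀·k_out, shared k_out fixed at 20/day).
Target blockade is summarised by the occupancy ratio
R/R_T = K_SS/(K_SS + C).

The package is aimed at pharmacometricians who want a fully testable,
self-contained reimplementation of this analysis: structural model and
simulator, nonlinear mixed-effects (NLME) estimation with Laplace/FOCE-type
marginal likelihood, AIC model ladders and kout grid profiling, two-stage
covariate screening, VPC/NPDE diagnostics, a synthetic-trial generator that
emulates the two source study designs (a rich ankylosing-spondylitis
reference cohort with linear kinetics, and a sparse routine IBD cohort), and
the population target-occupancy simulation study. See `docs/methods.md` for
the full model description and numerical choices.

## Worked example

```python
import numpy as np
from dtmdd import (final_model_params, typical_params, SubjectCovariates,
                   DoseEvent, simulate_profile, terminal_half_life)

pop = final_model_params()                      # published final estimates
typ = typical_params(pop, SubjectCovariates(BW=66.0))   # female, CD, 66 kg

sec = terminal_half_life(V1=2.8, V2=1.9, CL=0.20, Q=1.5)
print(f"terminal half-life {sec.t_half_beta:.1f} days")

doses = [DoseEvent(7.0 * w, 330.0) for w in (0, 2, 6, 14, 22)]  # 5 mg/kg
traj = simulate_profile(typ, doses, np.arange(0.0, 210.0, 0.1))
i14, i22 = 979, 1539                            # just before doses 4 and 5
print(f"week-14 trough: {traj.conc_mgL[i14]:.1f} mg/L, "
      f"central occupancy ratio {traj.ratio_C[i14]:.2f}, "
      f"peripheral {traj.ratio_P[i14]:.3f}")
print(f"max total central target fold: {traj.RTC_nM.max() / typ.R0C:.1f}")
```

prints

```
terminal half-life 16.7 days
week-14 trough: 8.3 mg/L, central occupancy ratio 0.22, peripheral 0.011
max total central target fold: 27.5
```

— the linear backbone eliminates with a ~17-day half-life; at the week-14
trough the central target is already escaping blockade (unbound/total ratio
22%) while the peripheral target remains almost fully occupied (1.1%); and
total central target accumulates ~28-fold over baseline because the
drug–target complex clears much more slowly than free target turns over.

Fitting and simulation at population level:

```python
from dtmdd import generate_joint_dataset, TMDDModel, IBD_RICH
from dtmdd.model import FINAL_COVARIATE_EFFECTS

ds = generate_joint_dataset(final_model_params(), 25, 125, seed=1,
                            ibd_design=IBD_RICH)
model = TMDDModel(ds, variant="double_tmdd", kout=20.0,
                  covariate_effects=FINAL_COVARIATE_EFFECTS)
res = model.fit()
print(res.summary())          # estimates, -2LL, AIC, convergence
res.vpc(n_reps=1000, seed=1)  # visual predictive check table
res.npde(n_reps=1000, seed=1) # normalized prediction distribution errors

from dtmdd.diagnostics import write_report
write_report(res, "diagnostics/")  # CSV tables + GOF/VPC/NPDE figure
```

A thin CLI mirrors the main workflows:

```bash
dtmdd generate --design mixed --n 150 --seed 1 --out study.csv
dtmdd fit --data study.csv --variant dtmdd --kout 20 --covariates --out fit/
dtmdd occupancy --n 1000 --seed 1 --out occ/
dtmdd simulate --bw 66 --out typical.csv
```

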
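# fosfopk

Population pharmacokinetics of intravenous and oral fosfomycin in
neonates with suspected sepsis: a reusable, tested implementation of the
full analysis pipeline — structural model, covariate models, nonlinear
mixed-effects estimation, trial simulation, design power, and
pharmacodynamic target attainment.

## Who this is for

Pharmacometricians and trial statisticians who want to (i) simulate
neonatal fosfomycin exposure for dose selection, (ii) re-estimate the
model on new or simulated data with a transparent FOCEI/Laplace engine,
or (iii) evaluate sparse-sampling trial designs by simulation.

## The model

Fosfomycin disposition is linear and renally cleared. The model is a
four-compartment system — depot (oral absorption, first order, rate
constant *K*ₐ, bioavailability *F*), central (*V*₂, clearance CL),
peripheral (*V*₃, inter-compartmental clearance *Q*₁) and CSF (*V*₄,
*Q*₂) — with the observed CSF concentration scaled by the CSF/plasma
partition ratio UPTK, so that at distributional steady state
CSF/plasma = UPTK.

All disposition parameters are centred on a fully mature 70 kg
individual. Individual typical values follow

- allometric weight scaling: CLᵢ = CL·(WT/70)^0.75, Vᵢ = V·(WT/70);
- sigmoid renal maturation in postmenstrual age:
  PMA^3.4 / (47.7^3.4 + PMA^3.4), multiplying CL;
- a postnatal-age function on CL:
  θ_M + (1 − θ_M)(1 − e^(−PNA·θ_N)), the fraction of clearance on the
  first day of life rising asymptotically to 1;
- a CSF-protein effect on UPTK applied on the logit scale, centred at
  the population median protein of 0.94 g/L.

Between-subject variability is log-normal on CL and *V*₂ and
logit-normal on *F*; residual error is proportional for plasma (separate
IV and oral magnitudes) and additive for CSF. The shipped reference
parameter set (`fosfopk.reference_parameters()`) carries the final
published estimates (CL 8.94 L/h/70 kg, *V*₂ 19.1 L/70 kg, UPTK 0.321,
*F* 0.478, …).

Estimation uses a conditional-mode (empirical Bayes) expansion of each
subject's marginal likelihood: FOCEI (the default, Gauss–Newton
curvature with residual variance at individual predictions) or a full
Laplace second-order expansion. Both are validated against adaptive
Gauss–Hermite quadrature.

## Worked example

Simulate a sparse cross-over trial (60 neonates, 100 mg/kg q12h IV for
four doses then oral crossover, two plasma samples per route each) and
refit the model:

```python
import numpy as np
import fosfopk as fp
from fosfopk.estimation import shrinkage

pop = fp.reference_parameters()
rng = np.random.default_rng(123)
demo = fp.sample_neofosfo_demographics(60, rng)
trial = fp.make_trial(demo, rng)                 # doses + sample times
data = fp.simulate_cohort(pop, demo, trial, seed=rng)

result = fp.fit(pop, data, max_evals=1500)
print(result.summary().head(7).to_string(index=False))
print("OFV:", round(result.ofv, 1))
print({k: round(float(v), 1) for k, v in shrinkage(result).items()})
```

```
parameter  estimate       se   rse_pct
   cl_std 10.099023 3.664130 36.282030
   v2_std 18.077991 1.054499  5.833054
   q1_std 10.178535 3.148082 30.928636
   v3_std  8.082425 0.959287 11.868802
     uptk  0.329400 0.025795  7.830900
       ka  0.125865 0.034266 27.224359
        f  0.432952 0.072008 16.631859
OFV: 2250.7
{'eta_cl': 4.6, 'eta_v2': 14.7, 'eta_f': 98.6}
```

Central volume (18.1 L/70 kg), the CSF/plasma ratio (0.33, informed by
the fifteen opportunistic CSF samples) and bioavailability (0.43)
recover the generating values (19.1, 0.321, 0.478) within their
standard errors. The standardized clearance estimate carries a wide CI
on any single trial of this design — 60 neonates observe CL only
through the maturation model, and extrapolating to a mature 70 kg
individual inflates the uncertainty — but its replicate-median centres
near the generating 8.94 L/h/70 kg (see the reproduction script below).
The clearance random effect shows almost no shrinkage (4.6%) while the
bioavailability effect is heavily shrunk: two oral samples per subject
carry little individual-level information on F. Phase half-lives of
the disposition system for a mature 70 kg adult:

```bash
$ fosfopk half-life --weight 70
alpha phase half-life: 0.42 h
beta phase half-life: 2.29 h
gamma phase half-life: 6.13 h
```

The beta phase (2.3 h) is the clinically relevant plasma half-life; the
slow gamma phase is introduced by the small, slowly equilibrating CSF
compartment.

The command-line interface exposes the same pipeline:
`fosfopk make-trial | simulate | fit | vpc | bootstrap | ta | power |
half-life` (see `fosfopk --help`).

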
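# Methods

This note records the modelling and numerical choices behind `fosfopk`,
the assumptions they rest on, and what the test suite does and does not
establish.

## Structural model

Amounts in four compartments — depot (1), central (2), peripheral (3),
CSF (4) — evolve under a constant linear rate matrix. IV doses are
instantaneous boluses into the central compartment (the clinical "slow
push" has no reported duration, so no infusion model is used). Oral
doses enter the depot multiplied by the bioavailable fraction F, so
oral exposure scales exactly with F, and are absorbed first order.
Elimination is first order from the central compartment (CL/V2).

The CSF compartment exchanges with the central compartment by a
symmetric concentration-driven flow Q2·(A2/V2 − A4/V4), and the
*observed* CSF concentration is UPTK·A4/V4. This choice is not forced —
the source analysis does not print the CSF differential equation — but
it is the one under which (i) the steady-state CSF/plasma concentration
ratio equals UPTK exactly (verified to 1e-6 in the tests), and (ii) the
published adult phase half-lives (0.4, 2.3, 6.1 h) are reproduced
exactly by eigenvalue analysis of the disposition matrix at the
published parameter values.

The published typical-*neonate* half-life triple (0.2, 5.2, 8.7 h) is
**not** reproduced by this model: with maturation applied to CL only
and allometry to Q1/Q2, the median trial neonate computes to
0.21/2.7/5.2 h. No scaling variant we tried (maturation on Q2, various
allometric conventions) yields 8.7 h while preserving the adult triple.
We treat the neonatal triple as non-verifiable and exclude it from the
checked quantities; the adult triple, which the same source calls the
reference for clinical interpretation, is the anchor.

Between events the system is propagated analytically in the eigenbasis
of the rate matrix. Eigenvalues of this mammillary-plus-depot system
are real and negative; parameter draws for which the eigenvector matrix
becomes ill-conditioned (ka colliding with a disposition rate — the
condition number is checked against 1e9) fall back to a
matrix-exponential propagation per event. The batched cohort path
(`compile_design`/`predict_design`) keeps the per-subject state in the
eigenbasis so each event step is element-wise; this is what makes the
replicate estimation studies tractable in pure numpy.

Steady state for repeated dosing uses the closed-form periodic solution
z = (I − e^{Mτ})⁻¹ b in the eigenbasis; the tests verify it against
brute-force repeated dosing to a < 0.1% trough-to-trough change. The
fraction of the interval above a MIC is computed on a fixed 0.05 h grid
with linear interpolation at threshold crossings.

## Covariate models

- Allometric scaling: exponent 0.75 on CL, Q1, Q2; 1 on volumes;
  centred on 70 kg.
- PMA renal maturation (Hill sigmoid, coefficient 3.4, half-maturation
  47.7 weeks, both fixed biological priors) and the postnatal-age
  function θ_M + (1−θ_M)(1−e^(−PNA·θ_N)) multiply **CL only**. Q1 and
  Q2 receive allometry only. This is the variant that reproduces the
  adult half-lives (see above).
- The serum-creatinine covariate (measured SCR standardised by the
  age-typical creatinine curve, power coefficient θ_SCR) is implemented
  for model-comparison workflows but inactive (θ_SCR fixed at 0) in the
  final configuration, which retained PNA instead.
- CSF protein perturbs the logit of UPTK linearly, centred at the
  population median 0.94 g/L; a missing protein measurement defaults to
  the median, making the covariate term vanish (protein was only
  available for 12 of 15 CSF subjects in the source trial).
- Units: PNA in days in the maturation function and in years (365.25
  days/year) in the creatinine curve; PMA in weeks; PMA = GA + PNA/7 is
  enforced to 1e-9 when both ages are supplied.

## Variability model

IIV is log-normal on CL and V2 and logit-normal on F (every simulated F
lies in (0,1)). The published CL and V2 variabilities are %CV values and
are stored as ω = √ln(1+CV²); the F variability (0.269) is reported
directly as a logit-scale standard deviation and used as such. Residual
error is proportional for plasma with separate IV-phase and oral-phase
magnitudes — phase assignment follows the route of the most recent dose
at the sample time — and additive for CSF. Simulated concentrations
below zero are floored at zero with a logged count; values below the
assay quantification limits (5 mg/L plasma, 1 mg/L CSF) are flagged but
never censored, since no study sample was below the limit.

## Estimation

The marginal likelihood of each subject integrates over η = (η_CL,
η_V2, η_F). Both engines first locate the conditional mode η̂ by a
batched Newton search: forward-difference Jacobian (step 1e-4, the
base point and all probes evaluated in a single stacked solve),
per-subject backtracking line search in which already-converged
subjects — gradient below a practical floor of 1e-3, set by the
finite-difference bias — never gate the others, and a warm start from
the previous outer iterate with a per-subject reset to zero whenever
the carried start is worse than zero (guarding against poisoning by
extreme outer iterates). Iteration stops when every subject's gradient
is below the floor or the largest η move falls under 1e-6; at that
point the residual mode error contributes O(curvature × 1e-12) to the
OFV, far below the comparison tolerances used anywhere in the suite. The OFV is −2·log of the Laplace
approximation at η̂ including all 2π constants, so it is directly
comparable with quadrature:

- **focei** (default): curvature JᵀR⁻¹J + Ω⁻¹ with the residual
  variance R evaluated at the individual predictions (the
  "interaction"). This matches the estimation method of the source
  analysis and is cheapest.
- **laplace**: curvature from a central finite-difference Hessian of
  the joint deviance.
- **foce**: the no-interaction variant (R at the typical predictions),
  for comparison only.

Both focei and laplace agree with 64-node adaptive Gauss–Hermite
quadrature to well under 0.5 OFV units on 1- and 2-η problems (the
suite's gating check; observed differences ≈ 0.07 and 0.02).

The outer problem optimises the free population parameters on an
unconstrained scale (log for positive parameters, logit for fractions,
identity for the protein coefficient) with L-BFGS-B. The structural
constants Q2, V4, the Hill coefficient and TM50 are always fixed, as is
θ_SCR. Numerical settings that matter:

- outer finite-difference gradient step 1e-3 on the transformed scale.
  The warm-started inner modes leave ~1e-6 OFV units of path
  dependence; a smaller step turns that into gradient noise larger than
  the signal near the optimum (we observed optimizer stalls with step
  1e-5), while the ~1e-3-relative bias this step induces in the located
  optimum is far below the sampling spread of any parameter.
- relative function tolerance 1e-6, projected-gradient tolerance 0.05
  OFV units.
- standard errors from a central finite-difference Hessian of the OFV
  (relative step 1e-2, each probe re-started from the optimum's inner
  modes so path dependence cannot enter the differences), covariance
  2H⁻¹ mapped to the natural scale by the delta method. Eigenvalues of
  the Hessian are floored at 1e-6 of the leading eigenvalue: a
  direction the data do not inform (typically ω_F under two oral
  samples per subject) then yields a very large standard error confined
  to itself instead of contaminating every parameter through the
  matrix inverse.

Model comparison uses the likelihood-ratio drop thresholds 6.64 (p<0.01)
and 3.84 (p<0.05) per degree of freedom, strict inequalities. Shrinkage
is 100·(1 − SD(η̂)/ω) with the sample SD. The bootstrap resamples
subjects (never observations) with replacement and refits; the VPC
simulates replicate datasets on the original design and compares
observed 2.5/50/97.5th percentiles per nominal-time bin ({0.083, 0.5,
1, 2, 4, 8} h post-dose, split by IV/oral phase; CSF pooled into one
median-only bin) with the 95% interval of the same statistics across
simulations.

## Synthetic data

No subject-level data from the source trial are public, so the
generators emulate its published design and marginal demographic
summaries; all joint structure is a modelling choice:

- **Trial cohort** (n=60 default): GA truncated-normal (mean 40.0, SD
  1.78, range 34.4–44.0 weeks); PNA a zero-heavy discrete mixture
  (P(0)=0.25, P(1)=0.30, remainder 2+geometric, truncated at 23 days)
  matching median 1 and mean ≈2.7 days; weight log-normally regressed
  on GA (2.805 kg at 40 weeks, slope 0.105/week, residual CV 12%, range
  1.56–5.67 kg); CSF protein log-normal (median 0.94 g/L, σ=0.45,
  truncated); SCR log-normal (σ=0.30) around the age-typical curve.
- **Broad simulation population** (n=10,000 default): GA
  truncated-normal (mean 37.8, SD 5.5 on 23–44 weeks, median ≈37); PNA
  an equal mixture of two geometrics (means 4 and 17 days, truncated at
  59) matching median 5 and mean ≈10.4; weight regressed on GA (2.5 kg
  at 37 weeks, slope 0.13/week, σ=0.15, range 0.4–5.17 kg). This
  population deliberately includes pre-term and <1500 g neonates — an
  explicit extrapolation beyond the trial's inclusion criteria.

The trial builder randomises one early ({0.083, 0.5, 1} h) and one late
({2, 4, 8} h) plasma sample per route per subject, places four IV doses
(q12h from 0 h) and four oral doses (q12h from 48 h), and gives a
quarter of subjects one CSF sample, split 1:2 between the IV and oral
phases (emulating 5/10 of 15). Attrition (two subjects lost before
crossover) and a day-7 sample are optional flags, off by default.

Because only marginal summaries are matched, the generators do not
reproduce the unpublished joint demographic distribution; quantities
that depend on it (exact target-attainment percentile values) are
checked qualitatively, not numerically. Passing the recovery tests
shows the estimator is consistent under the *assumed* joint structure,
not that the real trial's estimates would be reproduced.

## Replicate studies and problem sizes

- **Recovery study**: 20 replicate 60-subject trials, full final model
  re-estimated (structural constants fixed), refits started from the
  generating values — the usual convention for simulation
  re-estimation. Medians across replicates are compared with the
  published bootstrap 95% CIs.
- **Power study**: 50 replicate 45-subject trials, plasma-only design
  (the CSF substudy was opportunistic and is not part of the design
  question). The refits condition on the structural backbone — Ka, Q1,
  V3, the CSF submodel and the maturation coefficients held at their
  population values — and estimate CL, V2, F, their variabilities and
  the residual errors. A replicate succeeds when the asymptotic 95% CI
  half-width is ≤20% of the estimate for all of CL, V2 and F; we report
  per-parameter and joint success fractions. Rationale: a design-stage
  precision calculation asks how well the design determines its target
  parameters under an assumed model; freeing the absorption constant
  turns the question into one of structural identifiability (the Ka–F
  correlation inflates F's CI half-width to 22–31% of the estimate with
  only two oral samples per subject) that no 45-subject version of this
  design can answer.
- VPC self-consistency uses 10 observed replicates × 400 simulations;
  the shipped default for a single VPC is 1000 simulations.

These sizes keep a full run of the replicate studies in the tens of
minutes on a single core while leaving Monte-Carlo error well inside
the tolerances being checked.

## Known limitations

- Under the sparse two-plus-two-samples cross-over design, the ML
  estimates of Ka and F have strongly skewed finite-sample
  distributions (the Ka–F "flip-flop" ridge: a lower absorption rate
  with higher bioavailability fits almost as well, and individual
  replicates can land on either side). Replicate medians of Ka and F
  can therefore sit 10–20% from the generating values even though each
  refit maximises the exact marginal likelihood — we verified on
  replicate datasets that adaptive-quadrature likelihoods improve by
  the same margin at the FOCEI optima, and that the Laplace engine
  reproduces the same estimates. This is a property of the design, not
  of the estimator implementation.

- No inter-occasion variability, no covariance between η_F and the
  disposition ηs, no time-varying covariates within a subject, no
  nonlinear elimination, no protein-binding correction (fosfomycin
  plasma protein binding is negligible).
- Ka carries no IIV in the final configuration (none was reported),
  which understates uncertainty in oral profile *shape*; the machinery
  supports adding it.
- The estimation engine provides FOCEI/Laplace only — no SAEM or
  importance sampling — and its covariance step is a finite-difference
  approximation, not a replication of any particular software's
  covariance machinery.
- CSF target attainment is not computed (plasma targets only), and no
  pharmacodynamic kill model is included.
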
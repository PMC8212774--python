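"""Synthetic trial designs and demographic populations.

The trial generator emulates a neonatal cross-over design: 100 mg/kg IV
q12h for four doses from t = 0, conversion to oral 100 mg/kg q12h at
48 h, one randomised early ({0.083, 0.5, 1} h post-dose) and one late
({2, 4, 8} h) plasma sample after the first dose of each route, and an
opportunistic CSF sample in roughly a quarter of subjects.

Two demographic generators are provided, each matched to published
marginal summaries (median/range and mean/IQR) of its source cohort:
the trial cohort itself (term and near-term neonates, median weight
2805 g) and a broader observational neonatal population (including
pre-term and <1500 g subjects, median weight 2500 g) used for
simulation work. Only marginal summaries are published, so the joint
structure is a modelling choice: weight is regressed on gestational age
with a log-normal residual, postnatal age is a right-skewed discrete
mixture, and CSF protein and serum creatinine are log-normal (the
latter centred on the age-typical creatinine curve).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import (
    DAYS_PER_YEAR,
    SubjectCovariates,
    typical_serum_creatinine,
)
from .structural_model import CMT_CENTRAL, CMT_CSF, CMT_DEPOT, EventTable

__all__ = [
    "TrialDesign",
    "sample_neofosfo_demographics",
    "sample_hypothetical_population",
    "make_trial",
    "power_study",
    "EARLY_SAMPLE_TIMES",
    "LATE_SAMPLE_TIMES",
]

logger = logging.getLogger(__name__)

EARLY_SAMPLE_TIMES = (0.083, 0.5, 1.0)
LATE_SAMPLE_TIMES = (2.0, 4.0, 8.0)


@dataclass(frozen=True)
class PopulationSummary:
    """Median/range/mean/IQR of one covariate across a population."""

    median: float
    minimum: float
    maximum: float
    mean: float
    iqr_low: float
    iqr_high: float

    def __post_init__(self):
        ordered = (self.minimum, self.iqr_low, self.median, self.iqr_high, self.maximum)
        if any(a > b + 1e-12 for a, b in zip(ordered, ordered[1:])):
            raise ValueError(f"summary order statistics are inconsistent: {ordered}")


def summarize_demographics(covs) -> dict:
    """Per-covariate :class:`PopulationSummary` for a generated cohort."""
    arrays = {
        "weight": np.array([c.weight for c in covs]),
        "gestational_age": np.array([c.gestational_age for c in covs], dtype=float),
        "postnatal_age": np.array([c.postnatal_age for c in covs]),
        "postmenstrual_age": np.array([c.postmenstrual_age for c in covs]),
        "csf_protein": np.array(
            [c.csf_protein for c in covs if c.csf_protein is not None]
        ),
    }
    out = {}
    for name, x in arrays.items():
        if x.size == 0 or np.isnan(x).all():
            continue
        out[name] = PopulationSummary(
            median=float(np.median(x)),
            minimum=float(x.min()),
            maximum=float(x.max()),
            mean=float(x.mean()),
            iqr_low=float(np.percentile(x, 25)),
            iqr_high=float(np.percentile(x, 75)),
        )
    return out


@dataclass(frozen=True)
class TrialDesign:
    """Design rules for the cross-over PK trial.

    Defaults reproduce the study protocol: 100 mg/kg q12h, at least four
    IV doses over 48 h, then oral crossover at the same dose; two plasma
    samples per route per subject at randomised early/late times; a CSF
    sample in ``csf_fraction`` of subjects split 1:2 between the IV and
    oral phases. ``attrition`` optionally removes the oral phase for two
    subjects (the study lost two babies before crossover); the day-7
    sample is off by default.
    """

    dose_mg_per_kg: float = 100.0
    interval_h: float = 12.0
    n_iv_doses: int = 4
    oral_start_h: float = 48.0
    n_oral_doses: int = 4
    csf_fraction: float = 0.25
    csf_iv_phase_fraction: float = 1.0 / 3.0
    day7_sample: bool = False
    attrition: int = 0

    def __post_init__(self):
        if self.dose_mg_per_kg <= 0 or self.interval_h <= 0:
            raise ValueError("dose and interval must be positive")
        if not 0 <= self.csf_fraction <= 1:
            raise ValueError("csf_fraction must lie in [0, 1]")


def _truncated_normal(rng, loc, scale, low, high, size):
    """Rejection-sampled truncated normal (vectorised, seed-stable)."""
    out = rng.normal(loc, scale, size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(loc, scale, bad.sum())
        bad = (out < low) | (out > high)
    return out


def _truncated_lognormal(rng, median, sigma, low, high, size):
    out = median * np.exp(rng.normal(0.0, sigma, size))
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = median * np.exp(rng.normal(0.0, sigma, bad.sum()))
        bad = (out < low) | (out > high)
    return out


def _weight_from_ga(rng, ga, ref_ga, ref_kg, slope, sigma, low_kg, high_kg):
    """Log-normal weight regressed on GA (residual CV ~= sigma)."""
    w = ref_kg * np.exp(slope * (ga - ref_ga) + rng.normal(0.0, sigma, ga.shape))
    bad = (w < low_kg) | (w > high_kg)
    while bad.any():
        w[bad] = ref_kg * np.exp(
            slope * (ga[bad] - ref_ga) + rng.normal(0.0, sigma, bad.sum())
        )
        bad = (w < low_kg) | (w > high_kg)
    return w


def _scr_from_pna(rng, pna_days, sigma=0.30):
    pna_years = np.maximum(pna_days, 0.5) / DAYS_PER_YEAR
    return typical_serum_creatinine(pna_years) * np.exp(rng.normal(0.0, sigma, pna_days.shape))


def _assemble(ids, wt, ga, pna, scr, pr) -> list[SubjectCovariates]:
    out = []
    for i in range(len(ids)):
        out.append(
            SubjectCovariates(
                weight=float(wt[i]),
                gestational_age=float(ga[i]),
                postnatal_age=float(pna[i]),
                serum_creatinine=float(scr[i]),
                csf_protein=float(pr[i]),
                subject_id=int(ids[i]),
            )
        )
    return out


def sample_neofosfo_demographics(n: int, seed=None) -> list[SubjectCovariates]:
    """Covariates for ``n`` neonates matching the trial cohort summaries.

    Term and near-term babies: GA truncated-normal on [34.4, 44.0] weeks
    (median 40.0), PNA a zero-heavy discrete mixture on [0, 23] days
    (median 1, mean ~2.7), weight log-normally regressed on GA (median
    2.805 kg, range [1.56, 5.67] kg), CSF protein log-normal (median
    0.94 g/L) and SCR log-normal around the age-typical curve.
    PMA = GA + PNA/7 by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ga = _truncated_normal(rng, 40.0, 1.78, 34.4, 44.0, n)
    # P(0)=0.25, P(1)=0.30, tail 2 + Geometric: median 1, mean ~2.7
    u = rng.uniform(size=n)
    pna = np.where(u < 0.25, 0.0, 1.0)
    tail = u >= 0.55
    pna[tail] = 2.0 + np.minimum(rng.geometric(0.231, tail.sum()) - 1, 21)
    wt = _weight_from_ga(rng, ga, 40.0, 2.805, 0.105, 0.12, 1.56, 5.67)
    pr = _truncated_lognormal(rng, 0.94, 0.45, 0.02, 2.51, n)
    scr = _scr_from_pna(rng, pna)
    return _assemble(np.arange(1, n + 1), wt, ga, pna, scr, pr)


def sample_hypothetical_population(n: int = 10000, seed=None) -> list[SubjectCovariates]:
    """Covariates for the broad simulation population of neonates.

    Matched to the observational-cohort summaries: GA truncated-normal
    on [23, 44] weeks (median ~37), PNA an equal mixture of two
    geometric distributions (median 5, mean ~10.4 days, truncated at
    59), weight log-normally regressed on GA (median 2.5 kg, range
    [0.4, 5.17] kg). Includes pre-term and <1500 g subjects, i.e. the
    model is deliberately extrapolated beyond the trial's inclusion
    criteria when simulating this population.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ga = _truncated_normal(rng, 37.8, 5.5, 23.0, 44.0, n)
    comp = rng.uniform(size=n) < 0.5
    pna = np.where(
        comp,
        rng.geometric(1.0 / 5.0, n) - 1,
        rng.geometric(1.0 / 18.0, n) - 1,
    ).astype(float)
    pna = np.minimum(pna, 59.0)
    wt = _weight_from_ga(rng, ga, 37.0, 2.5, 0.13, 0.15, 0.4, 5.17)
    pr = _truncated_lognormal(rng, 0.92, 0.60, 0.004, 9.14, n)
    scr = _scr_from_pna(rng, pna)
    return _assemble(np.arange(1, n + 1), wt, ga, pna, scr, pr)


def make_trial(
    demographics: list[SubjectCovariates],
    seed=None,
    design: TrialDesign = TrialDesign(),
) -> EventTable:
    """Build the dose/observation event template for a simulated trial.

    Returns a design-only event table (DV missing, MDV 1) with per-row
    covariates. Early/late plasma sample times are randomised uniformly
    over the protocol grids, independently for the IV and oral phases;
    CSF sample times are drawn uniformly within the assigned phase.
    """
    if not demographics:
        raise ValueError("demographics must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(demographics)
    early_iv = rng.choice(EARLY_SAMPLE_TIMES, n)
    late_iv = rng.choice(LATE_SAMPLE_TIMES, n)
    early_oral = rng.choice(EARLY_SAMPLE_TIMES, n)
    late_oral = rng.choice(LATE_SAMPLE_TIMES, n)
    n_csf = int(round(design.csf_fraction * n))
    csf_subjects = rng.choice(n, size=n_csf, replace=False) if n_csf else np.array([], int)
    n_csf_iv = int(round(design.csf_iv_phase_fraction * n_csf))
    csf_phase_iv = np.zeros(n, dtype=bool)
    csf_phase_iv[csf_subjects[:n_csf_iv]] = True
    csf_time = np.full(n, np.nan)
    iv_end = design.oral_start_h
    oral_end = design.oral_start_h + design.n_oral_doses * design.interval_h
    for i in csf_subjects:
        if csf_phase_iv[i]:
            csf_time[i] = rng.uniform(1.0, iv_end - 1.0)
        else:
            csf_time[i] = rng.uniform(design.oral_start_h + 1.0, oral_end - 1.0)
    dropped = (
        rng.choice(n, size=min(design.attrition, n), replace=False)
        if design.attrition
        else np.array([], int)
    )

    rows = []
    for i, cov in enumerate(demographics):
        sid = cov.subject_id if cov.subject_id is not None else i + 1
        amt = design.dose_mg_per_kg * cov.weight
        base = {
            "ID": sid,
            "WT": cov.weight,
            "GA": cov.gestational_age,
            "PNA": cov.postnatal_age,
            "PMA": cov.postmenstrual_age,
            "SCR": cov.serum_creatinine,
            "PR": cov.csf_protein,
        }

        def dose(t, route):
            rows.append(
                dict(
                    base,
                    TIME=t,
                    AMT=amt,
                    EVID=1,
                    MDV=1,
                    CMT=CMT_CENTRAL if route == "iv" else CMT_DEPOT,
                    ROUTE=route,
                )
            )

        def obs(t, cmt):
            rows.append(dict(base, TIME=t, EVID=0, MDV=1, CMT=cmt))

        for k in range(design.n_iv_doses):
            dose(k * design.interval_h, "iv")
        obs(early_iv[i], CMT_CENTRAL)
        obs(late_iv[i], CMT_CENTRAL)
        completes_oral = i not in dropped
        if completes_oral:
            for k in range(design.n_oral_doses):
                dose(design.oral_start_h + k * design.interval_h, "oral")
            obs(design.oral_start_h + early_oral[i], CMT_CENTRAL)
            obs(design.oral_start_h + late_oral[i], CMT_CENTRAL)
            if design.day7_sample:
                obs(7 * 24.0, CMT_CENTRAL)
        if np.isfinite(csf_time[i]) and (completes_oral or csf_phase_iv[i]):
            obs(csf_time[i], CMT_CSF)

    df = pd.DataFrame(rows).sort_values(["ID", "TIME"], kind="stable").reset_index(drop=True)
    return EventTable(df)


def recovery_study(
    n_replicates: int = 20,
    n_subjects: int = 60,
    seed: int | None = None,
    pop=None,
    parameters: tuple = ("cl_std", "v2_std", "uptk", "ka", "f"),
) -> pd.DataFrame:
    """Simulate-and-refit study on the full cross-over design.

    Each replicate draws a fresh trial-cohort demographic sample, builds
    the randomised sparse design (including opportunistic CSF sampling),
    simulates observations under the generating model, and refits the
    full final model (all estimable parameters free, structural
    constants fixed). Returns one row of estimates per converged
    replicate; medians across replicates estimate the sampling
    distribution centre of each estimator under the trial design.
    Refits start from the generating values, the usual convention for
    simulation re-estimation studies.
    """
    from .estimation import EstimationError, fit
    from .interface import reference_parameters
    from .population import simulate_cohort

    pop = pop if pop is not None else reference_parameters()
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        demo = sample_neofosfo_demographics(n_subjects, rng)
        trial = make_trial(demo, rng)
        simulated = simulate_cohort(pop, demo, trial, seed=rng)
        try:
            result = fit(pop, simulated, compute_se=False)
        except EstimationError:
            logger.warning("recovery replicate %d failed to converge", rep)
            continue
        row = {p: getattr(result.estimates, p) for p in parameters}
        row["ofv"] = result.ofv
        row["converged"] = result.converged
        rows.append(row)
    if not rows:
        raise EstimationError("no recovery replicate converged")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# power / sample-size study


@dataclass
class PowerResult:
    """Per-parameter precision power of a simulated trial design."""

    power: dict
    joint_power: float
    n_converged: int
    n_replicates: int
    n_subjects: int
    precision: float
    replicates: pd.DataFrame = field(repr=False, default=None)


def power_study(
    n_subjects: int,
    n_replicates: int,
    precision: float = 0.20,
    seed: int | None = None,
    pop=None,
    parameters: tuple = ("cl_std", "v2_std", "f"),
) -> PowerResult:
    """Simulation-based precision power of the sparse cross-over design.

    For each replicate trial: draw demographics, build the randomised
    design (plasma sampling only, as in the original design evaluation),
    simulate under the model, refit, and score success per parameter
    when the asymptotic 95% CI half-width (1.96*SE) is at most
    ``precision`` times the estimate. Power is the fraction of converged
    replicates succeeding, reported per parameter and jointly.

    As in a design-stage analysis, the refits condition on the assumed
    structural backbone: the CSF submodel, the maturation coefficients,
    the absorption rate constant and the peripheral-compartment terms
    are held at their population values, and the precision of the three
    design targets (plus their variabilities and the residual errors) is
    what the trial is scored on. Estimating the weakly identified
    nuisance structure from four samples per subject is a model-building
    question, not a sample-size one.
    """
    if n_replicates < 10:
        raise ValueError("need at least 10 replicate trials")
    from .estimation import EstimationError, fit
    from .interface import reference_parameters
    from .population import simulate_cohort

    pop = pop if pop is not None else reference_parameters()
    rng = np.random.default_rng(seed)
    design = TrialDesign(csf_fraction=0.0)
    fixed = {"uptk", "theta_pr", "sigma_add_csf", "theta_m", "theta_n",
             "ka", "q1_std", "v3_std"}
    rows = []
    n_converged = 0
    n_failed = 0
    for rep in range(n_replicates):
        demo = sample_neofosfo_demographics(n_subjects, rng)
        trial = make_trial(demo, rng, design)
        simulated = simulate_cohort(pop, demo, trial, seed=rng)
        try:
            result = fit(pop, simulated, fixed=fixed, compute_se=True)
        except EstimationError:
            n_failed += 1
            continue
        if not result.converged:
            n_failed += 1
            continue
        n_converged += 1
        row = {}
        for p in parameters:
            est = getattr(result.estimates, p)
            se = result.se.get(p, np.nan)
            row[f"{p}_estimate"] = est
            row[f"{p}_halfwidth"] = 1.96 * se
            row[f"{p}_success"] = bool(np.isfinite(se) and 1.96 * se <= precision * abs(est))
        rows.append(row)
    if n_failed > 0.2 * n_replicates:
        logger.warning("power study: %d/%d replicates failed to converge", n_failed, n_replicates)
    if not rows:
        raise EstimationError("no power-study replicate converged")
    reps = pd.DataFrame(rows)
    power = {p: float(reps[f"{p}_success"].mean()) for p in parameters}
    joint = float(reps[[f"{p}_success" for p in parameters]].all(axis=1).mean())
    return PowerResult(
        power=power,
        joint_power=joint,
        n_converged=n_converged,
        n_replicates=n_replicates,
        n_subjects=n_subjects,
        precision=precision,
        replicates=reps,
    )
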
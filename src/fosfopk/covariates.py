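"""Covariate and maturation models for neonatal fosfomycin clearance.

Disposition parameters are centred on a fully mature 70 kg individual.
Individual typical values are obtained by allometric weight scaling
(fixed exponent 0.75 on clearances, 1 on volumes), a sigmoid
postmenstrual-age (PMA) renal maturation function, an asymptotic
postnatal-age (PNA) function on clearance, and a CSF-protein effect on
the CSF/plasma partition ratio applied on the logit scale.

All functions accept scalars or numpy arrays and are pure: they map
population parameters plus subject covariates to typical individual
parameters, with no random effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "STD_WEIGHT",
    "HILL",
    "TM50",
    "DAYS_PER_YEAR",
    "MEDIAN_CSF_PROTEIN",
    "SubjectCovariates",
    "PopulationParameters",
    "allometric_factor",
    "renal_maturation",
    "pna_maturation",
    "typical_serum_creatinine",
    "scr_covariate_factor",
    "csf_uptake",
    "individual_typical_parameters",
]

#: Standard weight (kg) on which all disposition parameters are centred.
STD_WEIGHT = 70.0
#: Hill coefficient of the PMA renal maturation function (fixed prior).
HILL = 3.4
#: PMA (weeks) at 50% renal maturation (fixed prior).
TM50 = 47.7
DAYS_PER_YEAR = 365.25
#: Study-population median CSF protein (g/L); the protein covariate is
#: centred here so the effect vanishes for a median subject.
MEDIAN_CSF_PROTEIN = 0.94


@dataclass(frozen=True)
class SubjectCovariates:
    """One neonate's baseline covariates.

    Parameters
    ----------
    weight : float
        Body weight in kg (> 0).
    gestational_age : float, optional
        GA in weeks. At least one of GA and PMA must be given.
    postnatal_age : float
        PNA in days (>= 0).
    postmenstrual_age : float, optional
        PMA in weeks; derived as ``GA + PNA/7`` when omitted, and checked
        for consistency (1e-9 weeks) when both are supplied.
    serum_creatinine : float, optional
        SCR in µmol/L. Tested but not retained in the final model.
    csf_protein : float, optional
        CSF protein in g/L; the study median is substituted when missing.
    """

    weight: float
    postnatal_age: float
    gestational_age: float | None = None
    postmenstrual_age: float | None = None
    serum_creatinine: float | None = None
    csf_protein: float | None = None
    subject_id: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if self.postnatal_age < 0:
            raise ValueError(f"postnatal_age must be >= 0, got {self.postnatal_age}")
        if self.gestational_age is None and self.postmenstrual_age is None:
            raise ValueError("one of gestational_age or postmenstrual_age is required")
        if self.gestational_age is not None and not self.gestational_age > 0:
            raise ValueError(f"gestational_age must be positive, got {self.gestational_age}")
        if self.postmenstrual_age is None:
            object.__setattr__(
                self, "postmenstrual_age", self.gestational_age + self.postnatal_age / 7.0
            )
        elif self.gestational_age is not None:
            expected = self.gestational_age + self.postnatal_age / 7.0
            if abs(self.postmenstrual_age - expected) > 1e-9:
                raise ValueError(
                    "inconsistent ages: PMA must equal GA + PNA/7 "
                    f"({self.postmenstrual_age} != {expected})"
                )
        if not self.postmenstrual_age > 0:
            raise ValueError("postmenstrual_age must be positive")


# Parameters that are fixed (not estimated) in the final model.
FIXED_PARAMETERS = ("q2_std", "v4_std", "hill", "tm50", "std_weight")


@dataclass(frozen=True)
class PopulationParameters:
    """Population (fixed-effect + variability) parameters of the final model.

    Disposition terms are per 70 kg: clearances in L/h/70 kg, volumes in
    L/70 kg. ``q2_std`` (CSF inter-compartmental clearance) and ``v4_std``
    (CSF volume) are fixed constants, as are the maturation-function priors
    ``hill`` and ``tm50``. ``omega_*`` are random-effect standard deviations
    (log scale for CL and V2, logit scale for F); ``sigma_prop_*`` are
    proportional residual fractions and ``sigma_add_csf`` an additive
    residual in mg/L.
    """

    cl_std: float
    v2_std: float
    q1_std: float
    v3_std: float
    uptk: float
    ka: float
    f: float
    theta_m: float
    theta_n: float
    theta_pr: float
    theta_scr: float = 0.0
    q2_std: float = 0.017
    v4_std: float = 0.15
    hill: float = HILL
    tm50: float = TM50
    std_weight: float = STD_WEIGHT
    omega_cl: float = 0.0
    omega_v2: float = 0.0
    omega_f: float = 0.0
    sigma_prop_iv: float = 0.0
    sigma_prop_oral: float = 0.0
    sigma_add_csf: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cl_std", "v2_std", "q1_std", "v3_std", "q2_std", "v4_std", "ka"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("uptk", "f"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in the open interval (0, 1), got {v}")
        if not 0.0 < self.theta_m <= 1.0:
            raise ValueError(f"theta_m must lie in (0, 1], got {self.theta_m}")
        if not self.theta_n > 0:
            raise ValueError(f"theta_n must be positive, got {self.theta_n}")
        for name in ("omega_cl", "omega_v2", "omega_f",
                     "sigma_prop_iv", "sigma_prop_oral", "sigma_add_csf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_updates(self, **kwargs) -> "PopulationParameters":
        """Return a copy with the given fields replaced.

        The fixed members (q2_std, v4_std, hill, tm50, std_weight) cannot
        be altered through this method: they are study constants.
        """
        bad = set(kwargs) & set(FIXED_PARAMETERS)
        if bad:
            raise ValueError(f"fixed parameters cannot be updated: {sorted(bad)}")
        return replace(self, **kwargs)


def allometric_factor(weight, exponent):
    """Allometric body-weight scaling factor ``(weight / 70)**exponent``.

    ``exponent`` is 0.75 for clearance terms and 1 for volume terms.
    """
    weight = np.asarray(weight, dtype=float)
    if np.any(weight <= 0):
        raise ValueError("weight must be strictly positive")
    out = (weight / STD_WEIGHT) ** exponent
    return float(out) if out.ndim == 0 else out


def renal_maturation(pma, hill: float = HILL, tm50: float = TM50):
    """Sigmoid renal maturation fraction as a function of PMA (weeks).

    Returns ``pma**hill / (tm50**hill + pma**hill)``: 0.5 at ``tm50``
    weeks, saturating to 1 in a fully mature individual.
    """
    pma = np.asarray(pma, dtype=float)
    if np.any(pma <= 0):
        raise ValueError("postmenstrual age must be strictly positive")
    # rational form in (pma/tm50)**hill avoids overflow for large PMA
    r = (pma / tm50) ** hill
    out = r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def pna_maturation(pna, theta_m: float, theta_n: float):
    """Postnatal clearance maturation fraction.

    ``theta_m`` is the fraction of clearance on the first day of life
    (day 0) and ``theta_n`` (1/day) the postnatal maturation rate:
    ``theta_m + (1 - theta_m) * (1 - exp(-pna * theta_n))``, rising from
    ``theta_m`` at birth towards 1.
    """
    if not 0.0 < theta_m <= 1.0:
        raise ValueError(f"theta_m must lie in (0, 1], got {theta_m}")
    if not theta_n > 0:
        raise ValueError(f"theta_n must be positive, got {theta_n}")
    pna = np.asarray(pna, dtype=float)
    if np.any(pna < 0):
        raise ValueError("postnatal age must be non-negative")
    out = theta_m + (1.0 - theta_m) * (1.0 - np.exp(-pna * theta_n))
    return float(out) if out.ndim == 0 else out


def typical_serum_creatinine(pna_years):
    """Typical serum creatinine (µmol/L) for postnatal age in years.

    Empirical reference function for the age-expected creatinine level:
    ``-2.37330 - 12.91367*ln(PNA) + 23.93581*PNA**0.5``. It captures the
    washout of maternal creatinine over the first weeks of life followed
    by a slow rise with age. Undefined at PNA = 0 (logarithm).
    """
    pna_years = np.asarray(pna_years, dtype=float)
    if np.any(pna_years <= 0):
        raise ValueError("postnatal age must be strictly positive (years)")
    out = -2.37330 - 12.91367 * np.log(pna_years) + 23.93581 * np.sqrt(pna_years)
    return float(out) if out.ndim == 0 else out


def scr_covariate_factor(scr, pna_years, theta_scr: float):
    """Clearance multiplier from serum creatinine standardised by age.

    ``(SCR / TSCR(PNA))**theta_scr``; equals 1 when the measured SCR
    matches the age-typical value or when the coefficient is zero.
    Retained for covariate model comparison; inactive in the final model.
    """
    scr = np.asarray(scr, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be strictly positive")
    tscr = typical_serum_creatinine(pna_years)
    out = (scr / tscr) ** theta_scr
    return float(out) if np.ndim(out) == 0 else out


def csf_uptake(uptk_pop, csf_protein, theta_pr: float):
    """Individual CSF/plasma ratio from CSF protein, on the logit scale.

    The population ratio is logit-transformed, perturbed linearly in the
    protein deviation from the study median (0.94 g/L), and mapped back:

    ``logit_i = logit(uptk_pop) * (1 + theta_pr * (protein - 0.94))``

    The result always lies in (0, 1). With a negative coefficient and a
    sub-0.5 population ratio, uptake increases with CSF protein.
    """
    uptk_pop = np.asarray(uptk_pop, dtype=float)
    if np.any((uptk_pop <= 0) | (uptk_pop >= 1)):
        raise ValueError("uptk_pop must lie in the open interval (0, 1)")
    csf_protein = np.asarray(csf_protein, dtype=float)
    if np.any(csf_protein < 0):
        raise ValueError("csf_protein must be non-negative")
    logit = np.log(uptk_pop / (1.0 - uptk_pop))
    perturbed = logit * (1.0 + theta_pr * (csf_protein - MEDIAN_CSF_PROTEIN))
    out = 1.0 / (1.0 + np.exp(-perturbed))
    return float(out) if out.ndim == 0 else out


def individual_typical_parameters(pop: PopulationParameters, cov: SubjectCovariates):
    """Covariate-typical individual parameters (no random effects).

    Clearance receives allometric scaling, PMA renal maturation and the
    PNA function; inter-compartmental clearances receive allometric
    scaling only; volumes scale linearly with weight. The CSF/plasma
    ratio is adjusted for CSF protein (study median substituted when the
    measurement is missing). SCR does not enter the final model.

    Returns an :class:`~fosfopk.structural_model.IndividualParameters`.
    """
    from .structural_model import IndividualParameters

    fcl = allometric_factor(cov.weight, 0.75)
    fv = allometric_factor(cov.weight, 1.0)
    cl = (
        pop.cl_std
        * fcl
        * renal_maturation(cov.postmenstrual_age, pop.hill, pop.tm50)
        * pna_maturation(cov.postnatal_age, pop.theta_m, pop.theta_n)
    )
    if pop.theta_scr != 0.0 and cov.serum_creatinine is not None:
        cl *= scr_covariate_factor(
            cov.serum_creatinine,
            max(cov.postnatal_age, 0.5) / DAYS_PER_YEAR,
            pop.theta_scr,
        )
    protein = cov.csf_protein if cov.csf_protein is not None else MEDIAN_CSF_PROTEIN
    return IndividualParameters(
        cl=cl,
        v2=pop.v2_std * fv,
        q1=pop.q1_std * fcl,
        v3=pop.v3_std * fv,
        q2=pop.q2_std * fcl,
        v4=pop.v4_std * fv,
        uptk=csf_uptake(pop.uptk, protein, pop.theta_pr),
        ka=pop.ka,
        f=pop.f,
    )


def typical_parameter_arrays(pop: PopulationParameters, covs) -> dict:
    """Vectorised typical parameters for a list of subjects.

    Returns a dict of float arrays (cl, v2, q1, v3, q2, v4, uptk, ka, f)
    aligned with ``covs``; used by the cohort simulator and the
    estimation engine, where per-subject Python objects would dominate
    run time.
    """
    wt = np.array([c.weight for c in covs], dtype=float)
    pma = np.array([c.postmenstrual_age for c in covs], dtype=float)
    pna = np.array([c.postnatal_age for c in covs], dtype=float)
    pr = np.array(
        [c.csf_protein if c.csf_protein is not None else MEDIAN_CSF_PROTEIN for c in covs],
        dtype=float,
    )
    fcl = allometric_factor(wt, 0.75)
    fv = allometric_factor(wt, 1.0)
    cl = (
        pop.cl_std
        * fcl
        * renal_maturation(pma, pop.hill, pop.tm50)
        * pna_maturation(pna, pop.theta_m, pop.theta_n)
    )
    n = len(covs)
    return {
        "cl": cl,
        "v2": pop.v2_std * fv,
        "q1": pop.q1_std * fcl,
        "v3": pop.v3_std * fv,
        "q2": pop.q2_std * fcl,
        "v4": pop.v4_std * fv,
        "uptk": np.asarray(csf_uptake(pop.uptk, pr, pop.theta_pr)) * np.ones(n),
        "ka": np.full(n, pop.ka),
        "f": np.full(n, pop.f),
    }
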
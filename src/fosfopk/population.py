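"""Between-subject variability and residual error.

Inter-individual variability (IIV) is log-normal on clearance and
central volume and logit-normal on oral bioavailability, so every
realised F stays inside (0, 1). Residual error is proportional for
plasma — with separate magnitudes for the IV and oral phases, assigned
by the route of the most recent dose — and additive for CSF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .covariates import PopulationParameters, SubjectCovariates, typical_parameter_arrays
from .structural_model import (
    OBS_CSF,
    OBS_IV_PLASMA,
    OBS_ORAL_PLASMA,
    EventTable,
    IndividualParameters,
    compile_design,
    predict_design,
)

__all__ = [
    "RandomEffectSpec",
    "ResidualErrorSpec",
    "draw_etas",
    "draw_individual",
    "apply_residual_error",
    "simulate_cohort",
    "cv_to_omega",
    "omega_to_cv",
]

logger = logging.getLogger(__name__)

#: Plasma / CSF lower limits of quantification (mg/L). No study sample
#: fell below them, so simulated values are only flagged, never censored.
LLOQ_PLASMA = 5.0
LLOQ_CSF = 1.0


def cv_to_omega(cv: float) -> float:
    """Log-normal SD from a coefficient of variation (fraction)."""
    return float(np.sqrt(np.log1p(cv**2)))


def omega_to_cv(omega: float) -> float:
    """Coefficient of variation (fraction) from a log-normal SD."""
    return float(np.sqrt(np.expm1(omega**2)))


@dataclass(frozen=True)
class RandomEffectSpec:
    """Standard deviations of the subject-level random effects.

    ``omega_cl`` and ``omega_v2`` act on the log scale, ``omega_f`` on
    the logit scale. ``corr`` optionally supplies a 3x3 correlation
    matrix (identity by default).
    """

    omega_cl: float
    omega_v2: float
    omega_f: float
    corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("omega_cl", "omega_v2", "omega_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.corr is not None:
            c = np.asarray(self.corr, dtype=float)
            if c.shape != (3, 3) or not np.allclose(c, c.T):
                raise ValueError("corr must be a symmetric 3x3 matrix")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError("corr must be positive semi-definite")
            object.__setattr__(self, "corr", c)

    @classmethod
    def from_population(cls, pop: PopulationParameters) -> "RandomEffectSpec":
        return cls(omega_cl=pop.omega_cl, omega_v2=pop.omega_v2, omega_f=pop.omega_f)

    @property
    def covariance(self) -> np.ndarray:
        sd = np.array([self.omega_cl, self.omega_v2, self.omega_f])
        corr = np.eye(3) if self.corr is None else self.corr
        return corr * np.outer(sd, sd)


@dataclass(frozen=True)
class ResidualErrorSpec:
    """Residual (unexplained) error magnitudes per observation phase."""

    proportional_iv: float
    proportional_oral: float
    additive_csf: float

    def __post_init__(self) -> None:
        for name in ("proportional_iv", "proportional_oral", "additive_csf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_population(cls, pop: PopulationParameters) -> "ResidualErrorSpec":
        return cls(
            proportional_iv=pop.sigma_prop_iv,
            proportional_oral=pop.sigma_prop_oral,
            additive_csf=pop.sigma_add_csf,
        )


def draw_etas(re: RandomEffectSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` zero-mean random-effect vectors (eta_CL, eta_V2, eta_F)."""
    z = rng.standard_normal((n, 3))
    sd = np.array([re.omega_cl, re.omega_v2, re.omega_f])
    if re.corr is None:
        return z * sd
    # eigen factorisation tolerates semi-definite correlation structures
    vals, vecs = np.linalg.eigh(re.covariance)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    return z @ root.T


def _apply_etas(typical: dict, etas: np.ndarray) -> dict:
    """Individualise typical-parameter arrays with random-effect draws."""
    p = dict(typical)
    p["cl"] = typical["cl"] * np.exp(etas[:, 0])
    p["v2"] = typical["v2"] * np.exp(etas[:, 1])
    logit_f = np.log(typical["f"] / (1.0 - typical["f"])) + etas[:, 2]
    p["f"] = 1.0 / (1.0 + np.exp(-logit_f))
    return p


def draw_individual(
    pop: PopulationParameters,
    cov: SubjectCovariates,
    re: RandomEffectSpec,
    rng: np.random.Generator | int,
) -> IndividualParameters:
    """One subject's parameters: covariate-typical values plus IIV.

    CL and V2 are multiplied by ``exp(eta)``; F is perturbed on the
    logit scale. With all omegas zero this returns exactly the typical
    individual.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    typ = typical_parameter_arrays(pop, [cov])
    eta = draw_etas(re, 1, rng)
    p = _apply_etas(typ, eta)
    return IndividualParameters(**{k: float(v[0]) for k, v in p.items()})


def apply_residual_error(
    predictions: np.ndarray,
    kind: str,
    spec: ResidualErrorSpec,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Add residual error to model predictions of one observation kind.

    ``kind`` is one of ``"iv-plasma"``, ``"oral-plasma"`` (proportional
    error) or ``"csf"`` (additive error). Simulated values that fall
    below zero are floored at zero and counted in the log.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    pred = np.asarray(predictions, dtype=float)
    if np.any(pred < 0):
        raise ValueError("predictions must be non-negative")
    eps = rng.standard_normal(pred.shape)
    if kind == "iv-plasma":
        y = pred * (1.0 + spec.proportional_iv * eps)
    elif kind == "oral-plasma":
        y = pred * (1.0 + spec.proportional_oral * eps)
    elif kind == "csf":
        y = pred + spec.additive_csf * eps
    else:
        raise ValueError(f"unknown observation kind {kind!r}")
    negative = int(np.sum(y < 0))
    if negative:
        logger.info("floored %d negative simulated concentrations at 0", negative)
    return np.maximum(y, 0.0)


def simulate_cohort(
    pop: PopulationParameters,
    covariates: list[SubjectCovariates],
    design: EventTable,
    re: RandomEffectSpec | None = None,
    err: ResidualErrorSpec | None = None,
    seed: int | np.random.Generator | None = None,
    return_etas: bool = False,
):
    """Simulate observed concentrations for a cohort on a trial design.

    Per subject: draw random effects, solve the individual profile at
    the design's observation times, then add phase-specific residual
    error. Returns a copy of ``design`` with the DV column filled (and
    the eta matrix when ``return_etas``). Fully reproducible given the
    seed; omegas and sigmas of zero reduce DV to the typical prediction.
    """
    if len(covariates) != design.n_subjects:
        raise ValueError(
            f"covariate/design mismatch: {len(covariates)} covariate sets "
            f"for {design.n_subjects} subjects"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    re = re if re is not None else RandomEffectSpec.from_population(pop)
    err = err if err is not None else ResidualErrorSpec.from_population(pop)
    compiled = compile_design(design)
    typ = typical_parameter_arrays(pop, covariates)
    etas = draw_etas(re, len(covariates), rng)
    p = _apply_etas(typ, etas)
    pred = predict_design(p, compiled)

    kind = compiled.obs_kind
    eps = rng.standard_normal(pred.shape)
    y = np.where(kind == OBS_IV_PLASMA, pred * (1 + err.proportional_iv * eps), pred)
    y = np.where(kind == OBS_ORAL_PLASMA, pred * (1 + err.proportional_oral * eps), y)
    y = np.where(kind == OBS_CSF, pred + err.additive_csf * eps, y)
    negative = int(np.sum((y < 0) & (kind != 0)))
    if negative:
        logger.info("floored %d negative simulated concentrations at 0", negative)
    y = np.maximum(y, 0.0)

    out = design.copy()
    mask = kind != 0
    rows = compiled.obs_row[mask]
    out.data.loc[rows, "DV"] = y[mask]
    out.data.loc[rows, "MDV"] = 0
    below = ((y < LLOQ_PLASMA) & ((kind == OBS_IV_PLASMA) | (kind == OBS_ORAL_PLASMA))) | (
        (y < LLOQ_CSF) & (kind == OBS_CSF)
    )
    if below.any():
        logger.info("%d simulated concentrations below LLOQ (retained)", int(below.sum()))
    if return_etas:
        return out, etas
    return out
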
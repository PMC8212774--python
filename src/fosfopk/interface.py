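"""File formats, run configuration and the shipped reference model.

Event data travel in a single rectangular CSV dialect (one row per dose
or observation) with ``"."`` marking missing numeric fields. All times
are hours since each subject's first dose, amounts mg, concentrations
mg/L, weights kg; unit conversions happen only at this boundary.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .covariates import PopulationParameters
from .structural_model import EVENT_COLUMNS, EventTable

__all__ = [
    "read_event_table",
    "write_event_table",
    "reference_parameters",
    "write_demographics",
    "read_demographics",
    "RunConfig",
    "load_config",
]

_NUMERIC_COLUMNS = [c for c in EVENT_COLUMNS if c not in ("ID", "ROUTE")]


class EventTableParseError(ValueError):
    """Raised with file, line and column context on malformed event rows."""


def read_event_table(path) -> EventTable:
    """Read an event-table CSV, validating the dialect row by row.

    Missing numeric fields are written as ``"."`` and parsed to NaN.
    Errors name the offending line (1-based, header = line 1) and column.
    """
    path = Path(path)
    df = pd.read_csv(
        path, na_values=["."], dtype={"ROUTE": "string"}, float_precision="round_trip"
    )
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventTableParseError(f"{path}: missing required columns {missing}")
    for col in _NUMERIC_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise EventTableParseError(f"{path}: column {col}: {exc}") from exc

    def err(idx: int, col: str, msg: str):
        raise EventTableParseError(f"{path}: line {idx + 2}, column {col}: {msg}")

    for idx, row in df.iterrows():
        if pd.isna(row["EVID"]) or row["EVID"] not in (0, 1):
            err(idx, "EVID", f"expected 0 or 1, got {row['EVID']}")
        if row["CMT"] not in (1, 2, 3, 4):
            err(idx, "CMT", f"unknown compartment code {row['CMT']}")
        if row["EVID"] == 1:
            if pd.isna(row["AMT"]) or row["AMT"] <= 0:
                err(idx, "AMT", "dose rows require a positive amount")
            if not pd.isna(row["DV"]):
                err(idx, "DV", "dose rows must not carry an observed value")
        if pd.isna(row["TIME"]) or row["TIME"] < 0:
            err(idx, "TIME", "times must be non-negative hours since first dose")
    for sid, sub in df.groupby("ID", sort=False):
        t = sub["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            first_bad = sub.index[1:][np.diff(t) < 0][0]
            err(first_bad, "TIME", f"subject {sid}: non-monotone time")
    return EventTable(df)


def write_event_table(table: EventTable, path) -> None:
    """Write an event table in the CSV dialect (missing values as ``"."``)."""
    df = table.data.copy()
    out = pd.DataFrame(index=df.index)
    for col in EVENT_COLUMNS:
        vals = df[col]
        if col in ("ID", "ROUTE"):
            out[col] = vals.astype("string").fillna(".")
        else:
            # plain repr keeps the round-trip lossless for float64 values
            out[col] = vals.map(lambda v: "." if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False)


_DEMOGRAPHIC_COLUMNS = ["ID", "WT", "GA", "PNA", "PMA", "SCR", "PR"]


def write_demographics(covs, path) -> None:
    """Write subject covariates as a demographics CSV (WT in kg)."""
    rows = []
    for i, c in enumerate(covs):
        rows.append(
            {
                "ID": c.subject_id if c.subject_id is not None else i + 1,
                "WT": c.weight,
                "GA": c.gestational_age,
                "PNA": c.postnatal_age,
                "PMA": c.postmenstrual_age,
                "SCR": c.serum_creatinine,
                "PR": c.csf_protein,
            }
        )
    df = pd.DataFrame(rows, columns=_DEMOGRAPHIC_COLUMNS)
    df.to_csv(path, index=False, na_rep=".")


def read_demographics(path) -> list:
    from .covariates import SubjectCovariates

    df = pd.read_csv(path, na_values=["."])
    out = []
    for _, row in df.iterrows():
        out.append(
            SubjectCovariates(
                weight=float(row["WT"]),
                gestational_age=None if pd.isna(row["GA"]) else float(row["GA"]),
                postnatal_age=float(row["PNA"]),
                postmenstrual_age=None if pd.isna(row["PMA"]) else float(row["PMA"]),
                serum_creatinine=None if pd.isna(row["SCR"]) else float(row["SCR"]),
                csf_protein=None if pd.isna(row["PR"]) else float(row["PR"]),
                subject_id=row["ID"],
            )
        )
    return out


def reference_parameters() -> PopulationParameters:
    """The shipped final-model population estimates.

    Disposition terms are per fully mature 70 kg individual. The
    clearance and central-volume IIV magnitudes are stored as log-scale
    standard deviations converted from the reported coefficients of
    variation (24.5% and 14.2%) via ``omega = sqrt(ln(1 + CV^2))``; the
    bioavailability IIV (0.269) is a logit-scale standard deviation and
    is used directly.
    """
    from .population import cv_to_omega

    return PopulationParameters(
        cl_std=8.94,
        v2_std=19.1,
        q1_std=8.01,
        v3_std=7.53,
        uptk=0.321,
        ka=0.0987,
        f=0.478,
        theta_m=0.449,
        theta_n=0.117,
        theta_pr=-0.952,
        theta_scr=0.0,
        omega_cl=cv_to_omega(0.245),
        omega_v2=cv_to_omega(0.142),
        omega_f=0.269,
        sigma_prop_iv=0.0769,
        sigma_prop_oral=0.186,
        sigma_add_csf=10.9,
    )


# ---------------------------------------------------------------------------
# run configuration


_KNOWN_BLOCKS = {"model", "design", "simulation", "estimation", "output"}
_KNOWN_KEYS = {
    "model": {
        "CL", "V2", "Q1", "V3", "Q2", "V4", "UPTK", "KA", "F",
        "THETA_M", "THETA_N", "THETA_PR", "THETA_SCR",
        "OMEGA_CL", "OMEGA_V2", "OMEGA_F",
        "SIGMA_PROP_IV", "SIGMA_PROP_ORAL", "SIGMA_ADD_CSF",
        "fixed",
    },
    "design": {"n_subjects", "dose_mg_per_kg", "interval_h", "n_iv_doses",
               "oral_start_h", "csf_fraction", "day7_sample", "attrition"},
    "simulation": {"seed", "n_replicates", "n_simulations", "population"},
    "estimation": {"method", "outer_tol", "inner_tol", "max_iter"},
    "output": {"directory", "prefix"},
}

_MODEL_KEY_TO_FIELD = {
    "CL": "cl_std", "V2": "v2_std", "Q1": "q1_std", "V3": "v3_std",
    "Q2": "q2_std", "V4": "v4_std", "UPTK": "uptk", "KA": "ka", "F": "f",
    "THETA_M": "theta_m", "THETA_N": "theta_n", "THETA_PR": "theta_pr",
    "THETA_SCR": "theta_scr",
    "OMEGA_CL": "omega_cl", "OMEGA_V2": "omega_v2", "OMEGA_F": "omega_f",
    "SIGMA_PROP_IV": "sigma_prop_iv", "SIGMA_PROP_ORAL": "sigma_prop_oral",
    "SIGMA_ADD_CSF": "sigma_add_csf",
}


@dataclass
class RunConfig:
    """Validated run configuration (model/design/simulation/estimation)."""

    model: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    estimation: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)
    source_text: str = ""

    def population_parameters(self) -> PopulationParameters:
        """Reference parameters overridden by the model block."""
        base = reference_parameters()
        updates = {}
        fixed_updates = {}
        for key, value in self.model.items():
            if key == "fixed":
                continue
            fld = _MODEL_KEY_TO_FIELD[key]
            if fld in ("q2_std", "v4_std"):
                fixed_updates[fld] = float(value)
            else:
                updates[fld] = float(value)
        pop = base.with_updates(**updates) if updates else base
        if fixed_updates:  # constructing anew is the only way to set fixed members
            from dataclasses import asdict

            d = asdict(pop)
            d.update(fixed_updates)
            pop = PopulationParameters(**d)
        return pop

    def config_hash(self) -> str:
        return hashlib.sha256(self.source_text.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown blocks and keys."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    unknown = set(raw) - _KNOWN_BLOCKS
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    for block, keys in raw.items():
        if keys is None:
            raw[block] = {}
            continue
        bad = set(keys) - _KNOWN_KEYS[block]
        if bad:
            raise ValueError(f"unknown keys in [{block}]: {sorted(bad)}")
    return RunConfig(**{b: raw.get(b, {}) for b in _KNOWN_BLOCKS}, source_text=text)
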
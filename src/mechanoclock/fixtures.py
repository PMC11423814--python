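"""Packaged parameter tables, condition configs, fit-space definition and
synthetic calibration data.

All tables are plain CSV/YAML under ``mechanoclock/data``.  The parameter
table carries one row per rate constant (module, name, value, units,
fit_lo, fit_hi, source); rows with finite fit bounds define the free
parameters of Bayesian calibration.  Calibration reference summaries
(period/amplitude mean +/- s.d. per condition) are synthetic-but-plausible
values following the qualitative trends of published luminescence
measurements, since no raw dataset ships with the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationDataset, FitSpace, reconstruct_experiment, \
    simulate_reporter
from .clock import CircadianParams
from .mechano import MechanoParams, TreatmentCondition
from .metrics import period_amplitude

__all__ = [
    "RunConfig",
    "default_parameters",
    "load_parameter_table",
    "write_parameter_table",
    "default_fit_space",
    "load_condition",
    "condition_from_mapping",
    "load_calibration_table",
    "build_calibration_datasets",
    "generate_synthetic_calibration",
    "data_path",
]

_UNITS = {"tau": "h", "K_d": "1/h", "default": "model units"}


def data_path(name: str) -> Path:
    """Path of a packaged data file."""
    return Path(resources.files("mechanoclock.data") / name)


# ------------------------------------------------------------ parameter table

def default_parameters() -> tuple[MechanoParams, CircadianParams]:
    """Baseline (point-estimate) parameter objects from the packaged table."""
    return load_parameter_table(data_path("parameters.csv"))


def load_parameter_table(path) -> tuple[MechanoParams, CircadianParams]:
    """Read a parameter CSV into typed parameter objects.

    Requires columns module,name,value; names must exactly cover known
    fields (missing fields keep defaults; unknown or duplicate names are
    schema errors).
    """
    df = pd.read_csv(path)
    required = {"module", "name", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"parameter table needs columns {sorted(required)}")
    if df.duplicated(["module", "name"]).any():
        dups = df[df.duplicated(['module', 'name'])]["name"].tolist()
        raise ValueError(f"duplicate parameter rows: {dups}")
    known = {"mechano": {f.name for f in dataclasses.fields(MechanoParams)},
             "circadian": {f.name for f in dataclasses.fields(CircadianParams)}}
    kw = {"mechano": {}, "circadian": {}}
    for _, row in df.iterrows():
        mod, name = row["module"], row["name"]
        if mod not in known:
            raise ValueError(f"unknown module {mod!r} in parameter table")
        if name not in known[mod]:
            raise ValueError(f"unknown parameter {mod}.{name!r}")
        kw[mod][name] = float(row["value"])
    if "n_hill" in kw["circadian"]:
        kw["circadian"]["n_hill"] = int(kw["circadian"]["n_hill"])
    return MechanoParams(**kw["mechano"]), CircadianParams(**kw["circadian"])


def write_parameter_table(path, mech: MechanoParams, circ: CircadianParams,
                          fit_ranges: dict | None = None,
                          source: str = "package baseline") -> None:
    """Write parameter objects to the CSV schema (roundtrips with loader)."""
    rows = []
    for mod, obj in (("mechano", mech), ("circadian", circ)):
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if v is None:
                continue
            unit = ("h" if f.name.startswith("tau")
                    else "1/h" if f.name.startswith("K_d") or f.name.startswith("k_")
                    else "um^2" if f.name in ("A_0", "K_A")
                    else "kPa" if f.name in ("C_E", "E_c0", "E_cmax", "K_lamE")
                    else "model units")
            lo, hi = (fit_ranges or {}).get(f"{mod[:4]}.{f.name}", (np.nan, np.nan))
            rows.append(dict(module=mod, name=f.name, value=v, units=unit,
                             fit_lo=lo, fit_hi=hi, source=source))
    pd.DataFrame(rows).to_csv(path, index=False)


def default_fit_space(path=None) -> FitSpace:
    """Free parameters (finite fit bounds) from the parameter table."""
    df = pd.read_csv(path or data_path("parameters.csv"))
    if not {"fit_lo", "fit_hi"}.issubset(df.columns):
        raise ValueError("parameter table lacks fit_lo/fit_hi columns")
    free = df[np.isfinite(df["fit_lo"]) & np.isfinite(df["fit_hi"])]
    names = [("circ." if m == "circadian" else "mech.") + n
             for m, n in zip(free["module"], free["name"])]
    return FitSpace(names=names, lower=free["fit_lo"].to_numpy(),
                    upper=free["fit_hi"].to_numpy())


# ------------------------------------------------------------------ conditions

_CONDITION_KEYS = {f.name for f in dataclasses.fields(TreatmentCondition)}


def condition_from_mapping(d: dict) -> TreatmentCondition:
    unknown = set(d) - _CONDITION_KEYS
    if unknown:
        raise ValueError(f"unknown condition keys: {sorted(unknown)}; "
                         f"allowed: {sorted(_CONDITION_KEYS)}")
    d = dict(d)
    for k, v in d.items():
        if k not in ("cell_density", "mutation", "label") and v is not None:
            d[k] = float(v)  # YAML 1.1 reads "1.0e7" as a string
    cond = TreatmentCondition(**d)
    cond.validate()
    return cond


def load_condition(path) -> TreatmentCondition:
    """Load a treatment condition from a YAML/JSON mapping file."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"condition file {path} must contain a mapping")
    return condition_from_mapping(d)


# ------------------------------------------------------------------ run config

@dataclass
class RunConfig:
    """Schema-validated options for pipeline runs (CLI and scripts)."""

    condition: dict = field(default_factory=dict)
    n_cells: int = 200
    days: float = 6.0
    seed: int = 0
    snr: float = 5.0
    sigma: float = 0.2
    sigma_circ: float = 0.05
    window_halfwidth: float = 0.1
    dt: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_cells < 1 or self.days <= 0 or self.snr <= 0:
            raise ValueError("n_cells >= 1, days > 0 and snr > 0 required")
        if self.sigma < 0 or self.sigma_circ < 0 or self.dt <= 0:
            raise ValueError("sigma, sigma_circ >= 0 and dt > 0 required")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ------------------------------------------------------- calibration fixtures

def load_calibration_table(path=None) -> pd.DataFrame:
    df = pd.read_csv(path or data_path("calibration_targets.csv"))
    need = {"label", "T_mean", "T_sd", "A_mean", "A_sd"}
    if not need.issubset(df.columns):
        raise ValueError(f"calibration table needs columns {sorted(need)}")
    return df


def _row_condition(row: pd.Series) -> TreatmentCondition:
    d = {k: row[k] for k in _CONDITION_KEYS
         if k in row.index and pd.notna(row[k])}
    if "contact_area" in d:
        d["contact_area"] = float(d["contact_area"])
    return condition_from_mapping(d)


def build_calibration_datasets(table: pd.DataFrame | None = None,
                               n_samples: int = 200_000,
                               horizon_h: float = 120.0,
                               seed: int = 0) -> list[CalibrationDataset]:
    """Reconstruct per-condition luminescence references from the summary table."""
    df = table if table is not None else load_calibration_table()
    out = []
    for i, (_, row) in enumerate(df.iterrows()):
        t, mu, sd = reconstruct_experiment(
            row["T_mean"], row["T_sd"], row["A_mean"], row["A_sd"],
            n_samples=n_samples, horizon_h=horizon_h, seed=seed + i)
        sd = np.maximum(sd, 0.05 * max(abs(row["A_mean"]), 1e-6))  # noise floor
        ds = CalibrationDataset(condition=_row_condition(row),
                                T_exp=row["T_mean"], T_sd=row["T_sd"],
                                A_exp=row["A_mean"], A_sd=row["A_sd"],
                                t=t, mu=mu, sigma=sd)
        ds.validate()
        out.append(ds)
    return out


def generate_synthetic_calibration(
    mech: MechanoParams, circ: CircadianParams,
    conditions: list[TreatmentCondition],
    T_sd: float = 0.5, A_sd_frac: float = 0.15,
    n_samples: int = 100_000, horizon_h: float = 120.0, seed: int = 0,
) -> list[CalibrationDataset]:
    """Calibration datasets at a known ground truth (for recovery tests).

    Simulates the reporter under each condition at the given parameters,
    measures period and amplitude (normalized to the first condition as
    control), and builds the reconstructed references at those values.
    Raises if the ground truth is non-oscillatory under any condition.
    """
    stats = []
    for cond in conditions:
        rep = simulate_reporter(mech, circ, cond)
        T, A = period_amplitude(rep.t, rep.L)
        stats.append((T, A))
    A_ctrl = stats[0][1]
    out = []
    for i, (cond, (T, A)) in enumerate(zip(conditions, stats)):
        A_rel = A / A_ctrl
        t, mu, sd = reconstruct_experiment(
            T, T_sd, A_rel, A_sd_frac * A_rel,
            n_samples=n_samples, horizon_h=horizon_h, seed=seed + i)
        sd = np.maximum(sd, 0.05 * A_rel)
        ds = CalibrationDataset(condition=cond, T_exp=T, T_sd=T_sd,
                                A_exp=A_rel, A_sd=A_sd_frac * A_rel,
                                t=t, mu=mu, sigma=sd)
        ds.validate()
        out.append(ds)
    return out
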
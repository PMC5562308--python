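"""Tabular readers/writers, YAML configuration, and run logging.

Observation tables are delimited text (comma default, tab accepted) with a
header row.  Required columns: ``sample_id, ph, corg_pct, temp_k`` and one
of ``time_days`` / ``time_years`` (years are converted at 365 d/y).
Optional: ``e_add_obs``, ``total_cu_mg_kg``, ``weight``.  Unknown columns
are preserved on round-trip; numeric parsing is strict (blanks never become
zero silently).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import EObservation, FitResult, TrendAnchor
from .model import DAYS_PER_YEAR, ModelParams, SoilSample
from .synthetic import SoilGenConfig

__all__ = [
    "RunConfig",
    "read_observation_table",
    "read_isotope_table",
    "read_anchor_table",
    "write_table",
    "write_report",
    "frame_to_samples",
    "frame_to_observations",
    "frame_to_anchors",
    "load_config",
    "params_from_mapping",
    "file_digest",
    "log_run",
]

logger = logging.getLogger("cuaging")

_REQUIRED = ("sample_id", "ph", "corg_pct", "temp_k")


@dataclass
class RunConfig:
    """Parsed YAML configuration; defaults reproduce the published model."""

    params: ModelParams = field(default_factory=ModelParams)
    simulate: SoilGenConfig = field(default_factory=SoilGenConfig)
    anchor_weight: float = 1.0
    n_starts: int = 10
    seed: int = 0
    free_pk: bool = False


def _package_version() -> str:
    try:
        return version("cuaging")
    except PackageNotFoundError:
        return "unknown"


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def log_run(command: str, seed=None, config_digest=None, inputs=()):
    """Log everything needed to reproduce a deterministic run."""
    logger.info("cuaging %s: command=%s", _package_version(), command)
    if seed is not None:
        logger.info("seed=%s", seed)
    if config_digest is not None:
        logger.info("config sha256=%s", config_digest)
    for p in inputs:
        logger.info("input %s sha256=%s", p, file_digest(p))


def _read_delimited(path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab; decimal point only
    df = pd.read_csv(path, sep=None, engine="python", comment="#", skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _require_numeric(df: pd.DataFrame, columns) -> None:
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()] + 2  # header is line 1
        if len(bad):
            raise ValueError(f"column '{col}': non-numeric values at line(s) {list(bad)}")
        if df[col].isna().any():
            rows = list(df.index[df[col].isna()] + 2)
            raise ValueError(f"column '{col}': missing values at line(s) {rows}")
        df[col] = vals


def read_observation_table(path) -> pd.DataFrame:
    """Read and validate an observation table; normalizes time to days."""
    df = _read_delimited(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if "time_days" not in df.columns:
        if "time_years" not in df.columns:
            raise ValueError("missing required column(s): time_days (or time_years)")
        df["time_days"] = pd.to_numeric(df["time_years"], errors="coerce") * DAYS_PER_YEAR
        df = df.drop(columns=["time_years"])
    numeric = ["ph", "corg_pct", "temp_k", "time_days"]
    for opt in ("e_add_obs", "total_cu_mg_kg", "weight"):
        if opt in df.columns:
            numeric.append(opt)
    _require_numeric(df, numeric)
    return df


def read_isotope_table(path) -> pd.DataFrame:
    """Read an isotope-measurement table (sample_id, spike_total_mg_kg, ir_meas[, ir_nat])."""
    df = _read_delimited(path)
    missing = [c for c in ("sample_id", "spike_total_mg_kg", "ir_meas") if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    numeric = ["spike_total_mg_kg", "ir_meas"]
    for opt in ("ir_nat", "e_control_mg_kg", "cu_added_mg_kg"):
        if opt in df.columns:
            numeric.append(opt)
    _require_numeric(df, numeric)
    return df


def read_anchor_table(path) -> pd.DataFrame:
    """Read a trend-anchor table (observation columns plus e_add_target)."""
    df = read_observation_table(path)
    if "e_add_target" not in df.columns:
        raise ValueError("missing required column(s): e_add_target")
    _require_numeric(df, ["e_add_target"])
    return df


def frame_to_samples(df: pd.DataFrame) -> list:
    return [
        SoilSample(
            str(r.sample_id),
            float(r.ph),
            float(r.corg_pct),
            float(r.temp_k),
            float(r.time_days),
        )
        for r in df.itertuples(index=False)
    ]


def frame_to_observations(df: pd.DataFrame) -> list:
    if "e_add_obs" not in df.columns:
        raise ValueError("missing required column(s): e_add_obs")
    samples = frame_to_samples(df)
    weights = df["weight"] if "weight" in df.columns else np.ones(len(df))
    return [
        EObservation(sample=s, e_add_obs=float(e), weight=float(w))
        for s, e, w in zip(samples, df["e_add_obs"], weights)
    ]


def frame_to_anchors(df: pd.DataFrame, weight: float = 1.0) -> list:
    samples = frame_to_samples(df)
    weights = df["weight"] if "weight" in df.columns else np.full(len(df), weight)
    return [
        TrendAnchor(sample=s, e_add_target=float(e), weight=float(w))
        for s, e, w in zip(samples, df["e_add_target"], weights)
    ]


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a table as CSV with 6 significant digits; optional # comment line."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def write_report(report: dict, path) -> None:
    """Flat key-value plain-text report at full precision."""
    with open(path, "w") as fh:
        for key, val in report.items():
            if isinstance(val, float):
                fh.write(f"{key}: {val!r}\n")
            else:
                fh.write(f"{key}: {val}\n")


def fit_report_dict(fit: FitResult, seed, n_starts) -> dict:
    p = fit.params
    return {
        "B": p.b,
        "C": p.c,
        "N": p.n,
        "F": p.f,
        "G": p.g,
        "K": p.k,
        "pK0": p.pk0,
        "r2": fit.r2,
        "rmse": fit.rmse,
        "n_obs": fit.n_obs,
        "objective": fit.objective,
        "converged": fit.converged,
        "n_function_evals": fit.n_iterations,
        "free_parameters": ",".join(fit.free),
        "seed": seed,
        "n_starts": n_starts,
        "version": _package_version(),
    }


def params_from_mapping(mapping: dict) -> ModelParams:
    """Build ModelParams from a YAML/JSON mapping; accepts upper- or lower-case keys."""
    known = {"b", "c", "n", "f", "g", "k", "pk0"}
    kwargs = {}
    for key, val in mapping.items():
        lk = str(key).lower()
        if lk not in known:
            raise ValueError(f"unknown model parameter '{key}'")
        kwargs[lk] = float(val)
    return ModelParams().replace(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration (all blocks optional)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    if "params" in raw:
        cfg.params = params_from_mapping(raw["params"])
    if "simulate" in raw:
        sim = raw["simulate"]
        cfg.simulate = SoilGenConfig(
            n=int(sim.get("n", 100)),
            ph_range=tuple(sim.get("ph_range", (2.98, 7.52))),
            corg_range=tuple(sim.get("corg_range", (0.41, 23.32))),
            temp_range=tuple(sim.get("temp_range", (278.0, 298.0))),
            time_range_days=tuple(sim.get("time_range_days", (1.0, 30000.0))),
            noise_sd=float(sim.get("noise_sd", 0.05)),
            seed=int(sim.get("seed", 0)),
        )
    fit = raw.get("fit", {})
    cfg.anchor_weight = float(fit.get("anchor_weight", 1.0))
    cfg.n_starts = int(fit.get("n_starts", 10))
    cfg.seed = int(fit.get("seed", raw.get("seed", 0)))
    cfg.free_pk = bool(fit.get("free_pk", False))
    return cfg
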
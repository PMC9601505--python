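"""File formats: time-series/PSD CSV, candidates JSON, run configuration YAML.

Conventions: times in days, frequencies in 1/days, angular frequency
``omega = 2 pi f``.  Candidate JSON is schema-versioned; floats survive
round trips exactly (shortest round-trip decimal representation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from lookelsewhere.noise import PowerSpectrum, TimeSeries

__all__ = [
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_psd_csv",
    "write_psd_csv",
    "candidates_to_json",
    "candidates_from_json",
    "RunConfig",
    "load_config",
    "ConfigError",
]

CANDIDATE_SCHEMA = 1


class ConfigError(ValueError):
    """Configuration or input-file validation failure."""


def read_timeseries_csv(path: str | Path) -> TimeSeries:
    """Read a two-column ``time,value`` CSV (header required, days/flux)."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["time", "value"]:
        raise ConfigError(
            f"{path}: line 1: expected header 'time,value', got {list(df.columns)!r}"
        )
    try:
        return TimeSeries(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_timeseries_csv(series: TimeSeries, path: str | Path) -> None:
    pd.DataFrame({"time": series.times, "value": series.values}).to_csv(
        path, index=False
    )


def read_psd_csv(path: str | Path) -> PowerSpectrum:
    """Read a two-column ``frequency,power`` CSV (1/days, flux^2 days)."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["frequency", "power"]:
        raise ConfigError(
            f"{path}: line 1: expected header 'frequency,power', got {list(df.columns)!r}"
        )
    try:
        return PowerSpectrum(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_psd_csv(psd: PowerSpectrum, path: str | Path) -> None:
    pd.DataFrame({"frequency": psd.frequencies, "power": psd.power}).to_csv(
        path, index=False
    )


def candidates_to_json(candidates: list, path: Optional[str | Path] = None) -> str:
    """Serialize candidates (schema 1).  Returns the JSON text."""
    payload = {
        "schema": CANDIDATE_SCHEMA,
        "candidates": [
            {
                "amplitude": c.params.amplitude,
                "period": c.params.period,
                "phase": c.params.phase,
                "duration": c.params.duration,
                "energy": c.significance.energy,
                "snr": math.sqrt(2.0 * c.significance.energy),
                "log_bf": c.significance.log_bf,
                "log_bf_reduced": c.significance.log_bf_reduced,
                "p_asym": c.significance.p_asym,
                "p_value": c.significance.p_value,
                "prior_choice": c.prior_choice,
                "method": c.method,
                "alias_flag": bool(c.alias_flag),
            }
            for c in candidates
        ],
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def candidates_from_json(path: str | Path) -> list[dict]:
    data = json.loads(Path(path).read_text())
    if data.get("schema") != CANDIDATE_SCHEMA:
        raise ConfigError(f"{path}: unsupported candidates schema {data.get('schema')!r}")
    return data["candidates"]


# ---------------------------------------------------------------------------
# Run configuration


_NOISE_KEYS = {"kind", "sigma", "index", "knee", "nu", "psd_file", "white_fraction"}
_SEARCH_KEYS = {
    "period_min",
    "period_max",
    "tau_mode",
    "n_tau",
    "alpha",
    "prior",
    "k",
    "method",
    "stellar_density",
    "density_sigma_frac",
}
_CAL_KEYS = {"n_sims", "seed", "n_boot"}
_TOP_KEYS = {"n", "cadence", "noise", "search", "calibration", "output_dir"}


@dataclass
class RunConfig:
    """Validated run configuration (see ``load_config``)."""

    n: int = 9600
    cadence: float = 1.0 / 48.0
    noise: dict = field(default_factory=lambda: {"kind": "white", "sigma": 1.0})
    search: dict = field(
        default_factory=lambda: {
            "period_min": 3.0,
            "period_max": 100.0,
            "tau_mode": "free",
            "n_tau": 12,
            "alpha": 3.0,
            "prior": "wide",
            "k": 5,
            "method": "cubature",
        }
    )
    calibration: dict = field(default_factory=lambda: {"n_sims": 500, "seed": 0})
    output_dir: str = "."

    def __post_init__(self) -> None:
        for key, allowed, name in [
            (self.noise, _NOISE_KEYS, "noise"),
            (self.search, _SEARCH_KEYS, "search"),
            (self.calibration, _CAL_KEYS, "calibration"),
        ]:
            unknown = set(key) - allowed
            if unknown:
                raise ConfigError(f"unknown {name} keys: {sorted(unknown)}")
        if self.n < 8:
            raise ConfigError("n must be >= 8")
        if self.cadence <= 0:
            raise ConfigError("cadence must be positive")
        kind = self.noise.get("kind", "white")
        if kind not in ("white", "powerlaw", "red_white", "student_t", "file"):
            raise ConfigError(f"unknown noise kind {kind!r}")
        if self.search.get("tau_mode", "free") not in ("free", "fixed_kepler"):
            raise ConfigError("search.tau_mode must be 'free' or 'fixed_kepler'")
        if self.search.get("prior", "wide") not in ("circular", "wide", "realistic"):
            raise ConfigError("search.prior must be circular, wide or realistic")
        if self.search.get("method", "cubature") not in ("laplace", "cubature"):
            raise ConfigError("search.method must be laplace or cubature")


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML run configuration.

    Unknown keys are rejected with the offending names; scalar types are
    checked by the dataclass validation.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f"line {mark.line + 1}: " if mark else ""
        raise ConfigError(f"{path}: {line}{exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys: {sorted(unknown)}")
    return RunConfig(**raw)
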
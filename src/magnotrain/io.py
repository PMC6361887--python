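"""Configuration and table I/O with validation.

Cohort configs are YAML mappings mirroring :class:`~magnotrain.cohort.
CohortConfig`; validation errors name the offending key. Cohort tables
round-trip losslessly through long-format CSV; loading checks schema
and value ranges and reports the offending row index.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Dict, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import cohort as _cohort
from .cohort import CohortConfig, GROUPS, MEASURES, SESSIONS

__all__ = [
    "ConfigError",
    "load_config",
    "config_to_dict",
    "save_config",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_json",
]

PathLike = Union[str, Path]

COHORT_COLUMNS = ("participant_id", "group", "age", "session", "measure", "value")


class ConfigError(ValueError):
    """Configuration problem; the message names the offending key."""


def load_config(path: PathLike) -> CohortConfig:
    """Read and validate a YAML cohort configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: Dict[str, Any]) -> CohortConfig:
    defaults = _cohort.default_config()
    known = {
        "n_experimental",
        "n_control",
        "trajectories",
        "between_sd",
        "within_sd",
        "rdk_mode",
        "enforce_inclusion",
        "apra_cutoff",
        "rdk_cutoff",
    }
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown config key: {key!r}")

    traj = {m: {g: tuple(t) for g, t in d.items()}
            for m, d in defaults.trajectories.items()}
    for m, d in (raw.get("trajectories") or {}).items():
        if m not in MEASURES:
            raise ConfigError(f"trajectories: unknown measure {m!r}")
        for g, t in d.items():
            if g not in GROUPS:
                raise ConfigError(f"trajectories[{m!r}]: unknown group {g!r}")
            if len(t) != len(SESSIONS):
                raise ConfigError(
                    f"trajectories[{m!r}][{g!r}] must list "
                    f"{len(SESSIONS)} session values"
                )
            traj[m][g] = tuple(float(v) for v in t)

    def _sd_table(key: str, base: Dict[str, float]) -> Dict[str, float]:
        out = dict(base)
        for m, v in (raw.get(key) or {}).items():
            if m not in MEASURES:
                raise ConfigError(f"{key}: unknown measure {m!r}")
            if float(v) < 0:
                raise ConfigError(f"{key}[{m!r}] must be >= 0")
            out[m] = float(v)
        return out

    try:
        return CohortConfig(
            n_experimental=int(raw.get("n_experimental", defaults.n_experimental)),
            n_control=int(raw.get("n_control", defaults.n_control)),
            trajectories=traj,
            between_sd=_sd_table("between_sd", defaults.between_sd),
            within_sd=_sd_table("within_sd", defaults.within_sd),
            rdk_mode=raw.get("rdk_mode", defaults.rdk_mode),
            enforce_inclusion=bool(
                raw.get("enforce_inclusion", defaults.enforce_inclusion)
            ),
            apra_cutoff=float(raw.get("apra_cutoff", defaults.apra_cutoff)),
            rdk_cutoff=float(raw.get("rdk_cutoff", defaults.rdk_cutoff)),
        )
    except ValueError as exc:  # dataclass-level validation
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: CohortConfig) -> Dict[str, Any]:
    return {
        "n_experimental": config.n_experimental,
        "n_control": config.n_control,
        "trajectories": {
            m: {g: list(t) for g, t in d.items()}
            for m, d in config.trajectories.items()
        },
        "between_sd": dict(config.between_sd),
        "within_sd": dict(config.within_sd),
        "rdk_mode": config.rdk_mode,
        "enforce_inclusion": config.enforce_inclusion,
        "apra_cutoff": config.apra_cutoff,
        "rdk_cutoff": config.rdk_cutoff,
    }


def save_config(config: CohortConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def write_cohort_csv(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, index=False, columns=list(COHORT_COLUMNS))


def read_cohort_csv(path: PathLike) -> pd.DataFrame:
    """Load and validate a long-format cohort CSV.

    Checks the schema, group/session/measure vocabularies and value
    ranges; errors cite the offending row index.
    """
    table = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    for i, row in table.iterrows():
        if row["group"] not in GROUPS:
            raise ValueError(f"row {i}: unknown group {row['group']!r}")
        if row["session"] not in SESSIONS:
            raise ValueError(f"row {i}: unknown session {row['session']!r}")
        if row["measure"] not in MEASURES:
            raise ValueError(f"row {i}: unknown measure {row['measure']!r}")
        v = row["value"]
        if not np.isfinite(v):
            raise ValueError(f"row {i}: non-finite value")
        if row["measure"] == "rdk_threshold" and not 0 < v <= 100:
            raise ValueError(
                f"row {i}: rdk_threshold {v} outside (0, 100]"
            )
        if row["measure"] in _cohort.COUNT_MEASURES and (v < 0 or v != int(v)):
            raise ValueError(f"row {i}: {row['measure']} must be a count, got {v}")
    return table


def write_json(obj: Any, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x: Any):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
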
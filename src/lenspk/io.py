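"""Configuration, CSV and manifest input/output.

Two config dialects are accepted: flat ``key = value`` lines whose
values carry unit suffixes ("Q_Aq = 4.2 uL/min"), or a nested YAML
document with sections anatomy/physiology/drug/lens/release/solver.
Keys are the model symbols (V_t, Q_UvSc, K_ScCh, ...).

Trajectory CSV: versioned header comment, then columns time_s, C_t,
C_ScCh, C_Ret, C_Vit, C_Aq, C_Ep (empty when not computable) and the
cumulative sink_* columns.  Numeric fields survive a round trip to at
least 12 significant digits.

Dataset CSV: two columns; the time column header declares its unit
(time_s / time_min / time_h / time_day) and is normalized on read.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import sys
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .model import COMPARTMENTS, SINKS, Trajectory
from .parameters import (ModelParameters, normalize_units, params_hash,
                         rabbit_dexamethasone, rabbit_diffusion_demo,
                         to_flat_dict, validate)
from .release import AqueousPKDataset, ReleaseDataset

__all__ = [
    "read_config", "write_config", "load_preset",
    "write_trajectory", "read_trajectory", "trajectory_to_frame",
    "read_release_csv", "read_aqueous_csv", "write_dataset_csv",
    "write_manifest",
]

TRAJECTORY_HEADER = "# lenspk trajectory v1"
_TIME_UNITS = {"time_s": 1.0, "time_min": 60.0, "time_h": 3600.0,
               "time_day": 86400.0}

PRESETS = {"rabbit-dexamethasone": rabbit_dexamethasone,
           "rabbit-diffusion-demo": rabbit_diffusion_demo}


class ConfigError(ValueError):
    pass


def load_preset(name: str) -> ModelParameters:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; "
                          f"available: {sorted(PRESETS)}") from None


def _parse_flat(text: str) -> dict:
    raw = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        raw[key.strip()] = val.strip()
    return raw


def read_config(path: Union[str, Path]) -> ModelParameters:
    """Parse, unit-normalize and validate a configuration file.

    Fatal diagnostics abort with a message naming the offending key.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ConfigError(f"{path}: empty configuration")

    body = "\n".join(ln for ln in text.splitlines()
                     if not ln.strip().startswith("#"))
    if "=" in body:          # flat key = value dialect (YAML uses ':')
        raw = _parse_flat(text)
    else:
        loaded = yaml.safe_load(text)
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: expected a mapping")
        raw = loaded
    try:
        params = normalize_units(raw)
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    fatal = [d for d in validate(params) if d.fatal]
    if fatal:
        msgs = "; ".join(f"{d.key}: {d.message}" for d in fatal)
        raise ConfigError(f"{path}: invalid parameters: {msgs}")
    return params


def write_config(params: ModelParameters, path: Union[str, Path]) -> None:
    """Write a flat-dialect config (internal units, no suffixes)."""
    lines = [f"# lenspk config (internal units: cm, mL, s, ng)"]
    for key, val in to_flat_dict(params).items():
        lines.append(f"{key} = {val!r}" if isinstance(val, str)
                     else f"{key} = {val:.12g}" if isinstance(val, float)
                     else f"{key} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Trajectory CSV
# --------------------------------------------------------------------------

def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    cols = {"time_s": traj.times}
    for name in COMPARTMENTS:
        cols[name] = traj.concentrations[name]
    cols["C_Ep"] = traj.concentrations.get(
        "C_Ep", np.full(traj.times.size, np.nan))
    for name in SINKS:
        cols[f"sink_{name}"] = traj.sinks[name]
    cols["delivered"] = traj.delivered
    if traj.lens_mass is not None:
        cols["lens_mass"] = traj.lens_mass
    return pd.DataFrame(cols)


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    frame = trajectory_to_frame(traj)
    with open(path, "w", newline="") as fh:
        fh.write(TRAJECTORY_HEADER + "\n")
        fh.write(f"# mode={traj.mode} params={traj.params_hash}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_trajectory(path: Union[str, Path]) -> Trajectory:
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file; expected '{TRAJECTORY_HEADER}' "
                         "followed by a CSV table")
    lines = text.splitlines()
    if not lines[0].startswith(TRAJECTORY_HEADER):
        raise ValueError(f"{path}: missing header '{TRAJECTORY_HEADER}'")
    meta = {}
    if len(lines) > 1 and lines[1].startswith("#"):
        for tok in lines[1].lstrip("# ").split():
            if "=" in tok:
                k, _, v = tok.partition("=")
                meta[k] = v
    frame = pd.read_csv(_io.StringIO(text), comment="#")
    times = frame["time_s"].to_numpy(float)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    conc = {n: frame[n].to_numpy(float) for n in COMPARTMENTS}
    if not frame["C_Ep"].isna().all():
        conc["C_Ep"] = frame["C_Ep"].to_numpy(float)
    sinks = {n: frame[f"sink_{n}"].to_numpy(float) for n in SINKS}
    return Trajectory(
        times=times, concentrations=conc, sinks=sinks,
        delivered=frame["delivered"].to_numpy(float),
        mode=meta.get("mode", "release"),
        params_hash=meta.get("params", ""),
        lens_mass=frame["lens_mass"].to_numpy(float)
        if "lens_mass" in frame else None)


# --------------------------------------------------------------------------
# Dataset CSV (release / aqueous)
# --------------------------------------------------------------------------

def _read_two_column(path: Union[str, Path]):
    frame = pd.read_csv(path, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, value)")
    tcol = frame.columns[0]
    if tcol not in _TIME_UNITS:
        raise ValueError(f"{path}: time column must be one of "
                         f"{sorted(_TIME_UNITS)}, got {tcol!r}")
    t = frame[tcol].to_numpy(float) * _TIME_UNITS[tcol]
    return t, frame[frame.columns[1]].to_numpy(float)


def read_release_csv(path: Union[str, Path]) -> ReleaseDataset:
    t, v = _read_two_column(path)
    return ReleaseDataset(t, v)


def read_aqueous_csv(path: Union[str, Path]) -> AqueousPKDataset:
    t, v = _read_two_column(path)
    return AqueousPKDataset(t, v)


def write_dataset_csv(times: np.ndarray, values: np.ndarray,
                      path: Union[str, Path], value_name: str,
                      time_unit: str = "s") -> None:
    unit_col = f"time_{time_unit}"
    if unit_col not in _TIME_UNITS:
        raise ValueError(f"unknown time unit {time_unit!r}")
    pd.DataFrame({unit_col: np.asarray(times) / _TIME_UNITS[unit_col],
                  value_name: values}).to_csv(path, index=False,
                                              float_format="%.17g")


# --------------------------------------------------------------------------
# Run manifests
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(path: Union[str, Path], params: Optional[ModelParameters],
                   outputs: list, seed: Optional[int] = None,
                   determinism: str = "exact", extra: Optional[dict] = None
                   ) -> dict:
    """JSON manifest tying outputs to their exact inputs."""
    from . import __version__
    manifest = {
        "software": f"lenspk {__version__}",
        "python": sys.version.split()[0],
        "start_time": datetime.now(timezone.utc).isoformat(),
        "config_digest": params_hash(params) if params is not None else None,
        "mode": params.mode if params is not None else None,
        "solver": (to_flat_dict(params) if params is not None else {}),
        "seed": seed,
        "determinism": determinism,
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }
    if params is not None:
        manifest["solver"] = {k: manifest["solver"][k]
                              for k in ("t_end", "output_step", "rel_tol",
                                        "abs_tol") if k in manifest["solver"]}
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
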
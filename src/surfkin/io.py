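"""Configuration and tabular I/O: parameter YAML, observation and trajectory CSV.

Parameter files are flat YAML mappings, one key per model parameter, each
either a bare number or a mapping with `value`, `fixed`, `lower`, `upper`.
Observation files are CSV with a `t_h,X_gL,S_gL,P_gL,A_gL` header, blank
cells for missing values, and experiment metadata in leading `# key: value`
comment lines. Every CLI run also emits a JSON manifest capturing the
resolved configuration, seed and paths.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import STATES, FitSpec, Observations
from .errors import ValidationError
from .params import PARAM_SPECS, KineticParameters

OBS_COLUMNS = ["t_h", "X_gL", "S_gL", "P_gL", "A_gL"]
_ALLOWED_KEYS = {"value", "fixed", "lower", "upper"}

_META_FLOATS = {
    "mu_F_1_h": "mu_F",
    "X0_g": "X0",
    "S0_g": "S0",
    "P0_g": "P0",
    "A0_g": "A0",
    "V0_L": "V0",
    "v0_L": "v0",
    "detection_limit_gL": "detection_limit",
}


def load_parameters(path) -> tuple[KineticParameters, FitSpec]:
    """Read a parameter YAML; unspecified keys fall back to the defaults.

    Returns the parameter set and a FitSpec whose free list and bounds follow
    the file's fixed flags and ranges.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: parameter file must be a mapping")
    values: dict[str, float] = {}
    fixed: dict[str, bool] = {n: s.fixed for n, s in PARAM_SPECS.items()}
    bounds: dict[str, tuple[float, float]] = {
        n: (s.lower, s.upper)
        for n, s in PARAM_SPECS.items()
        if s.lower is not None
    }
    for key, entry in raw.items():
        if key not in PARAM_SPECS:
            raise ValidationError(f"{path}: unknown parameter key {key!r}")
        if isinstance(entry, (int, float)):
            values[key] = float(entry)
            continue
        if not isinstance(entry, dict) or not set(entry) <= _ALLOWED_KEYS:
            raise ValidationError(
                f"{path}: entry for {key!r} must be a number or a mapping "
                f"with keys {_ALLOWED_KEYS}"
            )
        if "value" in entry:
            values[key] = float(entry["value"])
        if "fixed" in entry:
            fixed[key] = bool(entry["fixed"])
        if "lower" in entry or "upper" in entry:
            lo = float(entry.get("lower", bounds.get(key, (np.nan,))[0]))
            hi = float(entry.get("upper", bounds.get(key, (np.nan, np.nan))[1]))
            bounds[key] = (lo, hi)
    params = KineticParameters.defaults().replace(**values)
    params.validate()
    for key in values:
        if key in bounds and not np.isnan(bounds[key]).any():
            lo, hi = bounds[key]
            if not lo <= values[key] <= hi:
                raise ValidationError(
                    f"{path}: value {values[key]} for {key!r} outside its range "
                    f"[{lo}, {hi}]"
                )
    free = tuple(n for n in PARAM_SPECS if not fixed[n] and n in bounds)
    spec = FitSpec(free=free, bounds={n: bounds[n] for n in free})
    return params, spec


def save_parameters(path, params: KineticParameters, spec: FitSpec | None = None) -> None:
    """Write the parameter set (and optional fit metadata) as YAML."""
    out: dict[str, dict] = {}
    free = set(spec.free) if spec is not None else {
        n for n, s in PARAM_SPECS.items() if not s.fixed
    }
    for name, value in params.to_dict().items():
        entry: dict = {"value": float(value), "fixed": name not in free}
        if spec is not None and name in free:
            lo, hi = spec.bounds_of(name)
            entry["lower"], entry["upper"] = float(lo), float(hi)
        elif PARAM_SPECS[name].lower is not None:
            entry["lower"] = PARAM_SPECS[name].lower
            entry["upper"] = PARAM_SPECS[name].upper
        out[name] = entry
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def write_observations(path, obs: Observations) -> None:
    """Write one experiment to CSV with metadata comment lines."""
    lines = ["# surfkin-observations v1", f"# exp_id: {obs.exp_id}"]
    for meta_key, attr in _META_FLOATS.items():
        value = getattr(obs, attr)
        if value is not None:
            lines.append(f"# {meta_key}: {float(value)!r}")
    frame = pd.DataFrame(
        {
            "t_h": obs.times,
            "X_gL": obs.data["X"].to_numpy(),
            "S_gL": obs.data["S"].to_numpy(),
            "P_gL": obs.data["P"].to_numpy(),
            "A_gL": obs.data["A"].to_numpy(),
        }
    )
    body = frame.to_csv(index=False, float_format="%.6g", na_rep="")
    Path(path).write_text("\n".join(lines) + "\n" + body)


def read_observations(path) -> Observations:
    """Read one experiment CSV written by :func:`write_observations`."""
    path = Path(path)
    meta: dict[str, float] = {}
    exp_id = path.stem
    header_line = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip()
                    val = val.strip()
                    if key == "exp_id":
                        exp_id = val
                    elif key in _META_FLOATS:
                        meta[_META_FLOATS[key]] = float(val)
                continue
            header_line = lineno
            header = [c.strip() for c in line.split(",")]
            break
    if header_line is None:
        raise ValidationError(f"{path}: no header line found")
    if header != OBS_COLUMNS:
        raise ValidationError(
            f"{path}:{header_line}: malformed header {header!r}; "
            f"expected {OBS_COLUMNS} (units are part of the column names)"
        )
    frame = pd.read_csv(path, comment="#")
    times = frame["t_h"].to_numpy(float)
    if np.any(np.diff(times) <= 0):
        raise ValidationError(f"{path}: time column must be strictly increasing")
    data = pd.DataFrame(
        {s: frame[f"{s}_gL"].to_numpy(float) for s in STATES}
    )
    required = {"mu_F", "X0", "S0", "V0", "v0"}
    missing = required - set(meta)
    if missing:
        raise ValidationError(
            f"{path}: missing metadata comment lines for {sorted(missing)}"
        )
    return Observations(exp_id=exp_id, times=times, data=data, **meta)


def write_trajectory(path, traj) -> None:
    """Write a trajectory table (amounts, concentrations, rates, phase) to CSV."""
    traj.to_frame().to_csv(path, index=False, float_format="%.8g")


def read_trajectory_frame(path) -> pd.DataFrame:
    """Read back a trajectory CSV, validating the schema."""
    frame = pd.read_csv(path)
    required = {"t_h", "X_g", "S_g", "P_g", "A_g", "V_L", "v_L"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: trajectory file missing columns {sorted(missing)}")
    if np.any(np.diff(frame["t_h"].to_numpy(float)) <= 0):
        raise ValidationError(f"{path}: time column must be strictly increasing")
    return frame


def write_manifest(
    out_path, command: str, config_snapshot: dict, seed: int | None,
    inputs: list[str], outputs: list[str],
) -> Path:
    """Write the run manifest JSON next to the primary output."""
    manifest = {
        "command": command,
        "config": config_snapshot,
        "seed": seed,
        "version": _package_version(),
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("surfkin")
    except PackageNotFoundError:
        return "unknown"
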
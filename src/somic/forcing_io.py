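"""Readers and writers for driver tables, observations, trajectories and
parameter files.

Conventions
-----------
* Delimited tables are comma-separated UTF-8 with a mandatory header row;
  an optional ``# units: ...`` comment line declares units.
* Time is an integer month index at monthly cadence; gaps and duplicates
  are rejected rather than filled.
* Stocks are t C ha⁻¹ internally; observation files may declare
  ``kg m-2`` (1 kg C m⁻² = 10 t C ha⁻¹) and are converted on read.
* Parameter sets are flat ``key = value`` text configs keyed by the model
  symbols (k1…k5, f_s, k_m, s0, s1, cue_ref, cue_slope, q10, t_ref, w_min,
  temp_form).
* Gridded driver cubes use NetCDF3 classic via xarray's scipy backend.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ForcingRecord, ModelParams, Trajectory
from .errors import SchemaError
from .rate_modifiers import ModifierParams

__all__ = [
    "SiteRecord",
    "read_drivers",
    "write_drivers",
    "read_observations",
    "write_observations",
    "read_trajectory",
    "write_trajectory",
    "read_params",
    "write_params",
    "released_params_path",
    "read_driver_cube",
    "to_t_ha",
    "to_kg_m2",
    "KG_M2_PER_T_HA",
]

logger = logging.getLogger("somic")

#: 1 t C ha⁻¹ = 0.1 kg C m⁻².
KG_M2_PER_T_HA = 0.1

DRIVER_COLUMNS = ("time", "temp", "moisture", "litter", "clay")
TRAJ_SIG_DIGITS = 12


def to_kg_m2(x_t_ha):
    """t C ha⁻¹ → kg C m⁻²."""
    return np.asarray(x_t_ha, dtype=float) * KG_M2_PER_T_HA


def to_t_ha(x_kg_m2):
    """kg C m⁻² → t C ha⁻¹ (inverse of :func:`to_kg_m2`)."""
    return np.asarray(x_kg_m2, dtype=float) / KG_M2_PER_T_HA


@dataclass
class SiteRecord:
    """One site: drivers, observations and minimal metadata."""

    site_id: str
    clay: float
    depth_m: float
    drivers: list[ForcingRecord]
    observations: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["time", "soc"]))
    #: Ratio of pre-experiment to experimental C inputs, used for spin-up.
    pre_litter_factor: float = 1.0
    #: Rescale spun-up pools so the modeled stock matches the first
    #: observation.  True for field sites, where initial pool fractionation
    #: is unknown; synthetic sites carry a fully known initial state and
    #: set this to False.
    rescale_to_first_obs: bool = True

    def __post_init__(self):
        if not self.depth_m > 0:
            raise SchemaError(f"site {self.site_id}: depth must be > 0, got {self.depth_m}")
        if len(self.observations):
            t0, t1 = self.drivers[0].time, self.drivers[-1].time
            obs_t = self.observations["time"]
            if obs_t.min() < t0 or obs_t.max() > t1:
                raise SchemaError(
                    f"site {self.site_id}: observation times outside driver span [{t0}, {t1}]"
                )


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def _units_line(path) -> str | None:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# units:"):
                return line[len("# units:"):].strip()
            if not line.startswith("#"):
                break
    return None


def _check_time(df: pd.DataFrame, path, monthly: bool = True) -> None:
    t = df["time"]
    if t.isna().any():
        raise SchemaError(f"{path}: NaN in column 'time'")
    if t.duplicated().any():
        row = int(np.argmax(t.duplicated().to_numpy()))
        raise SchemaError(f"{path}: duplicate time stamp at row {row}")
    if not t.is_monotonic_increasing:
        raise SchemaError(f"{path}: column 'time' must be non-decreasing")
    if monthly and len(t) > 1 and not np.all(np.diff(t.to_numpy()) == 1):
        raise SchemaError(f"{path}: gaps in monthly time index are not allowed")


def read_drivers(path) -> list[ForcingRecord]:
    """Read a driver table into validated forcing records.

    Required columns: time, temp, moisture, litter, clay; optional:
    amendment (default 0), amendment_fs.  Rejects missing columns, NaN,
    non-monotone or gapped time, and out-of-range values, naming the
    offending column/row.
    """
    df = _read_table(path)
    for col in DRIVER_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    _check_time(df, path)
    for col in ("temp", "moisture", "litter", "clay"):
        if df[col].isna().any():
            row = int(df[col].isna().idxmax())
            raise SchemaError(f"{path}: NaN in column '{col}' at row {row}")
    if "amendment" not in df.columns:
        df["amendment"] = 0.0
    records = []
    for row_i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(ForcingRecord(
                time=int(row.time), temp=float(row.temp), moisture=float(row.moisture),
                litter=float(row.litter), clay=float(row.clay),
                amendment=float(row.amendment),
                amendment_fs=(float(row.amendment_fs)
                              if hasattr(row, "amendment_fs") and not pd.isna(row.amendment_fs)
                              else None),
            ))
        except Exception as e:
            raise SchemaError(f"{path}: invalid driver values at row {row_i}: {e}") from e
    return records


def write_drivers(records: Sequence[ForcingRecord], path) -> None:
    df = pd.DataFrame([{
        "time": r.time, "temp": r.temp, "moisture": r.moisture,
        "litter": r.litter, "clay": r.clay, "amendment": r.amendment,
        "amendment_fs": r.amendment_fs if r.amendment_fs is not None else np.nan,
    } for r in records])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# units: time=month index, temp=degC, moisture=[0,1] scalar, "
                 "litter/amendment=t C ha-1 month-1, clay=fraction\n")
        df.to_csv(fh, index=False)


def read_observations(path) -> pd.DataFrame:
    """Read an observation table (columns time, soc, optional soc_sd).

    The ``# units:`` header may declare ``kg m-2`` for soc; stocks are then
    converted to t C ha⁻¹.  An empty table is returned with a warning.
    """
    df = _read_table(path)
    for col in ("time", "soc"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    if len(df) == 0:
        warnings.warn(f"{path}: empty observation table", stacklevel=2)
        return df
    _check_time(df, path, monthly=False)
    if df["soc"].isna().any():
        row = int(df["soc"].isna().idxmax())
        raise SchemaError(f"{path}: NaN in column 'soc' at row {row}")
    if (df["soc"] < 0).any():
        row = int((df["soc"] < 0).idxmax())
        raise SchemaError(f"{path}: negative SOC at row {row}")
    units = _units_line(path) or ""
    if "kg m-2" in units or "kg/m2" in units:
        df["soc"] = to_t_ha(df["soc"])
        if "soc_sd" in df.columns:
            df["soc_sd"] = to_t_ha(df["soc_sd"])
    return df


def write_observations(df: pd.DataFrame, path, units: str = "t ha-1") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# units: time=month index, soc={units}\n")
        out = df.copy()
        if units in ("kg m-2", "kg/m2"):
            out["soc"] = to_kg_m2(out["soc"])
            if "soc_sd" in out.columns:
                out["soc_sd"] = to_kg_m2(out["soc_sd"])
        out.to_csv(fh, index=False)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a delimited table, one row per time step.

    Column order is stable: time, the five pools, total_soc, co2, uptake,
    sorption, then the five effective rate factors.
    """
    df = traj.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# units: time=month index, pools/total_soc=t C ha-1, "
                 "fluxes=t C ha-1 month-1, k_eff=month-1\n")
        df.to_csv(fh, index=False, float_format=f"%.{TRAJ_SIG_DIGITS}g")


def read_trajectory(path) -> pd.DataFrame:
    df = _read_table(path)
    if "time" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'time'")
    return df


# ---------------------------------------------------------------------------
# Parameter configs

_MOD_KEYS = ("temp_form", "q10", "t_ref", "w_min", "k_m", "s0", "s1", "cue_ref", "cue_slope")
_CORE_KEYS = ("k1", "k2", "k3", "k4", "k5", "f_s")


def read_params(path) -> ModelParams:
    """Read a flat ``key = value`` parameter config."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    raw: dict[str, str] = {}
    for ln, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"{path}: line {ln} is not 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        raw[key] = val
    unknown = set(raw) - set(_MOD_KEYS) - set(_CORE_KEYS)
    if unknown:
        raise SchemaError(f"{path}: unknown parameter keys {sorted(unknown)}")
    mod_kw = {k: (raw[k] if k == "temp_form" else float(raw[k])) for k in _MOD_KEYS if k in raw}
    core_kw = {k: float(raw[k]) for k in _CORE_KEYS if k in raw}
    return ModelParams(modifiers=ModifierParams(**mod_kw), **core_kw)


def write_params(p: ModelParams, path) -> None:
    lines = ["# SOMic parameter set (rates month-1, pools t C ha-1)"]
    for k in _CORE_KEYS:
        lines.append(f"{k} = {getattr(p, k)!r}")
    for k in _MOD_KEYS:
        v = getattr(p.modifiers, k)
        lines.append(f"{k} = {v if isinstance(v, str) else repr(v)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def released_params_path() -> Path:
    """Path of the shipped released parameter config."""
    return Path(__file__).parent / "data" / "released.cfg"


# ---------------------------------------------------------------------------
# Gridded cubes


def read_driver_cube(path) -> "list[tuple[str, list[ForcingRecord]]]":
    """Read a NetCDF driver cube (dims cell × time; variables temp, moisture,
    litter, clay) into per-cell forcing sequences."""
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy")
    for var in ("temp", "moisture", "litter", "clay"):
        if var not in ds:
            raise SchemaError(f"{path}: missing variable '{var}'")
    out = []
    times = [int(t) for t in ds["time"].values]
    for cell in ds["cell"].values:
        sub = ds.sel(cell=cell)
        clay = float(sub["clay"].values) if sub["clay"].ndim == 0 else None
        recs = [
            ForcingRecord(
                time=times[j],
                temp=float(sub["temp"].values[j]),
                moisture=float(sub["moisture"].values[j]),
                litter=float(sub["litter"].values[j]),
                clay=clay if clay is not None else float(sub["clay"].values[j]),
            )
            for j in range(len(times))
        ]
        out.append((str(cell), recs))
    ds.close()
    return out
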
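"""CSV schemas, pipeline configuration and run manifests.

All tabular interchange is plain CSV with header rows and ISO-8601 local
timestamps.  The fix table carries (bird_id, timestamp, x, y); the nest
table carries one row per nest attempt with onset/termination dates, fates,
nest coordinates and mean concealment.  Schema violations raise
:class:`SchemaError` naming the offending column.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import pandas as pd
import yaml

FIX_COLUMNS = ["bird_id", "timestamp", "x", "y"]
NEST_COLUMNS = [
    "nest_id", "bird_id", "site", "year", "attempt", "onset", "termination",
    "nest_fate", "female_fate", "nest_x", "nest_y", "concealment_cm",
]
RANGE_COLUMNS = ["nest_id", "date", "area_ha"]


class SchemaError(ValueError):
    """A required column is missing or unparsable."""


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; defaults follow the study protocol."""

    buffer_m: float = 27.5
    dbbmm_window: int = 7
    dbbmm_margin: int = 3
    dbbmm_location_error_m: float = 20.0
    ud_level: float = 0.99
    grid_cell_m: float = 10.0
    collinearity_threshold: float = 0.7
    night_fix_weight: float = 1.0
    standardize: bool = True
    use_dbbmm: bool = True
    nest_iter: int = 4_000
    nest_burn_in: int = 1_000
    female_iter: int = 7_000
    female_burn_in: int = 2_000
    n_chains: int = 3
    thin: int = 3
    seed: int = 0
    n_birds: int = 278
    censor_short_rate: float = 0.02
    output_dir: str = "."
    _user_set: set = field(default_factory=set, repr=False)

    _PROTOCOL_DEFAULTS = {
        "buffer_m", "dbbmm_window", "dbbmm_margin", "dbbmm_location_error_m",
        "ud_level", "collinearity_threshold", "nest_iter", "nest_burn_in",
        "female_iter", "female_burn_in", "n_chains", "thin",
    }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(raw) - valid
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg._user_set = set(raw)
        return cfg

    def manifest(self) -> dict:
        """Every setting with its provenance (protocol default vs user)."""
        out = {}
        for f in dataclasses.fields(self):
            if f.name.startswith("_"):
                continue
            source = (
                "user" if f.name in self._user_set
                else ("protocol-default" if f.name in self._PROTOCOL_DEFAULTS else "package-default")
            )
            out[f.name] = {"value": getattr(self, f.name), "source": source}
        return out

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2, default=str)


def _require(df: pd.DataFrame, columns, what: str) -> None:
    for c in columns:
        if c not in df.columns:
            raise SchemaError(f"{what} table is missing column {c!r}")


def read_fixes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, FIX_COLUMNS, "fix")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as err:
        raise SchemaError(f"fix table column 'timestamp' is not ISO-8601: {err}") from err
    for c in ("x", "y"):
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise SchemaError(f"fix table column {c!r} must be numeric")
    order_ok = df.groupby("bird_id")["timestamp"].is_monotonic_increasing
    if not order_ok.all():
        bad = order_ok[~order_ok].index[0]
        raise SchemaError(f"fix timestamps not strictly increasing for bird {bad!r}")
    return df


def write_fixes(df: pd.DataFrame, path) -> None:
    out = df[FIX_COLUMNS].copy()
    out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_nests(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, NEST_COLUMNS, "nest")
    for c in ("onset", "termination"):
        try:
            df[c] = pd.to_datetime(df[c])
        except (ValueError, TypeError) as err:
            raise SchemaError(f"nest table column {c!r} is not a date: {err}") from err
    if ((df["attempt"] < 1) | (df["attempt"] > 4)).any():
        raise SchemaError("nest table column 'attempt' must be 1-4")
    return df


def write_nests(df: pd.DataFrame, path) -> None:
    df[NEST_COLUMNS].to_csv(path, index=False)


def read_ranges(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, RANGE_COLUMNS, "range-size")
    df["date"] = pd.to_datetime(df["date"])
    return df


def read_exposure(path) -> pd.DataFrame:
    # behavioral covariate columns may legitimately be absent if the
    # collinearity screen removed them; only the core schema is required
    df = pd.read_csv(path)
    _require(
        df,
        ["nest_id", "site", "year", "attempt", "day", "nest_alive", "female_alive"],
        "exposure",
    )
    return df


def write_ud_grid(ud, path) -> None:
    """Plain-text raster export: header with origin/cell size, then masses."""
    with open(path, "w") as fh:
        fh.write(f"# origin_x {ud.x[0]:.3f} origin_y {ud.y[0]:.3f} cell_m {ud.cell_m}\n")
        for row in ud.masses:
            fh.write(" ".join(f"{v:.6e}" for v in row) + "\n")
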
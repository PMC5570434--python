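"""Tabular I/O and run configuration.

All tables are comma-delimited UTF-8 with one header row; units are
embedded in the column names (positions in um, times in s, moduli in kPa).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .activation import CalciumTrace
from .fem import StrainProfile
from .materials import ElasticityField


class TableError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Strain profiles
# ---------------------------------------------------------------------------

def read_strain_profile(path) -> StrainProfile:
    """Read a (position_um, strain) table; negative strain = shortening."""
    df = _read_table(path, ["position_um", "strain"])
    pos = df["position_um"].to_numpy(float)
    order = np.argsort(pos)
    pos = pos[order]
    dup = np.nonzero(np.diff(pos) == 0)[0]
    if len(dup):
        raise TableError(f"duplicate position {pos[dup[0]]} um in {path}")
    return StrainProfile(pos, df["strain"].to_numpy(float)[order])


def write_strain_profile(profile: StrainProfile, path) -> None:
    pd.DataFrame({"position_um": profile.positions,
                  "strain": profile.strain}).to_csv(path, index=False,
                                                    float_format="%.17g")


# ---------------------------------------------------------------------------
# Calcium traces
# ---------------------------------------------------------------------------

def read_calcium_traces(path) -> list[CalciumTrace]:
    """Read (time_s, F_over_F0, position_um) long-format transients.

    The position column may contain the literal string "global" for the
    cell-averaged transient.
    """
    df = _read_table(path, ["time_s", "F_over_F0", "position_um"])
    traces = []
    for pos, grp in df.groupby("position_um", sort=False):
        p = "global" if str(pos) == "global" else float(pos)
        grp = grp.sort_values("time_s")
        traces.append(CalciumTrace(times=grp["time_s"].to_numpy(float),
                                   values=grp["F_over_F0"].to_numpy(float),
                                   position=p))
    return traces


def write_calcium_traces(traces, path) -> None:
    frames = [pd.DataFrame({"time_s": t.times, "F_over_F0": t.values,
                            "position_um": t.position}) for t in traces]
    pd.concat(frames).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Elasticity fields
# ---------------------------------------------------------------------------

def write_elasticity_field(field: ElasticityField, path) -> None:
    field.to_table().to_csv(path, index=False, float_format="%.17g")


def read_elasticity_field(path, mode: str = "log-linear",
                          bounds=(0.1, 100.0)) -> ElasticityField:
    df = _read_table(path, ["x_um", "E_kPa"])
    return ElasticityField(df["x_um"].to_numpy(float),
                           df["E_kPa"].to_numpy(float),
                           mode=mode, bounds=bounds)


def _read_table(path, required_cols) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TableError(f"cannot read table {path}: {exc}") from exc
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing columns {missing} "
                         f"(found {list(df.columns)})")
    numeric = [c for c in required_cols if c != "position_um"]
    for c in numeric:
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # header + 1-based
            raise TableError(f"{path}: non-numeric value in column {c!r} "
                             f"at line {line}")
        df[c] = pd.to_numeric(df[c])
    return df


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved configuration of a run; serialized next to the outputs."""

    # geometry / mesh
    mesh_path: str | None = None
    length_um: float = 117.0
    width_um: float = 32.0
    corner_rounding: float = 0.4
    target_edge_length_um: float = 1.0
    linescan_spacing_um: float = 0.28
    anchor_band_um: float = 2.0
    # materials
    poisson: float = 0.49
    # activation
    nH: float = 2.6
    f_max_kPa: float = 54.33
    eps_opt: float = 0.23
    s: float = 0.24
    SL0_um: float = 1.9
    # boundary conditions
    alpha_kPa_per_um: float = 1e-2
    # solver
    dt_s: float = 3.2e-3
    t_end_s: float = 1.0
    # inverse
    coarse_regions: int = 20
    fine_segments: int = 200
    E_bounds_kPa: tuple = (0.1, 100.0)
    multistart: int = 5
    include_fmax: bool = False
    include_alpha: bool = False
    # misc
    seed: int = 0
    out_dir: str = "out"
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib
        with open(path, "rb") as f:
            data = tomllib.load(f)
        flat = {}
        for key, val in data.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        known = {f_.name for f_ in cls.__dataclass_fields__.values()}
        kwargs = {k: v for k, v in flat.items() if k in known}
        extras = {k: v for k, v in flat.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extras = extras
        if "E_bounds_kPa" in kwargs:
            cfg.E_bounds_kPa = tuple(kwargs["E_bounds_kPa"])
        return cfg

    def write(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, default=str) + "\n")
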
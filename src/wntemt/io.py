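"""Configuration loading, shipped parameter tables and CSV writers.

Parameter sets, Dvl protocols and sampling ranges are flat YAML (or JSON)
files; the package ships the model's reference tables as fixtures:

``table1.yaml``
    dimensional rate constants (nM, minutes),
``table2.yaml``
    the published nondimensional constants (loss rates rounded to 1),
``table2_exact.yaml``
    the exact nondimensionalization of table1 (loss rates 0.99),
``table3.yaml`` / ``table4.yaml``
    uniform sampling ranges for the dimensional / nondimensional
    sensitivity analysis,
``fig2a.yaml`` / ``fig2b.yaml``
    the sub-threshold (d = 1.2) and supra-threshold (d = 5.4) Dvl pulse
    protocols.

All CSV output carries a commented metadata header (version, seed,
tolerances) and round-trips through the matching reader.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .model import (
    DIMENSIONAL_NAMES,
    HILL_NAMES,
    NONDIM_NAMES,
    DimensionalParams,
    Frame,
    NondimParams,
)
from .sensitivity import SamplingRange
from .simulate import SignalProtocol

FIXTURES = (
    "table1", "table2", "table2_exact", "table3", "table4", "fig2a", "fig2b",
)


def fixture_path(name: str) -> Path:
    """Path of a shipped fixture file by short name (e.g. ``"table2"``)."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; have {FIXTURES}")
    res = importlib.resources.files("wntemt") / "fixtures" / f"{name}.yaml"
    return Path(str(res))


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def load_params(path: str | Path, frame: Frame) -> DimensionalParams | NondimParams:
    """Load and validate a parameter file for the given frame.

    Keys must be exactly the parameter names of that frame (alpha1..IC_D
    plus n1..n4 dimensionally; A1..F2 plus n1..n4 nondimensionally); missing
    and unknown keys are reported by name.
    """
    data = _load_mapping(path)
    expected = set(
        (DIMENSIONAL_NAMES if frame == "dimensional" else NONDIM_NAMES)
        + HILL_NAMES
    )
    missing = expected - data.keys()
    if missing:
        raise KeyError(f"{path}: missing parameter(s) {sorted(missing)}")
    unknown = data.keys() - expected
    if unknown:
        raise KeyError(f"{path}: unknown key(s) {sorted(unknown)}")
    for key, value in data.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValueError(f"{path}: value for {key!r} is not numeric: {value!r}")
    cls = DimensionalParams if frame == "dimensional" else NondimParams
    return cls(**{k: float(v) for k, v in data.items()})


def load_protocol(path: str | Path) -> SignalProtocol:
    """Load a piecewise-constant Dvl protocol.

    Format: ``segments: [{time: 0, d: 0}, {time: 20, d: 5.4}, ...]``.
    """
    data = _load_mapping(path)
    if "segments" not in data:
        raise KeyError(f"{path}: missing 'segments'")
    segs = tuple(
        (float(seg["time"]), float(seg["d"])) for seg in data["segments"]
    )
    return SignalProtocol(segs)


def load_ranges(path: str | Path, frame: Frame) -> list[SamplingRange]:
    """Load uniform sampling ranges: ``{name: [min, max], ...}``.

    A ``d`` or ``D`` entry (the Dvl row of the published range tables) is
    accepted but returned separately-named like any other range; callers fix
    Dvl per analysis and pass only the kinetic parameters to the sampler.
    """
    data = _load_mapping(path)
    out = []
    for name, pair in data.items():
        if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
            raise ValueError(f"{path}: range for {name!r} must be [min, max]")
        out.append(SamplingRange(name, float(pair[0]), float(pair[1]), frame))
    return out


def sampled_ranges(ranges: Iterable[SamplingRange]) -> list[SamplingRange]:
    """Drop the Dvl row: its level is fixed per analysis, not sampled."""
    return [r for r in ranges if r.name not in ("d", "D")]


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def _header_lines(meta: dict) -> str:
    from . import __version__

    lines = [f"# wntemt {__version__}"]
    for key, value in meta.items():
        lines.append(f"# {key} = {value}")
    return "\n".join(lines) + "\n"


def write_csv(df: pd.DataFrame, path: str | Path, **meta) -> None:
    """Write a tidy CSV with a commented metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv` (header comments skipped)."""
    return pd.read_csv(path, comment="#")


def trajectory_frame(traj) -> pd.DataFrame:
    """Tidy frame of a trajectory: time, d and the three species."""
    cols = ("E", "B", "S") if traj.frame == "dimensional" else ("e", "b", "s")
    df = pd.DataFrame(traj.states, columns=list(cols))
    df.insert(0, "d" if traj.frame == "nondimensional" else "D", traj.dvl)
    df.insert(0, "time", traj.t)
    return df


def equilibria_frame(eqs, dvl: float) -> pd.DataFrame:
    """Tidy frame of an equilibrium list at one Dvl level."""
    rows = []
    for eq in eqs:
        e, b, s = eq.state.as_array()
        rows.append(
            {
                "d": dvl, "e": e, "b": b, "s": s,
                "stability": "stable" if eq.stable else "unstable",
                "eigenvalue_max_real": eq.max_real_eig,
                "phenotype": eq.phenotype,
                "nonphysical": eq.nonphysical,
            }
        )
    return pd.DataFrame(rows)


def branches_frame(branches) -> pd.DataFrame:
    rows = []
    for br in branches:
        for d, eq in zip(br.values, br.equilibria):
            e, b, s = eq.state.as_array()
            rows.append(
                {
                    "d": d, "e": e, "b": b, "s": s,
                    "stability": "stable" if eq.stable else "unstable",
                    "branch": br.identity,
                }
            )
    return pd.DataFrame(rows)


def regionmap_frame(rmap) -> pd.DataFrame:
    rows = []
    for iy, y in enumerate(rmap.y_grid):
        for id_, d in enumerate(rmap.d_grid):
            rows.append({"d": d, "y": y, "region": int(rmap.region[iy, id_])})
    return pd.DataFrame(rows)
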
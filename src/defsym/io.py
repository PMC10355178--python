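"""Configuration, run manifests and tabular serialization.

Parameter sets travel as flat key-value YAML (JSON is valid YAML and is
accepted), with keys named after the model symbols; missing keys take
the default values.  Every written output is accompanied by a JSON run
manifest sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evolution_sim import (
    EvolutionaryTrajectory,
    SimulationSettings,
    StepRecord,
)
from .invasion_analysis import PIPGrid
from .model_core import PolymorphicState
from .params import ModelParameters

__all__ = [
    "RunManifest",
    "load_config",
    "write_manifest",
    "trajectory_to_frame",
    "frame_to_trajectory_states",
    "write_trajectory",
    "read_trajectory_frame",
    "state_to_frame",
    "write_pip",
    "read_pip",
]

_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParameters)}
_SETTINGS_KEYS = {f.name for f in dataclasses.fields(SimulationSettings)}


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce an output file."""

    params: dict
    settings: dict
    command: str
    seed: int
    version: str = __version__
    timestamp: str = ""

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if not d["timestamp"]:
            d["timestamp"] = datetime.datetime.now(
                datetime.timezone.utc).isoformat()
        return json.dumps(d, indent=2, sort_keys=True)


def load_config(path: Optional[Union[str, Path]] = None,
                overrides: Optional[Mapping[str, object]] = None,
                ) -> Tuple[ModelParameters, SimulationSettings]:
    """Build parameters and settings from defaults, file, then flags.

    Precedence: built-in defaults < config file < overrides.  Unknown
    keys and invariant violations raise with the offending key named.
    """
    merged: Dict[str, object] = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must be a flat mapping")
        merged.update(data)
    if overrides:
        merged.update({k: v for k, v in overrides.items() if v is not None})

    unknown = sorted(set(merged) - _PARAM_KEYS - _SETTINGS_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    params = ModelParameters.from_mapping(
        {k: float(v) for k, v in merged.items() if k in _PARAM_KEYS})
    raw_settings = {k: v for k, v in merged.items() if k in _SETTINGS_KEYS}
    settings = SimulationSettings.from_mapping(raw_settings)
    return params, settings


def write_manifest(path: Union[str, Path], manifest: RunManifest) -> Path:
    path = Path(path)
    path.write_text(manifest.to_json())
    return path


# --------------------------------------------------------------------------
# trajectories


def trajectory_to_frame(traj: EvolutionaryTrajectory) -> pd.DataFrame:
    """Long-format view: one row per (step, microbe, strain)."""
    rows = []
    for rec in traj.steps:
        rows.append({"step": rec.step, "microbe": "host", "trait": np.nan,
                     "partner_trait": np.nan, "density": rec.H})
        for j, y in enumerate(rec.y_strains):
            rows.append({"step": rec.step, "microbe": "symbiont", "trait": y,
                         "partner_trait": np.nan, "density": rec.D[j]})
        for i, beta in enumerate(rec.beta_strains):
            rows.append({"step": rec.step, "microbe": "parasite",
                         "trait": beta, "partner_trait": np.nan,
                         "density": rec.P[i]})
            for j, y in enumerate(rec.y_strains):
                rows.append({"step": rec.step, "microbe": "coinfected",
                             "trait": beta, "partner_trait": y,
                             "density": rec.B[i, j]})
    return pd.DataFrame(rows)


def frame_to_trajectory_states(frame: pd.DataFrame) -> Dict[int, PolymorphicState]:
    """Rebuild per-step states from a long-format trajectory frame."""
    out: Dict[int, PolymorphicState] = {}
    for step, g in frame.groupby("step"):
        ys = np.sort(g.loc[g.microbe == "symbiont", "trait"].to_numpy())
        bs = np.sort(g.loc[g.microbe == "parasite", "trait"].to_numpy())
        H = float(g.loc[g.microbe == "host", "density"].iloc[0])
        D = np.array([float(g.loc[(g.microbe == "symbiont")
                                  & (g.trait == y), "density"].iloc[0])
                      for y in ys])
        P = np.array([float(g.loc[(g.microbe == "parasite")
                                  & (g.trait == b), "density"].iloc[0])
                      for b in bs])
        B = np.zeros((len(bs), len(ys)))
        co = g[g.microbe == "coinfected"]
        for i, b in enumerate(bs):
            for j, y in enumerate(ys):
                sel = co[(co.trait == b) & (co.partner_trait == y)]
                if len(sel):
                    B[i, j] = float(sel["density"].iloc[0])
        out[int(step)] = PolymorphicState(ys, bs, H, D, P, B)
    return out


def write_trajectory(traj: EvolutionaryTrajectory, directory: Union[str, Path],
                     command: str = "evolve") -> Tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / "trajectory.csv"
    trajectory_to_frame(traj).to_csv(csv_path, index=False,
                                     float_format="%.17g")
    manifest = RunManifest(params=traj.params.to_dict(),
                           settings=traj.settings.to_dict(),
                           command=command, seed=traj.settings.seed)
    man_path = write_manifest(directory / "trajectory.manifest.json", manifest)
    return csv_path, man_path


def read_trajectory_frame(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


def state_to_frame(state: PolymorphicState) -> pd.DataFrame:
    """Wide single-row view with trait-labelled columns."""
    row = {"H": state.H}
    for j, y in enumerate(state.y_strains):
        row[f"D[{y!r}]"] = state.D[j]
    for i, b in enumerate(state.beta_strains):
        row[f"P[{b!r}]"] = state.P[i]
        for j, y in enumerate(state.y_strains):
            row[f"B[{b!r};{y!r}]"] = state.B[i, j]
    return pd.DataFrame([row])


# --------------------------------------------------------------------------
# PIPs


def write_pip(pip: PIPGrid, path: Union[str, Path]) -> Path:
    """Long CSV (resident, mutant, sign); undefined columns omitted."""
    rows = []
    for j, r in enumerate(pip.resident_axis):
        if j in pip.undefined_columns:
            continue
        for i, m in enumerate(pip.mutant_axis):
            rows.append({"resident": r, "mutant": m,
                         "sign": int(pip.sign_matrix[i, j])})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


def read_pip(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)
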
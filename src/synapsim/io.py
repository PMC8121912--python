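"""File schemas: trajectory and localization CSV, state snapshots.

Trajectory CSV columns: track_id, frame, t_s, x_um, y_um, synaptic(0/1),
with localization-precision metadata in a sidecar JSON.
Localization CSV columns: x_nm, y_nm, frame, channel, intensity.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .clustering import LocalizationField
from .geometry import SynapseGeometry
from .organization import SimState
from .spt import TrajectorySet

TRAJECTORY_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um", "synaptic"]
LOCALIZATION_COLUMNS = ["x_nm", "y_nm", "frame", "channel", "intensity"]


def write_trajectories(tracks: TrajectorySet, path: str | Path,
                       precision_nm: Optional[float] = None) -> None:
    tracks.to_frame().to_csv(path, index=False)
    if precision_nm is not None:
        sidecar = Path(path).with_suffix(".meta.json")
        sidecar.write_text(json.dumps({"localization_precision_nm": precision_nm}))


def read_trajectories(path: str | Path) -> TrajectorySet:
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    return TrajectorySet.from_frame(df)


def write_localizations(field: LocalizationField, path: str | Path) -> None:
    field.to_frame().to_csv(path, index=False)


def read_localizations(path: str | Path,
                       channel: Optional[str] = None) -> LocalizationField:
    df = pd.read_csv(path)
    if channel is not None and "channel" in df.columns:
        df = df[df.channel == channel]
    return LocalizationField(
        points=df[["x_nm", "y_nm"]].to_numpy(),
        frames=df["frame"].to_numpy() if "frame" in df.columns else None,
        channel=channel or "ch0",
        intensity=df["intensity"].to_numpy() if "intensity" in df.columns else None)


def write_state(state: SimState, path: str | Path) -> None:
    """Final-state snapshot as JSON (positions nm, states by name)."""
    data = {
        "clock_s": state.clock,
        "seed": state.seed,
        "rng_counter": state.rng_counter,
        "geometry": {
            "synapse_radius": state.geometry.synapse_radius,
            "psd_radius": state.geometry.psd_radius,
            "nanodomain_center": list(state.geometry.nanodomain_center),
            "nanodomain_radius": state.geometry.nanodomain_radius,
            "cleft_height": state.geometry.cleft_height,
        },
        "psd95": {
            "position": np.nan_to_num(state.psd_pos).tolist(),
            "state": state.psd_state.tolist(),
            "partner": state.psd_partner.tolist(),
        },
        "ampar": {
            "position": np.where(np.isfinite(state.ampar_pos),
                                 state.ampar_pos, None).tolist(),
            "state": state.ampar_state.tolist(),
            "partner": state.ampar_partner.tolist(),
        },
    }
    Path(path).write_text(json.dumps(data))


def read_state(path: str | Path) -> SimState:
    data = json.loads(Path(path).read_text())
    g = data["geometry"]
    geometry = SynapseGeometry(
        synapse_radius=g["synapse_radius"], psd_radius=g["psd_radius"],
        nanodomain_center=tuple(g["nanodomain_center"]),
        nanodomain_radius=g["nanodomain_radius"],
        cleft_height=g["cleft_height"])
    amp_pos = np.array([[np.nan if v is None else v for v in row]
                        for row in data["ampar"]["position"]], dtype=float)
    return SimState(
        geometry=geometry,
        psd_pos=np.asarray(data["psd95"]["position"], dtype=float),
        psd_state=np.asarray(data["psd95"]["state"], dtype=np.int8),
        psd_partner=np.asarray(data["psd95"]["partner"], dtype=np.int64),
        ampar_pos=amp_pos,
        ampar_state=np.asarray(data["ampar"]["state"], dtype=np.int8),
        ampar_partner=np.asarray(data["ampar"]["partner"], dtype=np.int64),
        clock=data["clock_s"], seed=data["seed"],
        rng_counter=data["rng_counter"])
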
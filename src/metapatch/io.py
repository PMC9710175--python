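"""Delimited-table I/O for occupancy tables, trajectories and phase maps.

All tabular outputs are UTF-8 CSV with a header row and '.' decimals;
missing values (undefined Theta, NaN correlations) are written as empty
fields and come back as NaN, never as 0.  Round trips preserve values to
full float precision (repr-level formatting).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import Trajectory
from .pipeline import OccupancyTable

__all__ = [
    "write_occupancy_table", "read_occupancy_table",
    "write_trajectory", "read_trajectory",
    "write_kymograph", "read_kymograph",
]

_FLOAT_FMT = "%.17g"


def write_occupancy_table(table: OccupancyTable, path: str | Path) -> None:
    """Tidy CSV: one row per (landscape, patch, time) with derived columns."""
    df = table.to_frame()
    if table.corridor_E is not None:
        K, T = table.corridor_E.shape
        corr = pd.DataFrame({
            "landscape": np.repeat(table.landscape, K * T),
            "patch": -np.repeat(np.arange(1, K + 1), T),  # negative = corridor k
            "time_min": np.tile(table.times_min, K),
            "E": table.corridor_E.ravel(), "P": table.corridor_P.ravel(),
            "theta": np.nan, "Z_sum": np.nan, "Z_half": np.nan,
        })
        df = pd.concat([df, corr], ignore_index=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_occupancy_table(path: str | Path) -> OccupancyTable:
    df = pd.read_csv(path, float_precision="round_trip")
    patches = df[df["patch"] > 0]
    corridors = df[df["patch"] < 0].copy()
    table = OccupancyTable.from_frame(patches)
    if len(corridors):
        corridors["patch"] = -corridors["patch"]
        corridors = corridors.sort_values(["patch", "time_min"])
        K = corridors["patch"].nunique()
        T = table.n_frames
        table.corridor_E = corridors["E"].to_numpy().reshape(K, T)
        table.corridor_P = corridors["P"].to_numpy().reshape(K, T)
    return table


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    return Trajectory(times=df["step"].to_numpy(),
                      rho_E=df["rho_E"].to_numpy(),
                      rho_P=df["rho_P"].to_numpy())


def write_kymograph(matrix: np.ndarray, path: str | Path) -> None:
    """Patch x time matrix; row k = patch k (1-based in the index column)."""
    df = pd.DataFrame(matrix,
                      index=pd.RangeIndex(1, matrix.shape[0] + 1, name="patch"))
    df.to_csv(path, float_format=_FLOAT_FMT)


def read_kymograph(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, index_col="patch",
                       float_precision="round_trip").to_numpy()
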
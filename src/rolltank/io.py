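"""Trajectory-table I/O.

Schema (one header line, delimited text): particle_id, t_s, x_m, y_m, z_m,
vx_mps, vy_mps, vz_mps, status.  Status is recorded on the final row of a
particle's block and ``interior`` elsewhere.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Trajectory

__all__ = ["trajectories_to_frame", "write_trajectories", "read_trajectories"]

COLUMNS = ["particle_id", "t_s", "x_m", "y_m", "z_m", "vx_mps", "vy_mps", "vz_mps", "status"]


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    frames = []
    for pid, tr in enumerate(trajectories):
        n = len(tr.times)
        status = ["interior"] * n
        if n:
            status[-1] = tr.status
        frames.append(
            pd.DataFrame(
                {
                    "particle_id": pid,
                    "t_s": tr.times,
                    "x_m": tr.positions[:, 0],
                    "y_m": tr.positions[:, 1],
                    "z_m": tr.positions[:, 2],
                    "vx_mps": tr.velocities[:, 0],
                    "vy_mps": tr.velocities[:, 1],
                    "vz_mps": tr.velocities[:, 2],
                    "status": status,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_trajectories(trajectories: list[Trajectory], path) -> None:
    trajectories_to_frame(trajectories).to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    df = pd.read_csv(Path(path))
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns {sorted(missing)}")
    out = []
    for _, g in df.groupby("particle_id", sort=True):
        g = g.sort_values("t_s")
        out.append(
            Trajectory(
                times=g["t_s"].to_numpy(),
                positions=g[["x_m", "y_m", "z_m"]].to_numpy(),
                velocities=g[["vx_mps", "vy_mps", "vz_mps"]].to_numpy(),
                status=str(g["status"].iloc[-1]),
                termination_reason=str(g["status"].iloc[-1]),
                metadata={"source": str(path)},
            )
        )
    return out
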
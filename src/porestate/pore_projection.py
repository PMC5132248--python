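"""Pore-axis definition and cylindrical projection of ion positions.

The pore axis of a frame is the line from the centroid of one user-chosen
atom set (``basis_from``) to the centroid of another (``basis_to``).  Each
ion position is reduced to an axial coordinate ``z`` (signed distance along
the axis from the from-centroid) and a radial distance ``r`` from the axis.
The axis is recomputed every frame, so the description is robust to overall
drift of the protein; centroids are unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .trajectory_io import Frame, Selections

__all__ = [
    "PoreAxis",
    "DegenerateAxisError",
    "compute_axis",
    "project",
    "project_trajectory",
    "write_axial_trace",
    "read_axial_trace",
]

_MIN_SEPARATION = 1e-6  # Å; below this the axis direction is undefined


class DegenerateAxisError(ValueError):
    """The two basis centroids (nearly) coincide; no axis direction exists."""


@dataclass(frozen=True)
class PoreAxis:
    origin: np.ndarray  # (3,) Å, centroid of basis_from
    direction: np.ndarray  # (3,) unit vector toward basis_to centroid


def compute_axis(frame: Frame, sel: Selections) -> PoreAxis:
    """Pore axis of one frame from the two basis atom sets."""
    c_from = frame.positions[sel.basis_from].mean(axis=0)
    c_to = frame.positions[sel.basis_to].mean(axis=0)
    d = c_to - c_from
    norm = float(np.linalg.norm(d))
    if norm < _MIN_SEPARATION:
        raise DegenerateAxisError(
            f"frame {frame.index}: basis centroids separated by {norm:.2e} Å"
        )
    return PoreAxis(origin=c_from, direction=d / norm)


def project(position: np.ndarray, axis: PoreAxis) -> tuple[np.ndarray, np.ndarray]:
    """Axial coordinate z and radial distance r of one or many positions.

    ``position`` may be shape (3,) or (n, 3); returns scalars or arrays.
    """
    pos = np.asarray(position, dtype=float)
    rel = pos - axis.origin
    z = rel @ axis.direction
    perp = rel - np.multiply.outer(z, axis.direction)
    r = np.linalg.norm(perp, axis=-1)
    if pos.ndim == 1:
        return float(z), float(r)
    return z, r


def project_trajectory(frames: Iterable[Frame], sel: Selections) -> pd.DataFrame:
    """Project every ion of every frame; one row per (frame, ion).

    Returns a DataFrame with columns ``frame``, ``time_ps``, ``ion_id``
    (atom index), ``z_A``, ``r_A``, ordered by (frame, ion).
    """
    ions = np.asarray(sel.ions, dtype=int)
    frames_col: list[np.ndarray] = []
    times: list[np.ndarray] = []
    zs: list[np.ndarray] = []
    rs: list[np.ndarray] = []
    n = len(ions)
    for fr in frames:
        axis = compute_axis(fr, sel)
        z, r = project(fr.positions[ions], axis)
        frames_col.append(np.full(n, fr.index, dtype=int))
        times.append(np.full(n, fr.time))
        zs.append(z)
        rs.append(r)
    if not frames_col:
        raise ValueError("no frames to project")
    return pd.DataFrame(
        {
            "frame": np.concatenate(frames_col),
            "time_ps": np.concatenate(times),
            "ion_id": np.tile(ions, len(frames_col)),
            "z_A": np.concatenate(zs),
            "r_A": np.concatenate(rs),
        }
    )


def write_axial_trace(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_axial_trace(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
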
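"""Core in-memory containers shared across the analysis stages.

Units are physical throughout: lengths in micrometres (um), times in
seconds (s), angles in radians.  Filament-axis angles follow the nematic
convention (theta and theta + pi identified) and are stored in
[-pi/2, pi/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySet",
    "ImageStack",
    "DisplacementField",
    "wrap_nematic",
]

#: Columns of the shared trajectory-table format (z is optional).
TRAJ_COLUMNS = ["id", "frame", "t", "x", "y", "theta", "length"]


def wrap_nematic(theta: np.ndarray) -> np.ndarray:
    """Map axis angles into the nematic fundamental domain [-pi/2, pi/2)."""
    return (np.asarray(theta) + np.pi / 2) % np.pi - np.pi / 2


@dataclass
class TrajectorySet:
    """Time-ordered samples (t, x, y, theta, length) of tracked filaments.

    Parameters
    ----------
    data
        Table with columns ``id, frame, t, x, y, theta, length`` and
        optionally ``z``.  Positions in um, angles in rad (nematic),
        lengths in um.
    frame_interval
        Acquisition interval in seconds.
    pixel_size
        Calibration in um per pixel (informational; positions are
        already in um).
    """

    data: pd.DataFrame
    frame_interval: float = 1.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        missing = [c for c in TRAJ_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns {missing}")
        self.data = self.data.sort_values(["id", "frame"]).reset_index(drop=True)
        for pid, grp in self.data.groupby("id"):
            frames = grp["frame"].to_numpy()
            if np.any(np.diff(frames) <= 0):
                raise ValueError(f"frames not strictly increasing for id {pid}")

    # -- construction -------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        positions: np.ndarray,
        dt: float,
        theta: Optional[np.ndarray] = None,
        lengths: Optional[np.ndarray] = None,
        pixel_size: float = 1.0,
        z: Optional[np.ndarray] = None,
    ) -> "TrajectorySet":
        """Build a dense set from an (n_traj, n_frames, 2) position array."""
        positions = np.asarray(positions, dtype=float)
        n_traj, n_frames, _ = positions.shape
        ids = np.repeat(np.arange(n_traj), n_frames)
        frames = np.tile(np.arange(n_frames), n_traj)
        if theta is None:
            th = np.zeros(n_traj * n_frames)
        else:
            theta = np.asarray(theta, dtype=float)
            th = (
                np.repeat(theta, n_frames)
                if theta.ndim == 1
                else theta.reshape(-1)
            )
        if lengths is None:
            ln = np.ones(n_traj * n_frames)
        else:
            lengths = np.asarray(lengths, dtype=float)
            ln = (
                np.repeat(lengths, n_frames)
                if lengths.ndim == 1
                else lengths.reshape(-1)
            )
        df = pd.DataFrame(
            {
                "id": ids,
                "frame": frames,
                "t": frames * dt,
                "x": positions[..., 0].reshape(-1),
                "y": positions[..., 1].reshape(-1),
                "theta": wrap_nematic(th),
                "length": ln,
            }
        )
        if z is not None:
            df["z"] = np.asarray(z, dtype=float).reshape(-1)
        return cls(df, frame_interval=dt, pixel_size=pixel_size)

    # -- access -------------------------------------------------------
    @property
    def ids(self) -> np.ndarray:
        return self.data["id"].unique()

    def __len__(self) -> int:
        return len(self.ids)

    def trajectory(self, pid) -> pd.DataFrame:
        return self.data[self.data["id"] == pid]

    def positions_dense(self) -> Optional[np.ndarray]:
        """Return (n_traj, n_frames, 2) if the set is gap-free and
        frame-aligned, else None."""
        counts = self.data.groupby("id")["frame"].agg(["min", "max", "count"])
        if counts["min"].nunique() != 1 or counts["max"].nunique() != 1:
            return None
        n_frames = int(counts["max"].iloc[0] - counts["min"].iloc[0] + 1)
        if not (counts["count"] == n_frames).all():
            return None
        n_traj = len(counts)
        xy = self.data[["x", "y"]].to_numpy().reshape(n_traj, n_frames, 2)
        return xy

    def concat(self, other: "TrajectorySet") -> "TrajectorySet":
        off = self.data["id"].max() + 1
        odf = other.data.copy()
        odf["id"] = odf["id"] + off
        return TrajectorySet(
            pd.concat([self.data, odf], ignore_index=True),
            frame_interval=self.frame_interval,
            pixel_size=self.pixel_size,
        )


@dataclass
class ImageStack:
    """Calibrated T x H x W intensity movie (single channel)."""

    frames: np.ndarray
    pixel_size: float  # um / px
    frame_interval: float = 1.0  # s
    channel: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError("frames must be T x H x W")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape[1:]

    def frame(self, i: int) -> np.ndarray:
        return self.frames[i]


@dataclass
class DisplacementField:
    """Gridded (u_x, u_y) displacement vectors on PIV window centres.

    ``x``/``y`` are 1-D centre coordinates (px), ``u``/``v`` the
    displacement components (px) with NaN marking masked windows.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    window: int = 32
    overlap: float = 0.5

    def divergence(self, spacing: Optional[float] = None) -> np.ndarray:
        """Central-difference divergence on the window grid.

        A spatially constant field yields exactly zero.
        """
        if spacing is None:
            spacing = float(self.x[1] - self.x[0]) if len(self.x) > 1 else 1.0
        dudx = np.gradient(self.u, spacing, axis=1)
        dvdy = np.gradient(self.v, spacing, axis=0)
        return dudx + dvdy
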
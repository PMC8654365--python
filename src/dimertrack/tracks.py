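"""Trajectory containers shared across the analysis stages.

Coordinates are nanometres, 2-D, origin at the lower-left corner of the
field of view; frames are 0-based integers; time step is 1/frame_rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional

import numpy as np
import pandas as pd

TRAJECTORY_COLUMNS = ["frame", "particle_id", "channel", "x_nm", "y_nm"]
GROUND_TRUTH_COLUMNS = ["pair_id", "frame", "state"]


class Track(NamedTuple):
    """One particle's time-ordered localizations (frames may have gaps)."""

    particle_id: int
    channel: int
    frames: np.ndarray  # (n,) int, strictly increasing
    xy: np.ndarray      # (n, 2) float, nm


@dataclass
class TrajectoryTable:
    """Localization table for a two-channel tracking experiment.

    ``df`` has columns frame, particle_id, channel, x_nm, y_nm.
    ``ground_truth`` (when the table comes from the simulator) has columns
    pair_id, frame, state with state in {"free", "dimer"}.
    """

    df: pd.DataFrame
    frame_rate: float = 20.0
    roi_size: Optional[float] = None
    ground_truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns: {missing}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def tracks(self, channel: Optional[int] = None) -> list[Track]:
        """Extract per-particle tracks, optionally restricted to one channel."""
        out: list[Track] = []
        df = self.df if channel is None else self.df[self.df["channel"] == channel]
        for pid, g in df.groupby("particle_id", sort=True):
            g = g.sort_values("frame")
            frames = g["frame"].to_numpy(dtype=np.int64)
            if len(frames) > 1 and np.any(np.diff(frames) <= 0):
                raise ValueError(f"particle {pid}: frames not strictly increasing")
            ch = int(g["channel"].iloc[0])
            if (g["channel"] != ch).any():
                raise ValueError(f"particle {pid} appears in more than one channel")
            out.append(Track(int(pid), ch, frames, g[["x_nm", "y_nm"]].to_numpy(dtype=float)))
        return out

    def __len__(self) -> int:
        return len(self.df)
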
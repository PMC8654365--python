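"""CSV/JSON round-tripping for every table the pipeline reads or writes.

Schemas (headers are exact):

* trajectories       — ``frame,particle_id,channel,x_nm,y_nm`` with an
  optional YAML sidecar ``<name>.meta.yaml`` carrying frame_rate/roi_size
* ground truth       — ``pair_id,frame,state`` with state in {free, dimer}
* point patterns     — ``species,x_nm,y_nm`` with species in {1, 2}
* pair series        — ``pair_id,frame,s_nm``
* events             — ``pair_id,start_frame,end_frame,state,n_frames,duration_s``

Malformed rows are rejected with their 1-based file line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .hmm import DimerEvents, KoffEstimate
from .msd import MSDCurve
from .pairs import CorrelatedMotionResult, PairSeries
from .ripley import RipleyResult
from .synthetic import PointPattern
from .tracks import TRAJECTORY_COLUMNS, TrajectoryTable

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A file does not conform to its documented schema."""


def _read_csv_checked(path: PathLike, columns: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise FormatError(f"{path}: expected header {','.join(columns)!r}, "
                          f"got {','.join(df.columns)!r}")
    for col in numeric:
        probe = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(probe.isna().to_numpy())
        if len(bad):
            raise FormatError(f"{path}: non-numeric value in column {col!r} "
                              f"at line {bad[0] + 2}")
        # astype parses exactly (correctly rounded); to_numeric's fast path
        # can be one ulp off, which would break write -> read identity
        df[col] = df[col].astype(np.float64)
    return df


def _meta_path(path: PathLike) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".meta.yaml") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.yaml")


# -- trajectories -----------------------------------------------------------

def write_trajectories(table: TrajectoryTable, path: PathLike) -> None:
    path = Path(path)
    table.df.to_csv(path, index=False)
    meta = {"frame_rate": float(table.frame_rate)}
    if table.roi_size is not None:
        meta["roi_size"] = float(table.roi_size)
    _meta_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    if table.ground_truth is not None:
        gt_path = path.with_name(path.stem + "_ground_truth.csv")
        table.ground_truth.to_csv(gt_path, index=False)


def read_trajectories(path: PathLike, frame_rate: Optional[float] = None) -> TrajectoryTable:
    df = _read_csv_checked(path, TRAJECTORY_COLUMNS,
                           numeric=["frame", "particle_id", "channel", "x_nm", "y_nm"])
    for col in ("frame", "particle_id", "channel"):
        df[col] = df[col].astype(np.int64)
    bad_ch = np.flatnonzero(~df["channel"].isin([1, 2]).to_numpy())
    if len(bad_ch):
        raise FormatError(f"{path}: channel must be 1 or 2 at line {bad_ch[0] + 2}")
    dup = np.flatnonzero(df.duplicated(subset=["particle_id", "frame"]).to_numpy())
    if len(dup):
        raise FormatError(f"{path}: duplicate (particle_id, frame) at line {dup[0] + 2}")

    meta_file = _meta_path(path)
    roi_size = None
    if meta_file.exists():
        meta = yaml.safe_load(meta_file.read_text()) or {}
        frame_rate = frame_rate if frame_rate is not None else meta.get("frame_rate")
        roi_size = meta.get("roi_size")
    if frame_rate is None:
        frame_rate = 20.0
    return TrajectoryTable(df=df, frame_rate=float(frame_rate), roi_size=roi_size)


# -- point patterns ---------------------------------------------------------

def write_point_pattern(pattern: PointPattern, path: PathLike) -> None:
    rows = pd.DataFrame({
        "species": np.concatenate([np.ones(pattern.n1, dtype=int),
                                   np.full(pattern.n2, 2, dtype=int)]),
        "x_nm": np.concatenate([pattern.coords1[:, 0], pattern.coords2[:, 0]]),
        "y_nm": np.concatenate([pattern.coords1[:, 1], pattern.coords2[:, 1]]),
    })
    rows.to_csv(path, index=False)
    _meta_path(path).write_text(yaml.safe_dump(
        {"window_w": float(pattern.window[0]), "window_h": float(pattern.window[1])}))


def read_point_pattern(path: PathLike,
                       window: Optional[tuple[float, float]] = None) -> PointPattern:
    df = _read_csv_checked(path, ["species", "x_nm", "y_nm"],
                           numeric=["species", "x_nm", "y_nm"])
    bad = np.flatnonzero(~df["species"].isin([1, 2]).to_numpy())
    if len(bad):
        raise FormatError(f"{path}: species must be 1 or 2 at line {bad[0] + 2}")
    meta_file = _meta_path(path)
    if window is None:
        if meta_file.exists():
            meta = yaml.safe_load(meta_file.read_text()) or {}
            window = (float(meta["window_w"]), float(meta["window_h"]))
        else:
            w = float(max(df["x_nm"].max(), 1.0))
            h = float(max(df["y_nm"].max(), 1.0))
            window = (w, h)
    c1 = df.loc[df["species"] == 1, ["x_nm", "y_nm"]].to_numpy(dtype=float)
    c2 = df.loc[df["species"] == 2, ["x_nm", "y_nm"]].to_numpy(dtype=float)
    return PointPattern(coords1=c1, coords2=c2, window=window)


# -- pair series ------------------------------------------------------------

def write_pair_series(pairs: Sequence[PairSeries], path: PathLike) -> None:
    frames = np.concatenate([p.frames for p in pairs]) if pairs else np.empty(0, dtype=int)
    rows = pd.DataFrame({
        "pair_id": np.concatenate([np.full(len(p), p.pair_id, dtype=int) for p in pairs])
        if pairs else np.empty(0, dtype=int),
        "frame": frames,
        "s_nm": np.concatenate([p.s for p in pairs]) if pairs else np.empty(0),
    })
    rows.to_csv(path, index=False)


def read_pair_series(path: PathLike) -> list[PairSeries]:
    """Read separation-only pair series (positions are not reconstructable).

    The separation is stored as the x-coordinate difference of two dummy
    positions, preserving ``s`` exactly for the HMM stage.
    """
    df = _read_csv_checked(path, ["pair_id", "frame", "s_nm"],
                           numeric=["pair_id", "frame", "s_nm"])
    out: list[PairSeries] = []
    for pid, g in df.groupby("pair_id", sort=True):
        g = g.sort_values("frame")
        s = g["s_nm"].to_numpy(dtype=float)
        n = len(s)
        xy1 = np.zeros((n, 2))
        xy2 = np.column_stack([-s, np.zeros(n)])
        out.append(PairSeries(pair_id=int(pid), frames=g["frame"].to_numpy(np.int64),
                              xy1=xy1, xy2=xy2))
    return out


# -- derived tables ---------------------------------------------------------

def write_msd_curve(curve: MSDCurve, path: PathLike) -> None:
    pd.DataFrame({"lag_s": curve.lags, "msd_um2": curve.msd,
                  "n_jumps": curve.n_jumps}).to_csv(path, index=False)


def write_correlated_motion(result: CorrelatedMotionResult, path: PathLike) -> None:
    pd.DataFrame({
        "sep_bin_nm": result.separation_bin_centers,
        "mean_jump_nm": result.mean_jump_magnitude,
        "mean_uncorrelated_jump_nm": result.mean_uncorrelated_jump,
        "n_jumps": result.n_jumps,
    }).to_csv(path, index=False)


def write_events(all_events: Sequence[DimerEvents], path: PathLike) -> None:
    rows = []
    for ev in all_events:
        for e in ev.events:
            rows.append((ev.pair_id, e.start_frame, e.end_frame, e.state,
                         e.n_frames, e.duration_s))
    pd.DataFrame(rows, columns=["pair_id", "start_frame", "end_frame", "state",
                                "n_frames", "duration_s"]).to_csv(path, index=False)


def write_koff(est: KoffEstimate, path: PathLike) -> None:
    Path(path).write_text(json.dumps({
        "k_off_per_s": est.k_off,
        "se_per_s": est.se,
        "mean_lifetime_s": None if np.isinf(est.mean_lifetime) else est.mean_lifetime,
        "lifetime_infinite": bool(np.isinf(est.mean_lifetime)),
        "n_pairs": est.n_pairs,
        "n_dimer_frames": est.n_dimer_frames,
        "log_likelihood": est.log_likelihood,
    }, indent=2, sort_keys=True) + "\n")


def write_ripley(result: RipleyResult, path: PathLike) -> None:
    pd.DataFrame({
        "r_nm": result.r,
        "L_minus_r_nm": result.L_minus_r,
        "K_nm2": result.K,
        "env_lo_nm": result.env_lo if result.env_lo is not None else np.nan,
        "env_hi_nm": result.env_hi if result.env_hi is not None else np.nan,
    }).to_csv(path, index=False)
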
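"""Synthetic ground-truth data for the tracking and co-clustering analyses.

Two generators:

* :func:`simulate_pair_tracks` — two-color single-particle trajectories of
  receptor pairs that stochastically dimerize and dissociate while diffusing
  in a square membrane region.  Camera-rate discretization, per-axis Gaussian
  localization error and i.i.d. missed detections emulate quantum-dot
  tracking movies.
* :func:`simulate_point_pattern` — two-species point patterns on a membrane
  sheet: complete spatial randomness, independent Thomas clusters, or
  co-clustered Thomas processes sharing one parent set.

All coordinates are nm; diffusion coefficients are um^2/s; rates are 1/s.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .tracks import TrajectoryTable

logger = logging.getLogger(__name__)

NM_PER_UM = 1000.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the pair-trajectory simulation.

    Diffusion coefficients are um^2/s, lengths nm, rates 1/s.  ``k_on`` is
    the association rate applying only while the pair separation is below
    ``capture_radius``; ``k_off`` is the dissociation rate of a dimer.
    ``initial_state`` sets the state of every pair at frame 0.
    """

    n_pairs: int = 50
    n_frames: int = 1000
    frame_rate: float = 20.0
    D_free_ch1: float = 0.1
    D_free_ch2: float = 0.1
    D_dimer: float = 0.05
    k_on: float = 1.0
    k_off: float = 0.18
    capture_radius: float = 150.0
    dimer_separation: float = 15.0
    sigma_loc_ch1: float = 15.0
    sigma_loc_ch2: float = 15.0
    p_miss: float = 0.0
    roi_size: float = 25000.0
    initial_state: str = "free"
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = dict(
            frame_rate=self.frame_rate, D_free_ch1=self.D_free_ch1,
            D_free_ch2=self.D_free_ch2, D_dimer=self.D_dimer, k_on=self.k_on,
            k_off=self.k_off, capture_radius=self.capture_radius,
            dimer_separation=self.dimer_separation,
            sigma_loc_ch1=self.sigma_loc_ch1, sigma_loc_ch2=self.sigma_loc_ch2,
            p_miss=self.p_miss, roi_size=self.roi_size,
        )
        for name, v in numeric.items():
            if not math.isfinite(v):
                raise ValueError(f"SimConfig.{name} must be finite, got {v!r}")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        for name in ("D_free_ch1", "D_free_ch2", "D_dimer", "k_on", "k_off",
                     "sigma_loc_ch1", "sigma_loc_ch2", "dimer_separation"):
            if numeric.get(name, getattr(self, name)) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.p_miss < 1.0):
            raise ValueError("p_miss must be in [0, 1)")
        if self.capture_radius <= 0 or self.roi_size <= 0:
            raise ValueError("capture_radius and roi_size must be > 0")
        if self.initial_state not in ("free", "dimer"):
            raise ValueError("initial_state must be 'free' or 'dimer'")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


def _reflect(x: np.ndarray, hi: float) -> np.ndarray:
    """Fold coordinates back into [0, hi] (reflecting boundary)."""
    y = np.mod(x, 2.0 * hi)
    return np.where(y > hi, 2.0 * hi - y, y)


def simulate_pair_tracks(config: SimConfig) -> TrajectoryTable:
    """Simulate two-color trajectories of dimerizing particle pairs.

    Free pairs: both labels take independent Gaussian steps with per-axis
    variance 2*D_free*dt; a free pair closer than ``capture_radius``
    associates with per-frame probability 1 - exp(-k_on*dt).  Dimers: a
    common center diffuses at ``D_dimer`` and the labels sit at fixed
    distance ``dimer_separation`` with orientation re-drawn every frame
    (fast rotational diffusion limit); dissociation probability per frame
    is 1 - exp(-k_off*dt).  Boundaries reflect.  Observed positions add
    per-axis Gaussian localization noise; each observation is dropped
    independently with probability ``p_miss``.  The hidden state sequence
    is recorded per pair per frame.
    """
    rng = np.random.default_rng(config.seed)
    n, T = config.n_pairs, config.n_frames
    dt = config.dt
    L = config.roi_size

    diffusion_span = NM_PER_UM * math.sqrt(
        4.0 * max(config.D_free_ch1, config.D_free_ch2, config.D_dimer) * dt * T
    )
    if L < 3.0 * diffusion_span:
        logger.warning(
            "roi_size=%.0f nm is not large relative to the expected diffusion "
            "span %.0f nm; reflecting-boundary effects may be noticeable", L, diffusion_span,
        )

    std_free = np.array(
        [math.sqrt(2.0 * config.D_free_ch1 * dt), math.sqrt(2.0 * config.D_free_ch2 * dt)]
    ) * NM_PER_UM
    std_dimer = math.sqrt(2.0 * config.D_dimer * dt) * NM_PER_UM
    q_on = -math.expm1(-config.k_on * dt)
    q_off = -math.expm1(-config.k_off * dt)
    half_sep = 0.5 * config.dimer_separation

    pos = np.empty((n, 2, 2))  # (pair, label, xy), true positions
    center = rng.uniform(0.0, L, size=(n, 2))
    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=n)
    unit0 = np.stack([np.cos(theta0), np.sin(theta0)], axis=-1)
    if config.initial_state == "dimer":
        dimer = np.ones(n, dtype=bool)
        pos[:, 0] = center + half_sep * unit0
        pos[:, 1] = center - half_sep * unit0
    else:
        dimer = np.zeros(n, dtype=bool)
        r0 = config.capture_radius * np.sqrt(rng.random(n))
        pos[:, 0] = center
        pos[:, 1] = _reflect(center + r0[:, None] * unit0, L)

    true_pos = np.empty((T, n, 2, 2))
    states = np.empty((T, n), dtype=bool)
    true_pos[0] = pos
    states[0] = dimer

    for t in range(1, T):
        sep = np.hypot(pos[:, 0, 0] - pos[:, 1, 0], pos[:, 0, 1] - pos[:, 1, 1])
        u = rng.random(n)
        assoc = (~dimer) & (sep < config.capture_radius) & (u < q_on)
        dissoc = dimer & (u < q_off)
        dimer = (dimer | assoc) & ~dissoc

        # draws are made for every pair regardless of state so the stream
        # layout stays fixed; only the relevant ones are applied
        step_c = rng.normal(0.0, std_dimer, size=(n, 2)) if std_dimer > 0 else np.zeros((n, 2))
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        step_f = rng.standard_normal((n, 2, 2)) * std_free[None, :, None]

        centers = 0.5 * (pos[:, 0] + pos[:, 1])
        new_pos = np.empty_like(pos)
        d = dimer
        if np.any(d):
            cen = _reflect(centers[d] + step_c[d], L)
            off = half_sep * np.stack([np.cos(theta[d]), np.sin(theta[d])], axis=-1)
            new_pos[d, 0] = cen + off
            new_pos[d, 1] = cen - off
        f = ~dimer
        if np.any(f):
            new_pos[f] = _reflect(pos[f] + step_f[f], L)
        pos = new_pos
        true_pos[t] = pos
        states[t] = dimer

    # observation model
    noise = rng.standard_normal((T, n, 2, 2))
    noise[:, :, 0, :] *= config.sigma_loc_ch1
    noise[:, :, 1, :] *= config.sigma_loc_ch2
    obs = true_pos + noise
    seen = rng.random((T, n, 2)) >= config.p_miss

    frame_idx, pair_idx, label_idx = np.nonzero(seen)
    df = pd.DataFrame(
        {
            "frame": frame_idx.astype(np.int64),
            "particle_id": (2 * pair_idx + label_idx).astype(np.int64),
            "channel": (label_idx + 1).astype(np.int64),
            "x_nm": obs[frame_idx, pair_idx, label_idx, 0],
            "y_nm": obs[frame_idx, pair_idx, label_idx, 1],
        }
    ).sort_values(["particle_id", "frame"], kind="mergesort", ignore_index=True)

    gt_frames = np.tile(np.arange(T, dtype=np.int64), n)
    gt_pairs = np.repeat(np.arange(n, dtype=np.int64), T)
    gt_state = np.where(states.T.ravel(), "dimer", "free")
    ground_truth = pd.DataFrame({"pair_id": gt_pairs, "frame": gt_frames, "state": gt_state})

    return TrajectoryTable(df=df, frame_rate=config.frame_rate, roi_size=L, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# point patterns


@dataclass(frozen=True)
class PointPatternConfig:
    """Parameters of the two-species membrane-sheet point pattern.

    ``kind`` selects the spatial structure: "csr" (both species uniform,
    with exactly n1/n2 points), "clustered" (independent Thomas process per
    species) or "coclustered" (both species' offspring scattered around one
    shared Poisson parent set).  ``parent_intensity`` is parents per um^2;
    offspring counts are Poisson(``offspring_mean``) per parent per species;
    offspring scatter is isotropic Gaussian(``cluster_sigma``).
    """

    kind: str = "csr"
    window: tuple[float, float] = (1000.0, 1000.0)
    n1: int = 300
    n2: int = 300
    parent_intensity: float = 20.0
    offspring_mean: float = 5.0
    cluster_sigma: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("csr", "clustered", "coclustered"):
            raise ValueError("kind must be csr, clustered or coclustered")
        w, h = self.window
        if not (w > 0 and h > 0):
            raise ValueError("window sides must be positive")
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError("point counts must be >= 0")
        if self.kind != "csr":
            if self.cluster_sigma <= 0:
                raise ValueError("cluster_sigma must be > 0 for clustered kinds")
            if self.parent_intensity <= 0 or self.offspring_mean <= 0:
                raise ValueError("parent_intensity and offspring_mean must be > 0")


@dataclass
class PointPattern:
    """Two-species point coordinates inside a rectangular window (nm)."""

    coords1: np.ndarray  # (n1, 2)
    coords2: np.ndarray  # (n2, 2)
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.coords1 = np.asarray(self.coords1, dtype=float).reshape(-1, 2)
        self.coords2 = np.asarray(self.coords2, dtype=float).reshape(-1, 2)
        w, h = self.window
        if w <= 0 or h <= 0:
            raise ValueError("window must have positive area")
        for c in (self.coords1, self.coords2):
            if len(c) and (c.min() < -1e-9 or c[:, 0].max() > w + 1e-9 or c[:, 1].max() > h + 1e-9):
                raise ValueError("points must lie inside the window")

    @property
    def n1(self) -> int:
        return len(self.coords1)

    @property
    def n2(self) -> int:
        return len(self.coords2)

    @property
    def area(self) -> float:
        return self.window[0] * self.window[1]


def _thomas_offspring(parents: np.ndarray, offspring_mean: float, sigma: float,
                      window: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    counts = rng.poisson(offspring_mean, size=len(parents))
    if counts.sum() == 0:
        return np.empty((0, 2))
    centers = np.repeat(parents, counts, axis=0)
    pts = centers + rng.normal(0.0, sigma, size=centers.shape)
    w, h = window
    keep = (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
    return pts[keep]


def _draw_parents(config: PointPatternConfig, rng: np.random.Generator) -> np.ndarray:
    # parents are drawn in a window extended by 4 sigma so that offspring
    # intensity is unbiased near the edges
    w, h = config.window
    m = 4.0 * config.cluster_sigma
    area_ext_um2 = (w + 2 * m) * (h + 2 * m) / 1e6
    n_parents = rng.poisson(config.parent_intensity * area_ext_um2)
    return rng.uniform([-m, -m], [w + m, h + m], size=(n_parents, 2))


def simulate_point_pattern(config: PointPatternConfig) -> PointPattern:
    """Realize a two-species point pattern of the configured kind."""
    rng = np.random.default_rng(config.seed)
    w, h = config.window
    if config.kind == "csr":
        c1 = rng.uniform([0, 0], [w, h], size=(config.n1, 2)) if config.n1 else np.empty((0, 2))
        c2 = rng.uniform([0, 0], [w, h], size=(config.n2, 2)) if config.n2 else np.empty((0, 2))
    elif config.kind == "clustered":
        c1 = _thomas_offspring(_draw_parents(config, rng), config.offspring_mean,
                               config.cluster_sigma, config.window, rng)
        c2 = _thomas_offspring(_draw_parents(config, rng), config.offspring_mean,
                               config.cluster_sigma, config.window, rng)
    else:  # coclustered: one shared parent set
        parents = _draw_parents(config, rng)
        c1 = _thomas_offspring(parents, config.offspring_mean, config.cluster_sigma,
                               config.window, rng)
        c2 = _thomas_offspring(parents, config.offspring_mean, config.cluster_sigma,
                               config.window, rng)
    return PointPattern(coords1=c1, coords2=c2, window=config.window)
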
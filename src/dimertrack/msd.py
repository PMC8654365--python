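"""Mean squared displacement and diffusion-coefficient estimation.

The MSD is time-lag averaged with overlapping windows: MSD(n*dt) is the mean
of |r(i+n) - r(i)|^2 over every frame pair (i, i+n) present in a track.
For 2-D Brownian motion MSD(t) = 4*D*t + 4*sigma_loc^2, so D is estimated
as slope/4 of an ordinary least-squares line (with intercept) through the
first few MSD points; the intercept absorbs the localization-noise offset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Hashable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .tracks import Track

logger = logging.getLogger(__name__)

NM_PER_UM = 1000.0


@dataclass
class MSDCurve:
    """Time-lag-averaged MSD: lags in seconds, msd in um^2."""

    lags: np.ndarray
    msd: np.ndarray
    n_jumps: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_jumps = np.asarray(self.n_jumps, dtype=np.int64)
        if not (len(self.lags) == len(self.msd) == len(self.n_jumps)):
            raise ValueError("lags, msd and n_jumps must have equal length")


@dataclass
class DiffusionEstimate:
    """Fitted diffusion coefficient (um^2/s) with 95% CI from the slope SE."""

    D: float
    intercept: float
    ci95_lo: float
    ci95_hi: float
    n_points_fit: int
    n_jumps_total: int

    @property
    def non_positive(self) -> bool:
        return self.D <= 0


def _msd_sums(frames: np.ndarray, xy_nm: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-lag sum of squared displacements (um^2) and pair counts, lags 1..max_lag."""
    frames = np.asarray(frames, dtype=np.int64)
    xy = np.asarray(xy_nm, dtype=float) / NM_PER_UM
    span = int(frames[-1] - frames[0])
    dense = np.full((span + 1, 2), np.nan)
    dense[frames - frames[0]] = xy
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=np.int64)
    for n in range(1, min(max_lag, span) + 1):
        d = dense[n:] - dense[:-n]
        sq = d[:, 0] ** 2 + d[:, 1] ** 2
        ok = np.isfinite(sq)
        counts[n - 1] = ok.sum()
        sums[n - 1] = sq[ok].sum() if counts[n - 1] else 0.0
    return sums, counts


def compute_msd(track: Track, frame_rate: float, max_lag: int = 10) -> MSDCurve:
    """Time-averaged MSD of one track; lags with no contributing pair are omitted."""
    if len(track.frames) < 2:
        raise ValueError("track must have at least 2 localizations")
    sums, counts = _msd_sums(track.frames, track.xy, max_lag)
    keep = counts > 0
    lags = np.arange(1, max_lag + 1)[keep] / frame_rate
    with np.errstate(invalid="ignore"):
        msd = sums[keep] / counts[keep]
    return MSDCurve(lags=lags, msd=msd, n_jumps=counts[keep])


def ensemble_msd(tracks: Sequence[Track], frame_rate: float, max_lag: int = 10) -> MSDCurve:
    """Jump-weighted pooled MSD over all tracks.

    Every displacement pair from every track contributes with equal weight,
    matching ensemble plots annotated with total jump counts.
    """
    if not tracks:
        raise ValueError("at least one track is required")
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=np.int64)
    for tr in tracks:
        if len(tr.frames) < 2:
            continue
        s, c = _msd_sums(tr.frames, tr.xy, max_lag)
        sums += s
        counts += c
    keep = counts > 0
    if not keep.any():
        raise ValueError("no displacement pairs found in any track")
    lags = np.arange(1, max_lag + 1)[keep] / frame_rate
    return MSDCurve(lags=lags, msd=sums[keep] / counts[keep], n_jumps=counts[keep])


def fit_diffusion(curve: MSDCurve, n_points: int = 5) -> DiffusionEstimate:
    """OLS line through the first ``n_points`` MSD points; D = slope/4.

    The 95% CI comes from the slope standard error with a t distribution on
    n_points - 2 degrees of freedom.  A non-positive D is reported, not
    clipped; callers can check ``non_positive``.
    """
    if len(curve.lags) < n_points:
        raise ValueError(f"curve has {len(curve.lags)} lags; need >= {n_points}")
    if n_points < 3:
        raise ValueError("need at least 3 points to fit slope with uncertainty")
    x = curve.lags[:n_points]
    y = curve.msd[:n_points]
    res = stats.linregress(x, y)
    slope_se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    tcrit = stats.t.ppf(0.975, n_points - 2)
    D = res.slope / 4.0
    half = tcrit * slope_se / 4.0
    est = DiffusionEstimate(
        D=float(D),
        intercept=float(res.intercept),
        ci95_lo=float(D - half),
        ci95_hi=float(D + half),
        n_points_fit=n_points,
        n_jumps_total=int(curve.n_jumps[:n_points].sum()),
    )
    if est.non_positive:
        logger.warning("fitted diffusion coefficient is non-positive (D=%.3g um^2/s)", est.D)
    return est


def per_cell_D(
    tracks_by_cell: Mapping[Hashable, Sequence[Track]],
    frame_rate: float,
    max_lag: int = 10,
    n_points: int = 5,
) -> dict[Hashable, DiffusionEstimate]:
    """One ensemble-MSD fit per cell; cells without usable tracks are skipped."""
    out: dict[Hashable, DiffusionEstimate] = {}
    for cell, tracks in tracks_by_cell.items():
        usable = [t for t in tracks if len(t.frames) >= 2]
        if not usable:
            logger.warning("cell %r has no usable track; skipped", cell)
            continue
        try:
            curve = ensemble_msd(usable, frame_rate, max_lag=max_lag)
            out[cell] = fit_diffusion(curve, n_points=n_points)
        except ValueError as exc:
            logger.warning("cell %r skipped: %s", cell, exc)
    return out


def compare_mobility(D_groupA: Sequence[float], D_groupB: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on per-cell diffusion coefficients.

    Returns (statistic, p_value).  Chosen over a t test because per-cell D
    distributions are typically right-skewed.
    """
    a = np.asarray(D_groupA, dtype=float)
    b = np.asarray(D_groupB, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 cells per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all per-cell D values are tied; returning p = 1", stacklevel=2)
        return 0.0, 1.0
    stat, p = stats.ranksums(a, b)
    return float(stat), float(p)
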
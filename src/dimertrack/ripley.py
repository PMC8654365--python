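"""Bivariate Ripley's K co-clustering analysis with Monte-Carlo envelopes.

K12(r) is the cross-species cumulative pair-count statistic
K12(r) = (1 / (lambda1 * lambda2 * A)) * sum_ij e_ij * 1[d(x_i, y_j) <= r],
normalized so that K12(r) = pi r^2 under complete spatial randomness (CSR).
The variance-stabilized transform L(r) - r = sqrt(K12/pi) - r is zero in
expectation under CSR and positive when the two species co-cluster.
Significance is assessed against a pointwise envelope from CSR simulations
with the same point counts and window; co-clustering is called when the
experimental curve exceeds the upper envelope at any radius up to the
critical interaction distance (default 50 nm).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numba
import numpy as np

from .synthetic import PointPattern

logger = logging.getLogger(__name__)

DEFAULT_R_GRID = np.arange(5.0, 205.0, 5.0)
DEFAULT_N_SIMS = 999
DEFAULT_ALPHA = 0.01
DEFAULT_CRITICAL_DISTANCE = 50.0


@dataclass
class RipleyResult:
    """L(r)-r curve with CSR envelope bounds (all lengths nm)."""

    r: np.ndarray
    L_minus_r: np.ndarray
    K: np.ndarray
    env_lo: Optional[np.ndarray] = None
    env_hi: Optional[np.ndarray] = None
    n_sims: int = 0
    alpha: float = DEFAULT_ALPHA
    significant_coclustering: Optional[bool] = None
    exceed_radii: Optional[np.ndarray] = None


def _l_minus_r(K: np.ndarray, r: np.ndarray) -> np.ndarray:
    return np.sqrt(np.maximum(K, 0.0) / np.pi) - r


@numba.njit(cache=True)
def _pair_counts(c1: np.ndarray, c2: np.ndarray, W: float, H: float,
                 r_grid: np.ndarray, translation: bool) -> np.ndarray:
    """Edge-weighted cross-pair counts per radius bin (bin k: (r_{k-1}, r_k])."""
    area = W * H
    n_r = r_grid.shape[0]
    r_max_sq = r_grid[n_r - 1] * r_grid[n_r - 1]
    out = np.zeros(n_r, dtype=np.float64)
    for i in range(c1.shape[0]):
        x1 = c1[i, 0]
        y1 = c1[i, 1]
        for j in range(c2.shape[0]):
            dx = abs(x1 - c2[j, 0])
            dy = abs(y1 - c2[j, 1])
            dsq = dx * dx + dy * dy
            if dsq <= r_max_sq:
                d = np.sqrt(dsq)
                # first grid radius >= d: the pair contributes from there on
                k = np.searchsorted(r_grid, d)
                if translation:
                    out[k] += area / ((W - dx) * (H - dy))
                else:
                    out[k] += 1.0
    return out


def _batch_K(c1: np.ndarray, c2: np.ndarray, window: tuple[float, float],
             r_grid: np.ndarray, edge_correction: str = "translation") -> np.ndarray:
    """K12 on a radius grid for a batch of patterns.

    ``c1``: (B, n1, 2), ``c2``: (B, n2, 2).  Returns (B, n_r).  Translation
    (toroidal-shift) edge correction weights each cross pair by
    A / ((W - |dx|) (H - |dy|)).
    """
    if edge_correction not in ("translation", "none"):
        raise ValueError(f"unknown edge correction {edge_correction!r}")
    W, H = window
    area = W * H
    B, n1, _ = c1.shape
    n2 = c2.shape[1]
    r = np.ascontiguousarray(r_grid, dtype=np.float64)
    K = np.empty((B, len(r)))
    for b in range(B):
        counts = _pair_counts(np.ascontiguousarray(c1[b]), np.ascontiguousarray(c2[b]),
                              float(W), float(H), r, edge_correction == "translation")
        K[b] = np.cumsum(counts) * (area / (n1 * n2))
    return K


def bivariate_K(pattern: PointPattern, r_grid: Optional[np.ndarray] = None,
                edge_correction: str = "translation") -> RipleyResult:
    """Bivariate K12(r) and L(r)-r for one two-species pattern."""
    if pattern.n1 < 1 or pattern.n2 < 1:
        raise ValueError("both species need at least one point")
    r = np.asarray(DEFAULT_R_GRID if r_grid is None else r_grid, dtype=float)
    if np.any(r <= 0) or np.any(np.diff(r) <= 0):
        raise ValueError("r_grid must be positive and strictly increasing")
    half_min_side = 0.5 * min(pattern.window)
    if r.max() > half_min_side:
        logger.warning("max radius %.0f nm exceeds half the shorter window side "
                       "(%.0f nm); edge correction unreliable there", r.max(), half_min_side)
    K = _batch_K(pattern.coords1[None], pattern.coords2[None], pattern.window,
                 r, edge_correction)[0]
    return RipleyResult(r=r, L_minus_r=_l_minus_r(K, r), K=K)


def min_sims_for_alpha(alpha: float) -> int:
    return int(math.ceil(2.0 / alpha)) - 1


def csr_envelope(
    pattern: PointPattern,
    r_grid: Optional[np.ndarray] = None,
    n_sims: int = DEFAULT_N_SIMS,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    edge_correction: str = "translation",
    return_sims: bool = False,
    block: int = 64,
):
    """Pointwise CSR envelope of L(r)-r from Monte-Carlo simulations.

    Simulates ``n_sims`` patterns with the pattern's point counts i.i.d.
    uniform in its window; the bounds at each radius are the
    alpha/2 * (n_sims + 1) smallest and largest simulated values
    (order statistics, e.g. the 5th and 995th of 999 at alpha = 0.01).
    """
    r = np.asarray(DEFAULT_R_GRID if r_grid is None else r_grid, dtype=float)
    k = int(alpha / 2.0 * (n_sims + 1))
    if k < 1:
        raise ValueError(
            f"n_sims={n_sims} too small for alpha={alpha}; need at least "
            f"{min_sims_for_alpha(alpha)} simulations"
        )
    rng = np.random.default_rng(seed)
    W, H = pattern.window
    n1, n2 = pattern.n1, pattern.n2
    sims = np.empty((n_sims, len(r)))
    done = 0
    while done < n_sims:
        b = min(block, n_sims - done)
        c1 = rng.uniform([0, 0], [W, H], size=(b, n1, 2))
        c2 = rng.uniform([0, 0], [W, H], size=(b, n2, 2))
        K = _batch_K(c1, c2, pattern.window, r, edge_correction)
        sims[done:done + b] = _l_minus_r(K, r[None, :])
        done += b
    order = np.sort(sims, axis=0)
    env_lo, env_hi = order[k - 1], order[n_sims - k]
    if return_sims:
        return env_lo, env_hi, sims
    return env_lo, env_hi


def coclustering_test(result: RipleyResult,
                      critical_distance: float = DEFAULT_CRITICAL_DISTANCE) -> RipleyResult:
    """Call co-clustering from the envelope exceedance at short range.

    Significant iff the experimental L(r)-r lies above the upper envelope
    for at least one radius <= ``critical_distance``.  Fills the result's
    ``significant_coclustering`` and ``exceed_radii`` fields in place.
    """
    if result.env_hi is None:
        raise ValueError("result has no envelope; run csr_envelope first")
    if result.r.max() < critical_distance:
        raise ValueError(
            f"radius grid (max {result.r.max():.0f} nm) does not cover the "
            f"critical distance {critical_distance:.0f} nm"
        )
    mask = result.r <= critical_distance
    exceed = mask & (result.L_minus_r > result.env_hi)
    result.significant_coclustering = bool(exceed.any())
    result.exceed_radii = result.r[exceed]
    return result


def ripley_analysis(
    pattern: PointPattern,
    r_grid: Optional[np.ndarray] = None,
    n_sims: int = DEFAULT_N_SIMS,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    critical_distance: float = DEFAULT_CRITICAL_DISTANCE,
    edge_correction: str = "translation",
) -> RipleyResult:
    """Full co-clustering analysis: K12, CSR envelope, significance call."""
    res = bivariate_K(pattern, r_grid, edge_correction)
    res.env_lo, res.env_hi = csr_envelope(pattern, res.r, n_sims=n_sims, alpha=alpha,
                                          seed=seed, edge_correction=edge_correction)
    res.n_sims = n_sims
    res.alpha = alpha
    return coclustering_test(res, critical_distance)
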
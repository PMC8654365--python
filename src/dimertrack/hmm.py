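"""Two-state hidden Markov model over pair-separation series.

Hidden states are free (0) and dimer (1).  The observation at each frame is
the scalar separation s (nm) between the two particles of a candidate pair.
Emissions: in the dimer state s is Rayleigh with scale ``sigma_d`` (the
radial distance of two isotropic Gaussian label positions, absorbing both
localization error and the physical label offset); in the free state s is
triangular-in-radius, 2s/s_max^2 on (0, s_max], the radial density of a
partner placed uniformly inside the candidate disk.  Separations are
treated as conditionally independent given the states — the diffusive
autocorrelation of the relative position is a documented approximation.

Transitions are per-frame probabilities p_on (free->dimer) and p_off
(dimer->free).  The continuous-time dissociation rate follows as
k_off = -ln(1 - p_off) * frame_rate, exact for a two-state Markov chain
observed at the camera interval.  Missing frames inside a series are
handled by applying the transition matrix without an emission factor,
which equals the matrix-power propagation over the gap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize

from .pairs import PairSeries

logger = logging.getLogger(__name__)

STATE_FREE, STATE_DIMER = "free", "dimer"
_TINY = 1e-300
MAX_GAP = 10  # longer gaps split a series before fitting


@dataclass(frozen=True)
class HMMParams:
    """Two-state transition and emission parameters.

    p_on, p_off are per-frame transition probabilities; sigma_d (nm) the
    dimer-state Rayleigh scale; s_max (nm) the free-state support bound
    (fixed to the candidate gate); pi_dimer the initial dimer probability.
    """

    p_on: float = 0.02
    p_off: float = 0.02
    sigma_d: float = 30.0
    s_max: float = 500.0
    pi_dimer: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_on", "p_off", "pi_dimer"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sigma_d <= 0 or self.s_max <= 0:
            raise ValueError("sigma_d and s_max must be > 0")

    @property
    def transition_matrix(self) -> np.ndarray:
        return np.array([[1 - self.p_on, self.p_on], [self.p_off, 1 - self.p_off]])


@dataclass
class DimerEvent:
    """One maximal same-state run of observed frames (end_frame inclusive)."""

    start_frame: int
    end_frame: int
    state: str
    n_frames: int               # observed frames in the event (gaps excluded)
    duration_s: Optional[float] = None


@dataclass
class DimerEvents:
    pair_id: int
    events: list[DimerEvent]

    def durations(self, state: str = STATE_DIMER) -> np.ndarray:
        return np.array([e.n_frames for e in self.events if e.state == state], dtype=float)


@dataclass
class HMMFit:
    params: HMMParams
    log_likelihood: float
    n_series: int
    converged: bool


@dataclass
class KoffEstimate:
    """Dissociation rate (1/s) with bootstrap SE and derived mean lifetime."""

    k_off: float
    se: Optional[float]
    mean_lifetime: float        # s; inf when k_off == 0
    n_pairs: int
    n_dimer_frames: int
    log_likelihood: float


# ---------------------------------------------------------------------------
# emissions


def emission_density(s, state: str, params: HMMParams):
    """Emission probability density of separation ``s`` (nm) in a state."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("separations must be >= 0")
    if state == STATE_DIMER:
        sig2 = params.sigma_d ** 2
        out = (s / sig2) * np.exp(-0.5 * s * s / sig2)
    elif state == STATE_FREE:
        out = np.where((s > 0) & (s <= params.s_max), 2.0 * s / params.s_max ** 2, 0.0)
    else:
        raise ValueError(f"unknown state {state!r}")
    return out if out.ndim else float(out)


def _emission_matrix(S: np.ndarray, sigma_d: float, s_max: float) -> np.ndarray:
    """Densities (n, T, 2) on a padded separation matrix; NaN entries -> 1.

    Unobserved frames (gaps and padding beyond a series' end) carry density
    one in both states, so the scaled forward step reduces to the pure
    transition (matrix power) and contributes nothing to the likelihood.
    """
    dens = np.ones(S.shape + (2,))
    obs = np.isfinite(S)
    s = S[obs]
    dens[obs, 0] = np.where((s > 0) & (s <= s_max), 2.0 * s / s_max ** 2, 0.0)
    sig2 = sigma_d * sigma_d
    dens[obs, 1] = (s / sig2) * np.exp(-0.5 * s * s / sig2)
    return dens


# ---------------------------------------------------------------------------
# packing

def split_long_gaps(series: Sequence[PairSeries], max_gap: int = MAX_GAP) -> list[PairSeries]:
    """Split series at gaps longer than ``max_gap`` missing frames."""
    out: list[PairSeries] = []
    for ps in series:
        splits = np.flatnonzero(np.diff(ps.frames) > max_gap + 1) + 1
        if len(splits) == 0:
            out.append(ps)
            continue
        for chunk in np.split(np.arange(len(ps.frames)), splits):
            if len(chunk) == 0:
                continue
            out.append(PairSeries(
                pair_id=ps.pair_id, frames=ps.frames[chunk],
                xy1=ps.xy1[chunk], xy2=ps.xy2[chunk],
                particle_id1=ps.particle_id1, particle_id2=ps.particle_id2,
            ))
    return out


@dataclass
class _Packed:
    """Separations on a dense frame grid, rows sorted by span (descending).

    ``order`` maps sorted row -> original series index; ``n_active[t]`` is
    the number of sorted rows whose span exceeds t, so the forward loop can
    restrict work to series still running at step t.
    """

    S: np.ndarray          # (n, T_max), NaN = missing frame
    spans: np.ndarray      # (n,) sorted descending
    order: np.ndarray      # (n,) original indices
    n_active: np.ndarray   # (T_max,)


def _pack(series: Sequence[PairSeries]) -> _Packed:
    if not series:
        raise ValueError("no pair series provided")
    spans = np.array([ps.frames[-1] - ps.frames[0] + 1 for ps in series], dtype=np.int64)
    order = np.argsort(-spans, kind="stable")
    spans_sorted = spans[order]
    T_max = int(spans_sorted[0])
    S = np.full((len(series), T_max), np.nan)
    for row, idx in enumerate(order):
        ps = series[idx]
        s = ps.s
        if not np.all(np.isfinite(s)):
            raise ValueError(f"pair {ps.pair_id}: non-finite separations")
        S[row, ps.frames - ps.frames[0]] = s
    # rows with span > t still have frame t; spans sorted descending
    n_active = np.searchsorted(-spans_sorted, -np.arange(T_max), side="left")
    return _Packed(S=S, spans=spans_sorted, order=order, n_active=n_active)


# ---------------------------------------------------------------------------
# forward / Viterbi


def _emission_cols(s_col: np.ndarray, sigma_d: float, s_max: float):
    """Densities for one frame column; NaN (missing) entries get density 1."""
    obs = np.isfinite(s_col)
    d0 = np.ones_like(s_col)
    d1 = np.ones_like(s_col)
    sv = s_col[obs]
    d0[obs] = np.where((sv > 0) & (sv <= s_max), 2.0 * sv / (s_max * s_max), 0.0)
    sig2 = sigma_d * sigma_d
    d1[obs] = (sv / sig2) * np.exp(-0.5 * sv * sv / sig2)
    return d0, d1


def _batch_forward(packed: _Packed, p_on: float, p_off: float, sigma_d: float,
                   s_max: float, pi_dimer: float) -> np.ndarray:
    """Scaled forward recursion vectorized over series; per-series loglik.

    Unobserved frames carry unit emission, so the step reduces to the pure
    transition (the g-step matrix power over a gap) and adds nothing to the
    likelihood.  Work at step t is restricted to series still running.
    """
    S = packed.S
    n, T = S.shape
    p00, p01 = 1.0 - p_on, p_on
    p10, p11 = p_off, 1.0 - p_off
    d0, d1 = _emission_cols(S[:, 0], sigma_d, s_max)
    a0 = (1.0 - pi_dimer) * d0
    a1 = pi_dimer * d1
    c = np.maximum(a0 + a1, _TINY)
    ll = np.log(c)
    a0 /= c
    a1 /= c
    for t in range(1, T):
        m = int(packed.n_active[t])
        if m == 0:
            break
        d0, d1 = _emission_cols(S[:m, t], sigma_d, s_max)
        b0 = (a0[:m] * p00 + a1[:m] * p10) * d0
        b1 = (a0[:m] * p01 + a1[:m] * p11) * d1
        c = np.maximum(b0 + b1, _TINY)
        ll[:m] += np.log(c)
        a0[:m] = b0 / c
        a1[:m] = b1 / c
    out = np.empty(n)
    out[packed.order] = ll
    return out


def forward_loglik(series: PairSeries, params: HMMParams) -> float:
    """Log-likelihood of one pair-separation series under the two-state HMM."""
    packed = _pack([series])
    return float(_batch_forward(packed, params.p_on, params.p_off, params.sigma_d,
                                params.s_max, params.pi_dimer)[0])


def total_loglik(series: Sequence[PairSeries], params: HMMParams) -> float:
    packed = _pack(series)
    return float(_batch_forward(packed, params.p_on, params.p_off, params.sigma_d,
                                params.s_max, params.pi_dimer).sum())


def viterbi_segment(series: PairSeries, params: HMMParams,
                    frame_rate: Optional[float] = None) -> DimerEvents:
    """Maximum-a-posteriori state path, merged into events.

    Gap frames carry no emission and are assigned no state; they do not
    split an event when the flanking observed frames share a state, and
    they are excluded from event durations.
    """
    frames = series.frames
    f0 = int(frames[0])
    span = int(frames[-1]) - f0 + 1
    S = np.full(span, np.nan)
    S[frames - f0] = series.s
    dens = _emission_matrix(S[None, :], params.sigma_d, params.s_max)[0]
    with np.errstate(divide="ignore"):
        logdens = np.log(np.maximum(dens, _TINY))
        logP = np.log(np.maximum(params.transition_matrix, _TINY))
        logpi = np.log(np.maximum(np.array([1 - params.pi_dimer, params.pi_dimer]), _TINY))
    delta = logpi + logdens[0]
    psi = np.zeros((span, 2), dtype=np.int8)
    for t in range(1, span):
        cand = delta[:, None] + logP          # cand[i, j]
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], [0, 1]] + logdens[t]
    path = np.zeros(span, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(span - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]

    observed = np.isfinite(S)
    obs_idx = np.flatnonzero(observed)
    events: list[DimerEvent] = []
    start = obs_idx[0]
    prev = obs_idx[0]
    count = 1
    for i in obs_idx[1:]:
        if path[i] != path[prev]:
            events.append(_mk_event(start + f0, prev + f0, path[prev], count, frame_rate))
            start = i
            count = 1
        else:
            count += 1
        prev = i
    events.append(_mk_event(start + f0, prev + f0, path[prev], count, frame_rate))
    return DimerEvents(pair_id=series.pair_id, events=events)


def _mk_event(start: int, end: int, state: int, n_frames: int,
              frame_rate: Optional[float]) -> DimerEvent:
    return DimerEvent(
        start_frame=int(start), end_frame=int(end),
        state=STATE_DIMER if state == 1 else STATE_FREE,
        n_frames=int(n_frames),
        duration_s=(n_frames / frame_rate) if frame_rate else None,
    )


# ---------------------------------------------------------------------------
# fitting

_PARAM_NAMES = ("p_on", "p_off", "sigma_d", "pi_dimer")
_LOGIT_LO, _LOGIT_HI = 1e-6, 1.0 - 1e-6


def _logit(p: float) -> float:
    p = min(max(p, _LOGIT_LO), _LOGIT_HI)
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def fit_hmm(
    all_series: Sequence[PairSeries],
    init: HMMParams,
    fixed: Iterable[str] = (),
    n_starts: int = 5,
    seed: int = 0,
    maxiter: int = 300,
    _weights: Optional[np.ndarray] = None,
    _packed: Optional[_Packed] = None,
) -> HMMFit:
    """Maximize the summed forward log-likelihood by bounded quasi-Newton.

    Free parameters among (p_on, p_off, sigma_d, pi_dimer) are optimized on
    logit/log scales with L-BFGS-B; ``s_max`` stays fixed at the candidate
    gate.  ``n_starts`` seeded restarts perturb the initial point to guard
    against local optima; the result is deterministic given data, ``init``
    and ``seed``.
    """
    fixed = frozenset(fixed)
    unknown = fixed - set(_PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown fixed parameter names: {sorted(unknown)}")
    free_names = [nm for nm in _PARAM_NAMES if nm not in fixed]
    if not free_names:
        ll = total_loglik(all_series, init)
        return HMMFit(params=init, log_likelihood=ll, n_series=len(all_series), converged=True)

    if _packed is None:
        series = split_long_gaps(all_series)
        if not any(len(ps) >= 2 for ps in series):
            raise ValueError("need at least one series with >= 2 frames")
        packed = _pack(series)
    else:
        packed = _packed
    weights = _weights
    s_max = init.s_max

    def to_vector(p: HMMParams) -> np.ndarray:
        vals = {"p_on": _logit(p.p_on), "p_off": _logit(p.p_off),
                "sigma_d": math.log(p.sigma_d), "pi_dimer": _logit(p.pi_dimer)}
        return np.array([vals[nm] for nm in free_names])

    def to_params(x: np.ndarray) -> HMMParams:
        d = dict(zip(free_names, x))
        return HMMParams(
            p_on=_expit(d["p_on"]) if "p_on" in d else init.p_on,
            p_off=_expit(d["p_off"]) if "p_off" in d else init.p_off,
            sigma_d=math.exp(d["sigma_d"]) if "sigma_d" in d else init.sigma_d,
            s_max=s_max,
            pi_dimer=_expit(d["pi_dimer"]) if "pi_dimer" in d else init.pi_dimer,
        )

    bound_map = {
        "p_on": (_logit(1e-5), _logit(0.95)),
        "p_off": (_logit(1e-5), _logit(0.95)),
        "sigma_d": (math.log(0.5), math.log(s_max)),
        "pi_dimer": (_logit(1e-4), _logit(1.0 - 1e-4)),
    }
    bounds = [bound_map[nm] for nm in free_names]

    def negll(x: np.ndarray) -> float:
        p = to_params(x)
        ll = _batch_forward(packed, p.p_on, p.p_off, p.sigma_d, s_max, p.pi_dimer)
        total = float(ll @ weights) if weights is not None else float(ll.sum())
        return -total

    rng = np.random.default_rng(seed)
    x_init = to_vector(init)
    best = None
    for k in range(max(1, n_starts)):
        x0 = x_init if k == 0 else np.clip(
            x_init + rng.normal(0.0, 0.75, size=len(x_init)),
            [b[0] for b in bounds], [b[1] for b in bounds],
        )
        res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("HMM optimization failed")
    if not best.success:
        logger.warning("HMM optimizer did not report convergence: %s", best.message)
    return HMMFit(params=to_params(best.x), log_likelihood=-float(best.fun),
                  n_series=len(all_series), converged=bool(best.success))


# ---------------------------------------------------------------------------
# off-rate


def koff_from_p(p_off: float, frame_rate: float) -> float:
    """Continuous-time rate from the per-frame probability: -ln(1-p)*rate."""
    if p_off >= 1.0:
        raise ValueError("p_off = 1 implies an infinite dissociation rate")
    return -math.log1p(-p_off) * frame_rate


def estimate_koff(
    all_series: Sequence[PairSeries],
    params: HMMParams,
    frame_rate: float,
    n_boot: int = 200,
    seed: int = 0,
) -> KoffEstimate:
    """Dissociation rate with pair-level bootstrap standard error.

    The point estimate converts the fitted per-frame p_off; the SE is the
    standard deviation of k_off over ``n_boot`` nonparametric resamples of
    the pair series, refitting the transition probabilities with the
    emission parameters held fixed.  ``n_boot = 0`` skips the bootstrap.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    k_off = koff_from_p(params.p_off, frame_rate)
    lifetime = math.inf if k_off == 0 else 1.0 / k_off

    series = split_long_gaps(all_series)
    n_dimer = 0
    for ps in series:
        ev = viterbi_segment(ps, params)
        n_dimer += int(ev.durations(STATE_DIMER).sum())
    ll = total_loglik(series, params)

    se: Optional[float] = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        packed = _pack(series)
        n = len(series)
        ks = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            w = np.bincount(idx, minlength=n).astype(float)
            fit = fit_hmm(series, params, fixed=("sigma_d", "pi_dimer"),
                          n_starts=1, seed=seed, _weights=w, _packed=packed)
            ks[b] = koff_from_p(fit.params.p_off, frame_rate)
        se = float(np.std(ks, ddof=1))
    return KoffEstimate(k_off=float(k_off), se=se, mean_lifetime=float(lifetime),
                        n_pairs=len(all_series), n_dimer_frames=n_dimer,
                        log_likelihood=float(ll))
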
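"""Workflow drivers binding the analysis stages into reproducible runs.

Two workflows:

* ``spt``    — (optional simulation) -> ensemble MSD + diffusion fit ->
  candidate pairs -> correlated motion -> HMM fit -> off-rate estimate.
* ``ripley`` — (optional simulation) -> bivariate K -> CSR envelope ->
  co-clustering call.

Every run is driven by a RunConfig (typically parsed from a YAML file with
strictly validated keys), consumes a single root seed with named substreams
per stage, writes all stage tables plus a JSON summary into the output
directory, and drops a resolved copy of the configuration next to the
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import io as dio
from ._rng import stage_seed
from .hmm import HMMParams, estimate_koff, fit_hmm, viterbi_segment
from .msd import ensemble_msd, fit_diffusion
from .pairs import (DEFAULT_MAX_GAP, DEFAULT_MIN_FRAMES, DEFAULT_S_MAX,
                    correlated_jump_stats, find_candidate_pairs)
from .ripley import DEFAULT_ALPHA, DEFAULT_CRITICAL_DISTANCE, DEFAULT_N_SIMS, ripley_analysis
from .synthetic import (PointPatternConfig, SimConfig, simulate_pair_tracks,
                        simulate_point_pattern)

logger = logging.getLogger(__name__)

_WORKFLOWS = ("spt", "ripley", "simulate")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    workflow: str
    outdir: Path
    seed: int = 0
    input_path: Optional[Path] = None
    simulate: Optional[dict[str, Any]] = None        # SimConfig overrides
    pattern: Optional[dict[str, Any]] = None         # PointPatternConfig overrides
    msd: dict[str, Any] = field(default_factory=dict)
    pairs: dict[str, Any] = field(default_factory=dict)
    hmm: dict[str, Any] = field(default_factory=dict)
    ripley: dict[str, Any] = field(default_factory=dict)

    _KEYS = {"workflow", "outdir", "seed", "input_path", "simulate", "pattern",
             "msd", "pairs", "hmm", "ripley"}
    _MSD_KEYS = {"max_lag", "n_points"}
    _PAIRS_KEYS = {"s_max", "min_frames", "max_gap", "bin_width"}
    _HMM_KEYS = {"p_on", "p_off", "sigma_d", "pi_dimer", "n_starts", "n_boot", "maxiter"}
    _RIPLEY_KEYS = {"r_min", "r_max", "r_step", "n_sims", "alpha", "critical_distance",
                    "edge_correction"}

    def __post_init__(self) -> None:
        if self.workflow not in _WORKFLOWS:
            raise ValueError(f"workflow must be one of {_WORKFLOWS}")
        self.outdir = Path(self.outdir)
        if self.input_path is not None:
            self.input_path = Path(self.input_path)
        for name, allowed in (("msd", self._MSD_KEYS), ("pairs", self._PAIRS_KEYS),
                              ("hmm", self._HMM_KEYS), ("ripley", self._RIPLEY_KEYS)):
            unknown = set(getattr(self, name)) - allowed
            if unknown:
                raise ValueError(f"unknown keys in {name!r} block: {sorted(unknown)}")
        for name, cls in (("simulate", SimConfig), ("pattern", PointPatternConfig)):
            block = getattr(self, name)
            if block is not None:
                allowed = {f.name for f in dataclasses.fields(cls)}
                unknown = set(block) - allowed
                if unknown:
                    raise ValueError(f"unknown keys in {name!r} block: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - cls._KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        d["input_path"] = None if self.input_path is None else str(self.input_path)
        return d


def _write_resolved(config: RunConfig) -> None:
    config.outdir.mkdir(parents=True, exist_ok=True)
    (config.outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))


def _stage(name: str):
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    return t0


def _stage_done(name: str, t0: float, **info: Any) -> None:
    logger.info("stage %s: done in %.2f s %s", name, time.perf_counter() - t0,
                " ".join(f"{k}={v}" for k, v in info.items()))


def run_spt_workflow(config: RunConfig, make_plots: bool = True) -> dict[str, Any]:
    """Simulate (optionally), then run MSD -> pairs -> HMM -> off-rate."""
    _write_resolved(config)
    out = config.outdir

    if config.simulate is not None:
        t0 = _stage("simulate")
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate-tracks"))
        sim = SimConfig(**sim_kwargs)
        table = simulate_pair_tracks(sim)
        dio.write_trajectories(table, out / "tracks.csv")
        _stage_done("simulate", t0, rows=len(table))
    elif config.input_path is not None:
        table = dio.read_trajectories(config.input_path)
    else:
        raise ValueError("spt workflow needs input_path or a simulate block")

    # MSD / diffusion
    t0 = _stage("msd")
    tracks = table.tracks()
    max_lag = int(config.msd.get("max_lag", 10))
    n_points = int(config.msd.get("n_points", 5))
    curve = ensemble_msd(tracks, table.frame_rate, max_lag=max_lag)
    est_D = fit_diffusion(curve, n_points=n_points)
    dio.write_msd_curve(curve, out / "msd_ensemble.csv")
    _stage_done("msd", t0, n_tracks=len(tracks), D=f"{est_D.D:.4g}")

    # candidate pairs + correlated motion
    t0 = _stage("pairs")
    s_max = float(config.pairs.get("s_max", DEFAULT_S_MAX))
    min_frames = int(config.pairs.get("min_frames", DEFAULT_MIN_FRAMES))
    max_gap = int(config.pairs.get("max_gap", DEFAULT_MAX_GAP))
    bin_width = float(config.pairs.get("bin_width", 50.0))
    pairs = find_candidate_pairs(table.tracks(channel=1), table.tracks(channel=2),
                                 s_max=s_max, min_frames=min_frames, max_gap=max_gap)
    dio.write_pair_series(pairs, out / "pair_series.csv")
    corr = None
    if pairs:
        corr = correlated_jump_stats(pairs, np.arange(0.0, s_max + bin_width, bin_width))
        dio.write_correlated_motion(corr, out / "correlated_motion.csv")
    _stage_done("pairs", t0, n_pairs=len(pairs))

    # HMM + off-rate
    koff = None
    if pairs:
        t0 = _stage("hmm")
        init = HMMParams(
            p_on=float(config.hmm.get("p_on", 0.02)),
            p_off=float(config.hmm.get("p_off", 0.02)),
            sigma_d=float(config.hmm.get("sigma_d", 30.0)),
            s_max=s_max,
            pi_dimer=float(config.hmm.get("pi_dimer", 0.5)),
        )
        fit = fit_hmm(pairs, init, n_starts=int(config.hmm.get("n_starts", 5)),
                      seed=stage_seed(config.seed, "hmm-fit"),
                      maxiter=int(config.hmm.get("maxiter", 300)))
        (out / "hmm_params.json").write_text(json.dumps(
            {"p_on": fit.params.p_on, "p_off": fit.params.p_off,
             "sigma_d_nm": fit.params.sigma_d, "s_max_nm": fit.params.s_max,
             "pi_dimer": fit.params.pi_dimer,
             "log_likelihood": fit.log_likelihood, "converged": fit.converged},
            indent=2, sort_keys=True) + "\n")
        events = [viterbi_segment(p, fit.params, table.frame_rate) for p in pairs]
        dio.write_events(events, out / "events.csv")
        koff = estimate_koff(pairs, fit.params, table.frame_rate,
                             n_boot=int(config.hmm.get("n_boot", 200)),
                             seed=stage_seed(config.seed, "hmm-bootstrap"))
        dio.write_koff(koff, out / "koff.json")
        _stage_done("hmm", t0, k_off=f"{koff.k_off:.4g}")

    summary = {
        "workflow": "spt",
        "seed": config.seed,
        "n_tracks": len(tracks),
        "n_pairs": len(pairs),
        "D_um2_per_s": est_D.D,
        "D_ci95": [est_D.ci95_lo, est_D.ci95_hi],
        "msd_intercept_um2": est_D.intercept,
        "k_off_per_s": None if koff is None else koff.k_off,
        "k_off_se_per_s": None if koff is None else koff.se,
        "mean_lifetime_s": None if koff is None or np.isinf(koff.mean_lifetime)
        else koff.mean_lifetime,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    if make_plots:
        _plot_spt(out, curve, corr)
    return summary


def run_ripley_workflow(config: RunConfig, make_plots: bool = True) -> dict[str, Any]:
    """Simulate (optionally), then run bivariate K -> envelope -> test."""
    _write_resolved(config)
    out = config.outdir
    rip = config.ripley
    n_sims = int(rip.get("n_sims", DEFAULT_N_SIMS))
    alpha = float(rip.get("alpha", DEFAULT_ALPHA))
    from .ripley import min_sims_for_alpha
    if n_sims < min_sims_for_alpha(alpha):
        raise ValueError(f"n_sims={n_sims} below the minimum "
                         f"{min_sims_for_alpha(alpha)} for alpha={alpha}")

    if config.pattern is not None:
        pat_kwargs = dict(config.pattern)
        pat_kwargs.setdefault("seed", stage_seed(config.seed, "simulate-pattern"))
        if "window" in pat_kwargs:
            pat_kwargs["window"] = tuple(pat_kwargs["window"])
        pattern = simulate_point_pattern(PointPatternConfig(**pat_kwargs))
        dio.write_point_pattern(pattern, out / "pattern.csv")
    elif config.input_path is not None:
        pattern = dio.read_point_pattern(config.input_path)
    else:
        raise ValueError("ripley workflow needs input_path or a pattern block")

    t0 = _stage("ripley")
    r_grid = np.arange(float(rip.get("r_min", 5.0)),
                       float(rip.get("r_max", 200.0)) + float(rip.get("r_step", 5.0)),
                       float(rip.get("r_step", 5.0)))
    result = ripley_analysis(
        pattern, r_grid, n_sims=n_sims, alpha=alpha,
        seed=stage_seed(config.seed, "ripley-envelope"),
        critical_distance=float(rip.get("critical_distance", DEFAULT_CRITICAL_DISTANCE)),
        edge_correction=str(rip.get("edge_correction", "translation")),
    )
    dio.write_ripley(result, out / "ripley.csv")
    _stage_done("ripley", t0, n1=pattern.n1, n2=pattern.n2,
                significant=result.significant_coclustering)

    summary = {
        "workflow": "ripley",
        "seed": config.seed,
        "n1": pattern.n1,
        "n2": pattern.n2,
        "significant_coclustering": result.significant_coclustering,
        "exceed_radii_nm": [] if result.exceed_radii is None
        else [float(x) for x in result.exceed_radii],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    if make_plots:
        _plot_ripley(out, result)
    return summary


# ---------------------------------------------------------------------------
# plots (file output only; Agg backend)


def _plot_spt(out: Path, curve, corr) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(curve.lags, curve.msd, "o-", ms=3)
    ax.set_xlabel(r"time lag $\Delta t$ (s)")
    ax.set_ylabel(r"MSD ($\mu$m$^2$)")
    fig.tight_layout()
    fig.savefig(out / "msd_ensemble.png", dpi=150)
    plt.close(fig)

    if corr is not None:
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ok = corr.n_jumps > 0
        x = corr.separation_bin_centers[ok]
        ax.plot(x, corr.mean_uncorrelated_jump[ok], "o-", ms=3, label="uncorrelated jump")
        ax.plot(x, corr.mean_jump_magnitude[ok], "s-", ms=3, label="jump magnitude")
        ax.set_xlabel("pair separation (nm)")
        ax.set_ylabel("distance (nm)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out / "correlated_motion.png", dpi=150)
        plt.close(fig)


def _plot_ripley(out: Path, result) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(result.r, result.L_minus_r, color="magenta", label="experimental")
    ax.plot(result.r, result.env_lo, "k--", lw=0.8, label="99% CSR envelope")
    ax.plot(result.r, result.env_hi, "k--", lw=0.8)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("r (nm)")
    ax.set_ylabel("L(r) - r (nm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "ripley.png", dpi=150)
    plt.close(fig)
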
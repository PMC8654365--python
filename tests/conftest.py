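"""Shared fixtures: expensive simulations are session-scoped and reused."""

from __future__ import annotations

import numpy as np
import pytest

from dimertrack.hmm import HMMParams, estimate_koff, fit_hmm
from dimertrack.pairs import find_candidate_pairs
from dimertrack.synthetic import SimConfig, simulate_pair_tracks
from dimertrack.tracks import TrajectoryTable


def run_koff_pipeline(k_off: float, seed: int, n_pairs: int = 300, n_frames: int = 1000,
                      n_boot: int = 0):
    """Simulate -> candidate pairs -> HMM fit -> off-rate, at full scale.

    Camera settings follow the acquisition protocol (20 frames/s, 1000-frame
    movies); the ROI keeps the pair density at single-molecule levels
    (~0.08 pairs/um^2).
    """
    cfg = SimConfig(n_pairs=n_pairs, n_frames=n_frames, frame_rate=20.0,
                    k_off=k_off, k_on=1.0, initial_state="dimer",
                    roi_size=62000.0, seed=seed)
    table = simulate_pair_tracks(cfg)
    pairs = find_candidate_pairs(table.tracks(channel=1), table.tracks(channel=2))
    fit = fit_hmm(pairs, HMMParams(s_max=500.0), seed=seed + 1)
    est = estimate_koff(pairs, fit.params, cfg.frame_rate, n_boot=n_boot, seed=seed + 2)
    return cfg, table, fit, est


@pytest.fixture(scope="session")
def homo_koff_recovery():
    """Full-pipeline off-rate recovery at the homo-interaction rate (0.18/s)."""
    return run_koff_pipeline(k_off=0.18, seed=11)


@pytest.fixture(scope="session")
def hetero_koff_recovery():
    """Full-pipeline off-rate recovery at the hetero-interaction rate (0.49/s)."""
    return run_koff_pipeline(k_off=0.49, seed=23)


@pytest.fixture(scope="session")
def free_diffusion_table() -> TrajectoryTable:
    """200 freely diffusing tracks (100 pairs, k_on = 0) at D = 0.05 um^2/s,
    500 frames, 20 nm localization noise."""
    cfg = SimConfig(n_pairs=100, n_frames=500, D_free_ch1=0.05, D_free_ch2=0.05,
                    k_on=0.0, k_off=0.0, initial_state="free",
                    sigma_loc_ch1=20.0, sigma_loc_ch2=20.0,
                    roi_size=60000.0, seed=42)
    return simulate_pair_tracks(cfg)


@pytest.fixture(scope="session")
def free_diffusion_table_noiseless() -> TrajectoryTable:
    """Same design without localization noise."""
    cfg = SimConfig(n_pairs=100, n_frames=500, D_free_ch1=0.05, D_free_ch2=0.05,
                    k_on=0.0, k_off=0.0, initial_state="free",
                    sigma_loc_ch1=0.0, sigma_loc_ch2=0.0,
                    roi_size=60000.0, seed=42)
    return simulate_pair_tracks(cfg)
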
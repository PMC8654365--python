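"""Generate the synthetic study datasets used by the downstream analyses.

Writes two-color tracking tables (mobility series at two diffusion
coefficients, and dimerizing-pair movies at the homo- and hetero-interaction
off-rates) plus three membrane-sheet point patterns (CSR, independently
clustered, co-clustered) under results/data/.
"""

from pathlib import Path

from dimertrack import io as dio
from dimertrack._rng import stage_seed
from dimertrack.synthetic import (PointPatternConfig, SimConfig, simulate_pair_tracks,
                                  simulate_point_pattern)

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # mobility datasets: free receptors at two diffusion coefficients
    for name, D in (("tracks_fast_D0.10", 0.10), ("tracks_slow_D0.05", 0.05)):
        cfg = SimConfig(n_pairs=50, n_frames=500, D_free_ch1=D, D_free_ch2=D,
                        k_on=0.0, k_off=0.0, initial_state="free",
                        sigma_loc_ch1=20.0, sigma_loc_ch2=20.0, roi_size=50000.0,
                        seed=stage_seed(SEED, name))
        table = simulate_pair_tracks(cfg)
        dio.write_trajectories(table, OUT / f"{name}.csv")
        print(f"{name}: {len(table)} localizations, {len(table.tracks())} tracks")

    # dimerizing-pair movies at the two study off-rates
    for name, k_off in (("tracks_homo_koff0.18", 0.18), ("tracks_hetero_koff0.49", 0.49)):
        cfg = SimConfig(n_pairs=300, n_frames=1000, k_off=k_off, k_on=1.0,
                        initial_state="dimer", roi_size=62000.0,
                        seed=stage_seed(SEED, name))
        table = simulate_pair_tracks(cfg)
        dio.write_trajectories(table, OUT / f"{name}.csv")
        frac = (table.ground_truth["state"] == "dimer").mean()
        print(f"{name}: {len(table)} localizations, {frac:.1%} dimer frames")

    # membrane-sheet point patterns
    patterns = {
        "pattern_csr": PointPatternConfig(kind="csr", window=(1732.0, 1732.0),
                                          n1=300, n2=300),
        "pattern_clustered": PointPatternConfig(kind="clustered", window=(1732.0, 1732.0),
                                                parent_intensity=20.0, offspring_mean=5.0,
                                                cluster_sigma=20.0),
        "pattern_coclustered": PointPatternConfig(kind="coclustered",
                                                  window=(1732.0, 1732.0),
                                                  parent_intensity=20.0, offspring_mean=5.0,
                                                  cluster_sigma=20.0),
    }
    import dataclasses
    for name, cfg in patterns.items():
        cfg = dataclasses.replace(cfg, seed=stage_seed(SEED, name))
        pat = simulate_point_pattern(cfg)
        dio.write_point_pattern(pat, OUT / f"{name}.csv")
        print(f"{name}: {pat.n1} + {pat.n2} gold particles")


if __name__ == "__main__":
    main()
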
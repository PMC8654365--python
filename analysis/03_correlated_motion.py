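"""Two-color correlated motion versus pair separation.

For each dimerizing dataset, finds candidate cross-channel pairs and bins
the uncorrelated jump distance |dr1 - dr2| and the mean jump magnitude by
pair separation.  Bound pairs move together, so both statistics drop at
small separation — the correlated-motion signature of direct interaction.
"""

from pathlib import Path

import numpy as np

from dimertrack import io as dio
from dimertrack.pairs import correlated_jump_stats, find_candidate_pairs

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"
OUT = ROOT / "correlated_motion"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    edges = np.arange(0.0, 550.0, 50.0)
    for name in ("tracks_homo_koff0.18", "tracks_hetero_koff0.49"):
        table = dio.read_trajectories(DATA / f"{name}.csv")
        pairs = find_candidate_pairs(table.tracks(channel=1), table.tracks(channel=2),
                                     s_max=500.0, min_frames=3)
        res = correlated_jump_stats(pairs, edges)
        dio.write_correlated_motion(res, OUT / f"correlated_motion_{name}.csv")
        ok = np.flatnonzero(res.n_jumps > 0)
        lo, hi = ok[0], ok[-1]
        print(f"{name}: {len(pairs)} candidate pair series, "
              f"{res.n_jumps.sum()} jumps")
        print(f"  uncorrelated jump: {res.mean_uncorrelated_jump[lo]:.0f} nm "
              f"in the {res.separation_bin_centers[lo]:.0f} nm bin vs "
              f"{res.mean_uncorrelated_jump[hi]:.0f} nm at "
              f"{res.separation_bin_centers[hi]:.0f} nm "
              f"({'reduced at small separation' if res.mean_uncorrelated_jump[lo] < res.mean_uncorrelated_jump[hi] else 'no reduction'})")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
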
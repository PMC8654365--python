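"""Dimer kinetics: two-state HMM segmentation and off-rate estimation.

Fits the two-state hidden Markov model to the candidate-pair separation
series of each dimerizing dataset, segments dimer events with Viterbi, and
estimates the dissociation rate k_off (with pair-level bootstrap SE) and
the mean interaction lifetime 1/k_off.  Ground-truth rates are 0.18/s
(homo) and 0.49/s (hetero), mirroring lifetimes of ~5.5 s and ~2 s.
"""

from pathlib import Path

import numpy as np

from dimertrack import io as dio
from dimertrack._rng import stage_seed
from dimertrack.hmm import HMMParams, estimate_koff, fit_hmm, viterbi_segment
from dimertrack.pairs import find_candidate_pairs

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"
OUT = ROOT / "kinetics"
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, k_true in (("tracks_homo_koff0.18", 0.18), ("tracks_hetero_koff0.49", 0.49)):
        table = dio.read_trajectories(DATA / f"{name}.csv")
        pairs = find_candidate_pairs(table.tracks(channel=1), table.tracks(channel=2))
        fit = fit_hmm(pairs, HMMParams(s_max=500.0), seed=stage_seed(SEED, f"fit-{name}"))
        events = [viterbi_segment(p, fit.params, table.frame_rate) for p in pairs]
        dio.write_events(events, OUT / f"events_{name}.csv")
        est = estimate_koff(pairs, fit.params, table.frame_rate, n_boot=100,
                            seed=stage_seed(SEED, f"boot-{name}"))
        dio.write_koff(est, OUT / f"koff_{name}.json")
        dimer_events = [e for ev in events for e in ev.events if e.state == "dimer"]
        print(f"{name}: fitted p_off = {fit.params.p_off:.5f}, "
              f"sigma_d = {fit.params.sigma_d:.1f} nm")
        print(f"  k_off = {est.k_off:.3f} +/- {est.se:.3f} 1/s "
              f"(truth {k_true}), mean lifetime {est.mean_lifetime:.2f} s, "
              f"{len(dimer_events)} dimer events called over {est.n_pairs} pair series")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
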
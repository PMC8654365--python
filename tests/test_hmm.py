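"""Two-state HMM: emissions, forward/Viterbi oracles, fitting, off-rates."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad

from dimertrack.hmm import (HMMParams, emission_density, estimate_koff, fit_hmm,
                            forward_loglik, koff_from_p, total_loglik, viterbi_segment,
                            STATE_DIMER, STATE_FREE)
from dimertrack.pairs import PairSeries


def series_from_s(s, frames=None, pair_id=0) -> PairSeries:
    """PairSeries carrying a given separation sequence (dummy geometry)."""
    s = np.asarray(s, dtype=float)
    n = len(s)
    frames = np.arange(n) if frames is None else np.asarray(frames)
    xy1 = np.zeros((n, 2))
    xy2 = np.column_stack([-s, np.zeros(n)])
    return PairSeries(pair_id, frames, xy1, xy2)


def dense_emissions(s_dense, params):
    """Per-frame emission densities on a dense grid; None entries -> 1."""
    out = np.ones((len(s_dense), 2))
    for t, s in enumerate(s_dense):
        if s is not None:
            out[t, 0] = emission_density(s, STATE_FREE, params)
            out[t, 1] = emission_density(s, STATE_DIMER, params)
    return out


def exhaustive_forward(s_dense, params):
    """Brute-force sum over all 2^T state paths (T = dense length, gaps included)."""
    dens = dense_emissions(s_dense, params)
    P = params.transition_matrix
    pi = np.array([1 - params.pi_dimer, params.pi_dimer])
    T = len(s_dense)
    total = 0.0
    for path in itertools.product([0, 1], repeat=T):
        p = pi[path[0]] * dens[0, path[0]]
        for t in range(1, T):
            p *= P[path[t - 1], path[t]] * dens[t, path[t]]
        total += p
    return math.log(total)


def exhaustive_viterbi(s_dense, params):
    dens = dense_emissions(s_dense, params)
    P = params.transition_matrix
    pi = np.array([1 - params.pi_dimer, params.pi_dimer])
    best, best_p = None, -np.inf
    for path in itertools.product([0, 1], repeat=len(s_dense)):
        p = pi[path[0]] * dens[0, path[0]]
        for t in range(1, len(s_dense)):
            p *= P[path[t - 1], path[t]] * dens[t, path[t]]
        if p > best_p:
            best, best_p = path, p
    return best


def sample_hmm(params: HMMParams, n_series, T, rng) -> list[PairSeries]:
    """Sample directly from the HMM generative model (the estimator's model)."""
    out = []
    for i in range(n_series):
        states = np.empty(T, dtype=int)
        states[0] = rng.random() < params.pi_dimer
        for t in range(1, T):
            if states[t - 1] == 1:
                states[t] = 0 if rng.random() < params.p_off else 1
            else:
                states[t] = 1 if rng.random() < params.p_on else 0
        s = np.where(states == 1,
                     params.sigma_d * np.sqrt(-2 * np.log(rng.random(T))),
                     params.s_max * np.sqrt(rng.random(T)))
        out.append(series_from_s(s, pair_id=i))
    return out


class TestEmissionDensity:
    def test_dimer_density_plug_in_value(self):
        p = HMMParams(sigma_d=25.0)
        assert emission_density(25.0, STATE_DIMER, p) == \
            pytest.approx(math.exp(-0.5) / 25.0, rel=1e-12)

    def test_dimer_mode_at_sigma(self):
        p = HMMParams(sigma_d=30.0)
        s = np.linspace(1.0, 200.0, 4000)
        d = emission_density(s, STATE_DIMER, p)
        assert abs(s[np.argmax(d)] - 30.0) < 0.1

    @pytest.mark.parametrize("state", [STATE_FREE, STATE_DIMER])
    def test_densities_normalized(self, state):
        p = HMMParams(sigma_d=22.0, s_max=500.0)
        hi = p.s_max if state == STATE_FREE else np.inf
        val, err = quad(lambda s: emission_density(s, state, p), 0, hi)
        assert abs(val - 1.0) < 1e-9

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            emission_density(10.0, "bound", HMMParams())


class TestForward:
    def test_length_one_series(self):
        p = HMMParams(p_on=0.1, p_off=0.2, sigma_d=20.0, s_max=400.0, pi_dimer=0.3)
        s = 55.0
        expected = math.log(0.3 * emission_density(s, STATE_DIMER, p)
                            + 0.7 * emission_density(s, STATE_FREE, p))
        ps = PairSeries(0, np.array([5]), np.zeros((1, 2)),
                        np.array([[-s, 0.0]]))
        assert forward_loglik(ps, p) == pytest.approx(expected, abs=1e-12)

    def test_frozen_chain_sums_dimer_densities(self):
        p = HMMParams(p_on=0.0, p_off=0.0, sigma_d=25.0, pi_dimer=1.0)
        s = np.array([10.0, 30.0, 45.0])
        expected = sum(math.log(emission_density(v, STATE_DIMER, p)) for v in s)
        assert forward_loglik(series_from_s(s), p) == pytest.approx(expected, abs=1e-10)

    def test_matches_exhaustive_path_sum(self):
        """Forward log-likelihood equals the 2^T brute-force path sum
        (T <= 8, gaps included) on 100 random instances."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            T = rng.integers(2, 9)
            p = HMMParams(p_on=rng.uniform(0.01, 0.4), p_off=rng.uniform(0.01, 0.4),
                          sigma_d=rng.uniform(10, 60), s_max=500.0,
                          pi_dimer=rng.uniform(0.05, 0.95))
            s_dense = [float(rng.uniform(1, 480)) for _ in range(T)]
            # knock out up to two interior frames as gaps
            n_gaps = int(rng.integers(0, min(3, T - 2) + 1)) if T > 2 else 0
            gap_pos = rng.choice(np.arange(1, T - 1), size=n_gaps, replace=False) \
                if n_gaps else []
            for g in gap_pos:
                s_dense[g] = None
            frames = np.array([t for t in range(T) if s_dense[t] is not None])
            vals = np.array([v for v in s_dense if v is not None])
            got = forward_loglik(series_from_s(vals, frames=frames), p)
            assert abs(got - exhaustive_forward(s_dense, p)) < 1e-8

    def test_loglik_invariant_to_series_order(self):
        rng = np.random.default_rng(1)
        p = HMMParams(sigma_d=25.0)
        series = sample_hmm(p, 20, 50, rng)
        a = total_loglik(series, p)
        b = total_loglik(series[::-1], p)
        assert a == pytest.approx(b, rel=1e-12)

    def test_non_finite_separation_rejected(self):
        ps = series_from_s([10.0, np.nan, 20.0])
        with pytest.raises(ValueError):
            forward_loglik(ps, HMMParams())


class TestViterbi:
    def test_emission_dominance_all_dimer(self):
        p = HMMParams(p_on=0.05, p_off=0.05, sigma_d=25.0, s_max=500.0, pi_dimer=0.5)
        ev = viterbi_segment(series_from_s(np.full(40, 10.0)), p)
        assert len(ev.events) == 1
        assert ev.events[0].state == STATE_DIMER
        assert ev.events[0].n_frames == 40

    def test_matches_exhaustive_argmax(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            T = rng.integers(2, 9)
            p = HMMParams(p_on=rng.uniform(0.01, 0.4), p_off=rng.uniform(0.01, 0.4),
                          sigma_d=rng.uniform(10, 60), s_max=500.0,
                          pi_dimer=rng.uniform(0.05, 0.95))
            vals = rng.uniform(1, 480, size=T)
            ev = viterbi_segment(series_from_s(vals), p)
            path = np.empty(T, dtype=int)
            for e in ev.events:
                path[e.start_frame:e.end_frame + 1] = 1 if e.state == STATE_DIMER else 0
            expected = exhaustive_viterbi(list(vals), p)
            np.testing.assert_array_equal(path, expected)

    def test_block_boundaries_recovered(self):
        # alternating 50-frame near/far blocks with well-separated emissions
        rng = np.random.default_rng(3)
        p = HMMParams(p_on=0.05, p_off=0.05, sigma_d=25.0, s_max=500.0, pi_dimer=0.5)
        s = np.concatenate([
            25.0 * np.sqrt(-2 * np.log(rng.random(50))),
            rng.uniform(300, 480, 50),
            25.0 * np.sqrt(-2 * np.log(rng.random(50))),
            rng.uniform(300, 480, 50),
        ])
        ev = viterbi_segment(series_from_s(s), p)
        starts = sorted(e.start_frame for e in ev.events)
        assert len(ev.events) == 4
        for got, true in zip(starts, [0, 50, 100, 150]):
            assert abs(got - true) <= 2

    def test_events_tile_observed_frames(self):
        rng = np.random.default_rng(4)
        frames = np.sort(rng.choice(60, size=35, replace=False))
        vals = rng.uniform(1, 480, size=35)
        ev = viterbi_segment(series_from_s(vals, frames=frames), HMMParams())
        n_covered = sum(e.n_frames for e in ev.events)
        assert n_covered == 35

    def test_durations_in_seconds(self):
        ev = viterbi_segment(series_from_s(np.full(20, 10.0)), HMMParams(), frame_rate=20.0)
        assert ev.events[0].duration_s == pytest.approx(1.0)


class TestFitHMM:
    def test_recovers_generative_parameters(self):
        truth = HMMParams(p_on=0.02, p_off=0.01, sigma_d=25.0, s_max=500.0, pi_dimer=0.6)
        rng = np.random.default_rng(5)
        series = sample_hmm(truth, 200, 1000, rng)
        fit = fit_hmm(series, HMMParams(p_on=0.05, p_off=0.05, sigma_d=40.0,
                                        s_max=500.0, pi_dimer=0.5), seed=6)
        for name in ("p_on", "p_off", "sigma_d", "pi_dimer"):
            got, want = getattr(fit.params, name), getattr(truth, name)
            assert abs(got - want) / want < 0.15, f"{name}: {got} vs {want}"

    def test_no_dimer_evidence_drives_rates_to_bounds(self):
        rng = np.random.default_rng(7)
        series = [series_from_s(rng.uniform(400, 499, size=200), pair_id=i)
                  for i in range(30)]
        fit = fit_hmm(series, HMMParams(s_max=500.0), n_starts=2, seed=8)
        assert fit.params.p_on < 1e-3
        assert fit.params.pi_dimer < 0.01

    def test_refit_from_truth_is_stationary(self):
        truth = HMMParams(p_on=0.03, p_off=0.02, sigma_d=25.0, s_max=500.0, pi_dimer=0.5)
        rng = np.random.default_rng(9)
        series = sample_hmm(truth, 150, 600, rng)
        ll_truth = total_loglik(series, truth)
        fit = fit_hmm(series, truth, n_starts=1, seed=10)
        assert fit.log_likelihood >= ll_truth - 1e-6
        # MLE sits near the truth at this sample size; movement stays small
        for name in ("p_on", "p_off", "sigma_d", "pi_dimer"):
            got, want = getattr(fit.params, name), getattr(truth, name)
            assert abs(got - want) / want < 0.15

    def test_unknown_fixed_name_rejected(self):
        with pytest.raises(ValueError):
            fit_hmm([series_from_s([10, 20, 30])], HMMParams(), fixed=("sigma",))


class TestKoff:
    def test_closed_form_conversion(self):
        est_k = koff_from_p(0.0089598, 20.0)
        assert est_k == pytest.approx(0.1800, abs=2e-4)
        assert 1.0 / est_k == pytest.approx(5.56, abs=0.01)

    def test_zero_p_off_gives_zero_rate_infinite_lifetime(self):
        series = [series_from_s(np.full(10, 20.0))]
        p = HMMParams(p_off=0.0, sigma_d=25.0)
        est = estimate_koff(series, p, 20.0, n_boot=0)
        assert est.k_off == 0.0
        assert math.isinf(est.mean_lifetime)

    def test_p_off_one_rejected(self):
        with pytest.raises(ValueError):
            koff_from_p(1.0, 20.0)

    def test_recovery_median_error_and_bias_sign(self):
        """Across seeded replicates of the full generator + estimator, the
        median relative error of k_off stays below 10% at both study rates,
        and the bias keeps the same sign."""
        from dimertrack.pairs import pair_series_from_tracks
        from dimertrack.synthetic import SimConfig, simulate_pair_tracks

        biases = {}
        for k_true in (0.18, 0.49):
            errors = []
            for rep in range(10):
                cfg = SimConfig(n_pairs=150, n_frames=800, k_off=k_true, k_on=1.0,
                                initial_state="dimer", roi_size=45000.0,
                                seed=3000 + rep)
                table = simulate_pair_tracks(cfg)
                series = pair_series_from_tracks(table)
                fit = fit_hmm(series, HMMParams(s_max=500.0), n_starts=2, seed=rep)
                k_hat = koff_from_p(fit.params.p_off, 20.0)
                errors.append((k_hat - k_true) / k_true)
            errors = np.array(errors)
            assert np.median(np.abs(errors)) < 0.10, (k_true, errors)
            biases[k_true] = np.median(errors)
        assert np.sign(biases[0.18]) == np.sign(biases[0.49]) or \
            min(abs(b) for b in biases.values()) < 0.02

    def test_bootstrap_se_close_to_replicate_sd(self):
        """Pair-level bootstrap SE within a factor of 2 of the across-replicate
        SD of the estimator (HMM-generated data, emissions fixed on refit)."""
        truth = HMMParams(p_on=0.02, p_off=0.02, sigma_d=25.0, s_max=500.0, pi_dimer=0.5)
        ks = []
        rng = np.random.default_rng(11)
        first_series = None
        for rep in range(12):
            series = sample_hmm(truth, 80, 300, rng)
            if first_series is None:
                first_series = series
            fit = fit_hmm(series, truth, n_starts=1, seed=rep)
            ks.append(koff_from_p(fit.params.p_off, 20.0))
        sd = np.std(ks, ddof=1)
        fit0 = fit_hmm(first_series, truth, n_starts=1, seed=0)
        est = estimate_koff(first_series, fit0.params, 20.0, n_boot=60, seed=13)
        assert est.se is not None
        assert sd / 2 < est.se < sd * 2

    def test_viterbi_dwell_matches_rate(self, homo_koff_recovery):
        """Mean called dimer-event duration ~ 1/k_off for k_off*dt << 1."""
        cfg, table, fit, est = homo_koff_recovery
        from dimertrack.pairs import pair_series_from_tracks
        durations = []
        for ps in pair_series_from_tracks(table):
            ev = viterbi_segment(ps, fit.params, cfg.frame_rate)
            durations.extend(e.n_frames for e in ev.events if e.state == STATE_DIMER)
        mean_s = np.mean(durations) / cfg.frame_rate
        q = -math.expm1(-cfg.k_off / cfg.frame_rate)
        expected_s = 1.0 / (q * cfg.frame_rate)  # geometric dwell, ~1/k_off
        assert abs(mean_s - expected_s) / expected_s < 0.15
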
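# dimertrack

Quantitative single-particle-tracking and spatial-statistics pipeline for
membrane receptor interaction analysis — the kind of evidence used to show
that two receptor tyrosine kinases (e.g. EGFR and RON) meet, co-cluster and
transiently dimerize on the plasma membrane of live cells.

The package takes localization tables from two-color quantum-dot tracking
(or any upstream particle tracker) and two-species immunogold point
patterns from membrane-sheet TEM, and provides four analyses:

1. **Mobility (MSD / diffusion).** Time-lag-averaged mean squared
   displacement with overlapping windows; for 2-D Brownian motion
   MSD(Δt) = 4DΔt + 4σ², so D is slope/4 of an ordinary least-squares line
   through the first 5 MSD points (intercept absorbs the localization-noise
   offset 4σ²), with a 95% CI from the slope standard error. Per-cell D
   distributions are compared with a two-sided Wilcoxon rank-sum test.
2. **Correlated motion.** Candidate cross-channel pairs (separation below a
   500 nm gate for ≥ 3 co-observed frames) contribute per-frame jump pairs;
   the *uncorrelated jump distance* |Δr₁ − Δr₂| binned by pair separation
   drops toward the noise floor when two particles move as one complex,
   while independent movers satisfy E|Δr₁ − Δr₂|² = 4(D₁+D₂)Δt + 4(σ₁²+σ₂²).
3. **Dimer kinetics (two-state HMM).** A hidden Markov model over the pair
   separation series with states {free, dimer}: Rayleigh(σ_d) emissions in
   the dimer state, triangular-radial emissions 2s/s_max² in the free state,
   per-frame transition probabilities (p_on, p_off) fitted by maximum
   likelihood (multi-start L-BFGS on logit/log scales). Viterbi segmentation
   yields interaction events; the dissociation rate is
   k_off = −ln(1 − p_off)·(frame rate), mean lifetime 1/k_off, with a
   pair-level bootstrap SE.
4. **Co-clustering (bivariate Ripley's K).** K₁₂(r) with translational edge
   correction, L(r) − r = √(K₁₂/π) − r, and a pointwise 99% envelope from
   999 CSR simulations; co-clustering is called when the experimental curve
   exceeds the upper envelope at any radius up to the 50 nm critical
   interaction distance.

Because raw microscopy data for such experiments are rarely deposited, the
package ships a first-class synthetic generator: two-color Brownian pairs
with stochastic dimerization/dissociation, per-frame Gaussian localization
error and missed detections (20 frames/s, up to 1000 frames), and
membrane-sheet point patterns under CSR, independent Thomas clustering, or
shared-parent co-clustering. Every analysis is validated against this
ground truth and against independent oracles (exhaustive path enumeration
for the HMM, brute-force pair counting for Ripley, closed forms for jump
statistics).

## Worked example

```bash
python analysis/01_simulate_data.py
python analysis/04_dimer_kinetics.py
```

which prints (exact numbers for the seeds checked into the scripts):

```
tracks_homo_koff0.18: fitted p_off = 0.00861, sigma_d = 23.7 nm
  k_off = 0.173 +/- 0.008 1/s (truth 0.18), mean lifetime 5.78 s, 345 dimer events called over 3033 pair series
tracks_hetero_koff0.49: fitted p_off = 0.02463, sigma_d = 23.9 nm
  k_off = 0.499 +/- 0.031 1/s (truth 0.49), mean lifetime 2.01 s, 336 dimer events called over 3110 pair series
```

Read: from 300 simulated receptor pairs per condition (20 frames/s, 1000
frames) the full pipeline — candidate-pair search, HMM fit, rate
conversion — recovers the generator's dissociation rates of 0.18 s⁻¹ and
0.49 s⁻¹ within a few percent, i.e. mean interaction lifetimes of ~5.5 s
(stable homo-dimers) versus ~2 s (transient hetero-complexes). The fitted
emission scale σ_d ≈ 24 nm is the expected combination of the 15 nm per-
channel localization noise and the 15 nm physical label separation.

The other drivers cover mobility (`02`, recovering D = 0.100 and 0.050
µm²/s with rank-sum p ≈ 1.6e-4 between conditions), correlated motion
(`03`, uncorrelated jump ≈ 42 nm for bound pairs vs ≈ 166 nm for distant
ones), and Ripley co-clustering (`05`: shared-parent patterns significant
at every radius ≤ 50 nm, independently clustered patterns not). Note that
pointwise envelopes carry a ~5–10% per-pattern false-positive rate across
the tested radii — the checked-in CSR example happens to graze the
envelope at one radius, a useful reminder that single-sheet calls need the
replicate-level calibration quantified in the test suite.

There is also a CLI for file-based workflows:

```bash
dimertrack run --config run.yaml          # full spt or ripley workflow
dimertrack simulate-tracks --outdir out --seed 1
dimertrack msd out/tracks.csv --outdir out
```

## Layout

```
src/dimertrack/     library: synthetic, msd, pairs, hmm, ripley, io, pipeline, cli
analysis/           numbered narrative drivers writing under results/
tests/              pytest suite (unit, property and end-to-end acceptance tests)
scripts/acceptance.py
docs/methods.md     model assumptions, parameter choices, limitations
```
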
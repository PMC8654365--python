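# Methods

This note records the models behind each analysis stage, the parameter
choices where the design was genuinely open, and what the synthetic data do
and do not establish about real experiments. Units throughout: lengths nm,
diffusion coefficients µm²/s, rates s⁻¹, frames 0-based at the camera
interval Δt = 1/frame_rate.

## Trajectory simulation

The generator emulates two-color quantum-dot tracking of a membrane
receptor pair as a continuous-state, discrete-time process at the camera
interval (default 20 frames/s, movies up to 1000 frames, matching the
acquisition settings of the experiments the pipeline targets).

State dynamics per pair and frame step:

* **free** — both labels take independent Gaussian steps with per-axis
  variance 2·D_free·Δt. If the current separation is below the capture
  radius, the pair associates with probability 1 − exp(−k_on·Δt).
* **dimer** — a common center steps with per-axis variance 2·D_dimer·Δt;
  the two labels sit at fixed distance `dimer_separation` with orientation
  re-drawn every frame (fast-rotational-diffusion limit; no rotational
  model is specified by the experiments). Dissociation probability per
  frame is 1 − exp(−k_off·Δt).

Dwell times in each state are therefore geometric with the stated success
probabilities, so the embedded chain observed at Δt has exactly the
per-frame probabilities the HMM estimates, and k = −ln(1−p)/Δt inverts the
discretization without bias. Sub-frame transitions are not modeled; for
k·Δt ≤ 0.05 (covering 0.18 s⁻¹ and 0.49 s⁻¹ at 20 Hz) the induced bias is
below 1%.

Boundaries reflect at the edges of a square ROI. The default ROI is chosen
so that pair density stays at single-molecule levels (~0.08 pairs/µm²); a
log warning flags configurations where the diffusion span approaches the
ROI size. Observations add per-axis Gaussian localization noise (default
15 nm per channel, typical of quantum-dot SPT) and are dropped i.i.d. with
probability `p_miss`; blinking autocorrelation is deliberately out of
scope. The hidden state sequence is recorded per pair and frame.

Default kinetic parameters: k_off = 0.18 s⁻¹ (the stable homo-interaction
value; scripts override to 0.49 s⁻¹ for the transient hetero-interaction
condition), k_on = 1 s⁻¹ within a 150 nm capture radius. k_on and the
capture radius are nuisance parameters — association is not modeled by the
analyses, they only control how often the estimator sees rebinding.

## Point-pattern simulation

Membrane-sheet immunogold patterns come in three kinds: **csr** (each
species i.i.d. uniform with exactly the requested counts), **clustered**
(independent Thomas process per species) and **coclustered** (both species
scatter offspring around one shared Poisson parent set). Parents are drawn
in a window extended by 4·cluster_sigma so offspring intensity is unbiased
near edges; offspring falling outside the window are discarded, so realized
counts are random for the Thomas kinds and are reported in the output.
Defaults (20 parents/µm², 5 offspring per parent per species, 20 nm
scatter, ~1.7 µm window) give ~300 points per species — a plausible
labeling density for a membrane sheet at gold-particle resolution.

## MSD and diffusion

MSD uses overlapping windows: MSD(nΔt) averages |r(i+n) − r(i)|² over every
frame pair present, which maximizes jump counts and matches how ensemble
tracking figures report them; ensemble averaging is jump-weighted, not
track-weighted. Gaps contribute no pairs. D = slope/4 from an OLS fit with
intercept to the first 5 MSD points; the intercept absorbs the 4σ²
localization offset (fitting through the origin would bias D upward with
noisy data), and the 95% CI uses the slope SE with a t distribution on
n−2 df. Non-positive fitted D is reported and flagged, never clipped.
Group comparisons use the two-sided Wilcoxon rank-sum test because
per-cell D distributions are right-skewed.

## Correlated motion

The uncorrelated jump distance is defined as |Δr₁ − Δr₂| per one-frame
interval (the term is used in the tracking literature without an explicit
formula; this definition is fixed here). Intervals are binned by the
separation at the interval start — causally, only information available
before the jump. Defaults: 500 nm candidate gate, ≥ 3 co-observed frames,
50 nm bins over 0–500 nm; gaps of ≤ 3 frames are kept as missing inside a
series, longer gaps (or a co-observed frame outside the gate) split it.
For independent particles E|Δr₁ − Δr₂|² = 4(D₁+D₂)Δt + 4(σ₁²+σ₂²), which
the tests verify against the closed form.

## Two-state HMM and k_off

Observations are the per-frame pair separations of candidate series.
Emissions: dimer — Rayleigh with fitted scale σ_d (the radial density of a
2-D Gaussian offset; σ_d absorbs both the combined localization error
√(σ₁²+σ₂²) and the physical label separation); free — triangular-radial
2s/s_max² on (0, s_max], the distance density of a partner uniform in the
candidate disk, with s_max fixed to the candidate gate. Separations are
treated as conditionally independent given the states; the diffusive
autocorrelation of the relative position is a known approximation whose
cost shows up as a small (few percent) downward bias in k_off, inside the
15% recovery tolerance the tests enforce.

The forward recursion is scaled and vectorized across series; missing
frames apply the transition matrix with no emission factor (equal to the
g-step matrix power), gaps longer than 10 frames split a series.
(p_on, p_off, σ_d, π_dimer) are fitted by bounded L-BFGS on logit/log
scales with 5 seeded restarts; the fit is deterministic given data, init
and seed. Viterbi segmentation yields events; gap frames carry no state
and are excluded from durations.

k_off = −ln(1 − p_off)·frame_rate (exact for the embedded chain; the naive
p_off/Δt differs noticeably once p ≳ 0.02, i.e. for the faster rate). The
SE is the standard deviation of k_off over 200 (default) nonparametric
bootstrap resamples of pair series, refitting the transition probabilities
with emissions held fixed — resampling is implemented as multiplicity
weights on per-series log-likelihoods, so no data are copied.

## Bivariate Ripley's K

K₁₂(r) = (A/(n₁n₂))·Σᵢⱼ e_ij·1[d ≤ r] with translational edge-correction
weights e_ij = A/((W−|dx|)(H−|dy|)) (simple and unbiased for r well below
the window size; the source experiments do not name a correction). The
envelope simulates CSR with the same counts and window; bounds at each
radius are the α/2·(n+1)-th order statistics (5th/995th of 999 at
α = 0.01), requiring n_sims ≥ 2/α − 1. Envelopes are pointwise, matching
how such figures are drawn; the inflation of type-I error across radii is
real — with the default 5 nm grid up to 50 nm the per-pattern false-call
rate under CSR is ~5–10%, which the calibration tests measure — and the
co-clustering call therefore restricts attention to r ≤ 50 nm (the
critical interaction distance) and should be read at replicate level.
Pair counting is an O(n₁n₂) compiled kernel, verified exactly against a
brute-force double loop.

## Problem sizes and numerical choices

* Off-rate recovery runs at 300 pairs × 1000 frames per condition; a
  typical realization contains ~350–500 dissociation events, leaving ~5%
  Monte-Carlo error on k̂_off. The lifetime-consistency check averages
  three replicate runs per condition so that the comparison tests the
  estimator rather than a single draw.
* Diffusion recovery uses 200 tracks × 500 frames (≈ 10⁵ jumps per lag);
  correlated-motion closed forms use 10⁵ jumps; Ripley calibration and
  power use 50 patterns × 999-simulation envelopes at ~300 points per
  species.
* Scaled probabilities are floored at 1e-300; probabilities are bounded in
  [1e-5, 0.95] (transitions) and σ_d in [0.5, s_max] nm during fitting;
  ties in Viterbi resolve toward the free state via argmax order.
* All randomness flows from one root seed through named, CRC-keyed
  substreams, so adding a stage never perturbs earlier streams and reruns
  are byte-identical.

## What the synthetic data do not show

The generator omits quantum-dot blinking kinetics, spectral crosstalk and
channel misregistration, 3-D membrane topography, drift, and anomalous or
confined diffusion. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to those artifacts; on
real data the candidate gate, gap handling and emission scales would need
checking against the instrument's registration and blinking behavior.
k_on is density-dependent by construction and is never interpreted as a
biophysical association constant. A three-state model (adding a co-confined
state) is a documented non-goal; where receptors are co-confined without
binding, the two-state fit will fold some co-confinement into apparent
dimer dwell time.
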
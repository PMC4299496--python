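# Methods

## Model

Two noisy phase oscillators on the torus, the circadian phase θ and the
cell-cycle phase φ, each advancing with an intrinsic angular velocity
2π/T plus a phase-dependent coupling term and Brownian phase noise:

    dθ = (2π/T₁ + F₁(θ, φ)) dt + σ₁ dW,
    dφ = (2π/T₂ + F₂(θ, φ)) dt + σ₂ dY.

Conventions: θ = 0 at a reporter peak, φ = 0 at mitosis, both increasing
in time.  A disabled oscillator (division-free or clock-less fixture) is
encoded as an infinite period (zero drift) with zero diffusion.

Phase diffusion is the only stochasticity; amplitude effects enter only
through the measurement model (below).  F₁ and F₂ are signed mixtures of
two-dimensional Gaussian bumps with diagonal covariance.  Gaussians are
periodized by summing the 3×3 nearest periodic images of each center;
for the width bound used everywhere (s ≤ 1.5 rad), the first omitted
image contributes less than e^(−2π²/(2·1.5²)) ≈ 1.5 % of the center
value, and for the default widths (0.7 rad) it is ≈ 10⁻¹⁷.

## Events are first passages

A circadian peak is the first passage of the unwrapped θ through the
next multiple of 2π; a division likewise for φ (implemented as level
crossings of the running maximum, with linear interpolation between
samples).  This choice — rather than counting every up-crossing of the
diffusing phase — is what makes the uncoupled theory exact: intervals
between successive events of an uncoupled oscillator are
inverse-Gaussian with mean T and shape (2π/σ)², hence

    mean = T,    SD = σ · T^{3/2} / (2π).

These two relations are used throughout: to invert printed interval
statistics into fixture parameters, as the analytic oracle for the
simulator and for the particle-filter likelihood, and for
method-of-moments initialization of fits.

## Simulation

Euler–Maruyama with step dt = 0.02 h for data generation (drifts are
slow and smooth; halving dt changes interval means by < 0.05 h, and the
uncoupled interval distribution matches the inverse-Gaussian law to
Kolmogorov distance < 0.02 at 10⁴ samples).  Cohorts draw initial phases
uniformly and discard a 240-h burn-in so observation windows start at
the model's stationary joint phase distribution; uncoupled fixtures skip
the burn-in because uniform phases are already stationary for them.

Seeding: a master seed spawns one child stream per cell (NumPy
`SeedSequence`), and each cell's noise is drawn in fixed-length blocks,
so cohorts are bit-reproducible and independent of internal chunking and
of cohort size.

## Fixtures

The named fixtures encode the study conditions the pipeline is validated
against:

- `REF-FREE37`: division-free circadian cells, T₁ = 23.7 h, σ₁ inverted
  from an interval SD of 3.1 h (σ₁ ≈ 0.169 rad·h^(−1/2)).
- `REF-CC34` / `REF-CC40`: pure cell-cycle fixtures, T₂ = 24.5 / 18.1 h
  with σ₂ inverted from SDs of 4.4 / 3.5 h.
- `REF-NULL`: T₁ = 24, T₂ = 21.5, both couplings identically zero.
- `REF-REV`: clock → cell-cycle gating only: one negative F₂ bump
  (K = −2.5 rad/h) at (θ, φ) = (1.5, 5.5), widths (0.7, 0.7).
- `REF-A37`: unidirectional cell-cycle → clock coupling whose stable
  locked state places divisions 5 h (in noise-free dynamics) before the
  next reporter peak.

`REF-A37` deserves detail, because its design is constrained from three
sides at once: (i) its strength must be *tuned only against the
deterministic lead-time oracle* (1-D bisection on the bump weight until
the attractor's division-to-peak lead is 5.0 h); (ii) under the full
noise the simulated cohort must still show divisions ~5 h before peaks;
(iii) the 1:1 lock must be robust (stochastic winding ≈ 1).  A single
localized Gaussian bump cannot satisfy all three: the per-cycle period
mismatch (2π(1 − T₂/T₁) ≈ 0.66 rad) must be absorbed by the bump, so a
weak bump locks only marginally (division phases smear over hours),
while a strong bump overshoots — once noise pushes a trajectory into the
high-gain region it is thrown a large fraction of a cycle forward, and
the population ratchets through extra circadian cycles (stochastic
winding down to 0.87).  The adopted F₁ therefore has the two-bump
structure the model family defaults to: a tuned accelerating bump at
(θ, φ) = (3.0, 0.4), widths (0.7, 0.7) — just past the circadian trough,
acting around mitosis — plus a fixed weaker slowdown (K = −1.5 rad/h) at
(5.9, 4.2), widths (0.45, 0.5), which holds early-running clocks just
below the peak until shortly before division.  With the tuned strength
(K ≈ 1.90 rad/h) the noise-free system has exactly one attractor
(lead 5.00 h, map slope 0.29) and one repeller, and stochastic cohorts
show mean adjacent division-to-peak intervals of 4.8–5.3 h with
stochastic winding within ~5 % of 1.

## Synthetic recordings

Reporter: y(t) = b + A(t)·(1 + cos θ)/2 + ε with b = 50, A(t) an
Ornstein–Uhlenbeck process (mean 100, reversion 0.1 h⁻¹, stationary SD
20) sampled with its exact one-step kernel, and i.i.d. Gaussian
observation noise σ_obs = 5 (5 % of the mean amplitude).  Each division
multiplies the 1–2 samples nearest the division time by (1 − δ),
δ = 0.6 — the short nuclear-envelope-breakdown dip.  Nuclear size:
s(t) = s₀·(1 + φ_within/2π) + noise, a ramp that doubles over each cycle
and halves at division; the within-cycle phase is measured against the
first-passage cycle count so resets coincide exactly with ground-truth
events.  Sampling: 0 to 72 h, step 0.5 h (145 samples).

What the generator does *not* emulate: lineage structure (each trace is
one tracked nucleus), photobleaching and segmentation artifacts,
cell-to-cell parameter heterogeneity, and amplitude–phase interaction.
Benchmarks against this generator therefore measure algorithmic
correctness under the model's own assumptions, not robustness to
everything real microscopy produces.

## Event detection

Peaks: 2.5-h moving-average smoothing, local maxima with ≥ 12 h
separation and prominence ≥ 20 % of the trace IQR, 3-point parabolic
refinement, no reports within half a smoothing window of the ends.
Divisions: a sample dipping below 70 % of the smaller neighboring level
(levels measured above the trace's 5th percentile, so detection is
invariant under affine rescaling) that recovers within two samples, with
a depth guard of 0.35·IQR against pure-noise excursions; candidate dips
closer than 10 h keep only the deepest — mammalian cell cycles are far
longer, so closer pairs cannot both be divisions.

A caveat discovered by benchmarking against generator truth: under phase
diffusion the rendered signal maximum is displaced from the first-passage
peak time by ~1.3 h SD (the apparent maximum rides local phase
excursions).  Detection therefore recovers essentially every true peak,
with a median timing offset < 1 h but a heavy tail that no detector can
remove; interval *statistics* (means over many intervals) still agree
with ground truth to < 0.3 h.

## Instantaneous phase (HMM)

Hidden state: (phase bin, amplitude bin) on a 48 × 15 product grid
(amplitude bins geometric over [A₀/4, 4A₀]).  Phase transition: wrapped
Gaussian with drift 2π·dt/T and variance σ²·dt; amplitude transition:
exact Ornstein–Uhlenbeck one-step kernel between bin centers, weighted
by bin width; emission: Gaussian around b + A(1 + cos θ)/2.  The decoder
is exact Viterbi over the product chain (the two transition factors are
applied sequentially, so each step costs 48²·15 + 15²·48 operations).
Decoded phase is unwrapped by accumulating minimal signed bin
differences, ties broken toward the drift.  Emissions within ±1 sample
of known/detected divisions are masked (uninformative) so dips do not
corrupt the phase.

Known behavior: on noise-free input the decoded velocity is exact to one
bin width per step; on noisy rendered traces the decoded rotation rate
carries a small slow bias (~0.1–0.3 h in period terms) from the
amplitude–phase ambiguity near waveform extrema, and phase-binned
velocity profiles show small systematic wiggles near θ = 0 where the
emission gradient vanishes.  Velocity profiles are therefore always
*centered* on the division-free cohort's profile, as the analysis
requires; the centered profiles recover the sign and phase range of an
injected coupling.

## Likelihood

The probability of one cell's ordered event sequence factorizes into
causally independent terms: P(next observed event has the observed type
and falls in its 0.5-h bin | history).  Each factor is estimated with an
ensemble of hidden-phase particles:

1. At the first event the observed phase is pinned exactly (θ = 0 at a
   peak, φ = 0 at a division) and the companion phase is drawn from the
   model's stationary conditional, estimated from a 96-h pre-simulation
   of 2,048 particles (window ±0.3 rad around the pinned phase, widened
   until ≥ 20 samples match).
2. Particles are propagated by Euler–Maruyama (default step 0.1 h);
   each particle records the first subsequent event (type and bin) it
   produces, with the same first-passage semantics as the simulator.
3. The factor is the matching particle fraction, floored at
   1/(10·N) so isolated zero counts penalize rather than annihilate the
   likelihood; the ensemble is then resampled among matching particles
   (if none match, the observed coordinate is re-pinned at its nearest
   level).  A terminal factor scores "no further event before the
   window end".

Numerical choices: event times are binned at the imaging cadence
(0.5 h), so likelihood granularity matches observability; the particle
drift uses the coupling fields tabulated on a 128×128 torus grid with
bilinear interpolation (interpolation error is quadratic in the grid
step and far below the Monte-Carlo noise of the factor estimates);
common random numbers make the likelihood a deterministic function of
(parameters, data, seed), with per-trace streams keyed by cell id so a
trace's log-likelihood is independent of its cohort.  On uncoupled
division-free data the per-factor probabilities match the analytic
inverse-Gaussian bin masses within Monte-Carlo error, and maximizing the
particle likelihood reproduces the closed-form inverse-Gaussian MLE.

## Fitting

CMA-ES (rank-μ update, cumulative step-size adaptation) over an
unconstrained coordinate system: logistic maps onto box bounds for
periods [12, 48] h, diffusions [0.02, 0.8], widths [0.2, 1.5] rad and
weights [−12, 12] rad/h (weight zero at coordinate zero); bump centers
live on the torus.  Every candidate in a generation is evaluated with
one generation seed (common random numbers), refreshed across
generations so the optimizer cannot adapt to one noise draw; the final
answer is the better of the last generation's best and the distribution
mean under a fixed evaluation seed.  Fits start from method-of-moments
estimates (periods and diffusions from interval means/SDs, couplings at
zero).

Coupling directionality is decided by comparing three nested models fit
to the same data with common random numbers — uncoupled, F₁-only, and
F₂-only — under a BIC penalty (parameters × ln of the number of scored
event factors); the coupled fits start from the uncoupled fit's periods
and noise.  This is markedly more robust at small sample sizes than
reading the direction off one unconstrained fit, where coupling terms
can partially absorb period misfit along a likelihood ridge.  That ridge
is also why intrinsic-period recovery degrades for strongly coupled
data at small cohort sizes: the locked cohort mostly exposes the common
locked period, and T₁ of the driven oscillator is only weakly
identified until cohorts are large.

## Synchronization and causality

Order parameters are the standard population phasor moduli
R = |N⁻¹ Σ e^{iθ}| (0 for uniform phases, 1 for identical), with the
1:1 relative-phase variant on θ − φ, bootstrap SDs over cells, and
reset-style cohorts supported by equalizing initial phases.  Granger
direction calls: both series linearly detrended and standardized, a
bivariate VAR with AIC-selected order (1..8 lags, i.e. up to 4 h), Wald
tests on the joint nullity of the cross-lag coefficients in each
direction, calls at p < 0.001 (or a stronger-direction variant comparing
the two p-values).  On independent noise the empirical call rate matches
the nominal level; calls are invariant under affine rescaling of either
series.

## Problem sizes used by the test-suite

The suite validates every statistical claim at sizes chosen to keep the
default run a few minutes on one CPU while leaving comfortable margins
on each assertion: interval oracles on 40–150 cells with long (300–600 h)
windows where censoring is negligible; acceptance-condition cohorts at
their stated sizes (2,000–3,000 cells × 72 h); identifiability at
32-trace cohorts with 40 particles (uncoupled fit, a global grid scan
over single-bump placements, and two refined coupled fits per study;
five seeded replicates per scenario); Granger calibration at 700
independent pairs.

## Known limitations

- **Window censoring.**  Complete intervals inside a finite window are a
  biased-short sample of the interval distribution (long intervals are
  preferentially truncated).  At 72 h this bias is ≈ −0.2 h for ~24-h
  intervals and ≈ −0.3 to −0.4 h for the broader cell-cycle fixtures —
  of the same order as the tightest tolerances quoted for interval
  means, so window-censored means sit slightly below the generator's
  intrinsic values by construction.  Survival-style corrections are out
  of scope.
- **No lineage branching**: a division continues a single tracked
  trajectory; sister cells are not spawned.
- **Viterbi point estimates**: the decoder returns the jointly most
  probable path, not posterior marginals; decoded velocities are mildly
  shrunk toward the prior drift.
- **Desk-scale identifiability**: direction calls are reliable at the
  tested sizes, but full parameter recovery (especially the driven
  oscillator's intrinsic period under strong coupling) requires larger
  cohorts than the test-suite exercises.
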
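# cellclock

Quantitative analysis of coupled circadian and cell-cycle oscillators in
single cells.

In proliferating mammalian cells two ~24-h rhythms run side by side: the
circadian clock (read out by a fluorescent reporter of clock gene
expression) and the cell division cycle.  When two such cycles interact
they can synchronize — mode-lock — so that divisions occur at a stereotyped
circadian phase.  `cellclock` implements, as a tested reusable pipeline,
the stochastic-modeling side of that question: which cycle drives which,
and how strongly?

It is aimed at people analyzing single-cell time-lapse recordings (a
reporter intensity and a nuclear-size proxy per tracked nucleus, sampled
every 30 min for ~72 h) or building synthetic benchmarks for such
analyses.

## The model

Both cycles are noisy phase oscillators on the torus: the circadian phase
θ (θ = 0 at a reporter peak) and the cell-cycle phase φ (φ = 0 at
mitosis):

    dθ = ( 2π/T₁ + F₁(θ, φ) ) dt + σ₁ dW_t
    dφ = ( 2π/T₂ + F₂(θ, φ) ) dt + σ₂ dY_t

with intrinsic periods T₁, T₂, phase-diffusion coefficients σ₁, σ₂, and
independent Wiener processes W, Y.  F₁ is the influence of the cell cycle
on the clock (positive values accelerate the circadian phase), F₂ the
reverse influence.  Each coupling function is a signed mixture of
two-dimensional Gaussian bumps with diagonal covariance, periodized on
the torus.

On top of this core the package provides:

- **Simulation** — Euler–Maruyama cohorts with reproducible per-cell
  seeding; events (circadian peaks `p`, divisions `d`) as first passages
  of the unwrapped phases (`cellclock.simulate`).
- **Noise-free skeleton** — Poincaré return map on the mitosis section,
  mode-locked states (attractor/repeller, division-to-peak lead time),
  winding numbers (`cellclock.model`).
- **Synthetic recordings** — raised-cosine reporter traces with an
  Ornstein–Uhlenbeck amplitude, 30–60-min division dips, a nuclear-size
  ramp, and named study-condition fixtures (`cellclock.synth`).
- **Event detection** — peak and division-dip detection on sampled traces
  (`cellclock.detect`).
- **Instantaneous phase** — Viterbi decoding of a phase–amplitude hidden
  Markov model and phase-velocity profiles (`cellclock.hmm`).
- **Interval statistics** — typed interval tables (p,p), (p,d,p), (d,p),
  division phases, group comparisons, Q10, successive-interval
  correlations (`cellclock.intervals`).
- **Inference** — sequential Monte-Carlo likelihood of event sequences,
  CMA-ES maximization, joint multi-condition fits, multistart analyses,
  period rescaling, identifiability studies with nested-model direction
  calls (`cellclock.likelihood`, `cellclock.fitting`).
- **Synchronization & causality** — Kuramoto-style order parameters over
  time and per-cell Granger-causality direction calls
  (`cellclock.syncstats`).
- **CLI** — `cellclock synth|detect|hmm|intervals|fit|fit-joint|
  multistart|sync|granger|identifiability` (`cellclock.cli`).

## Worked example

The reference fixture `REF-A37` is a unidirectionally coupled model
(cell cycle → clock) whose coupling strength is tuned, by bisection on
the noise-free dynamics only, so that the stable locked state places
divisions 5 h before the next reporter peak:

```python
from cellclock.synth import make_fixture
from cellclock.model import find_locked_states, winding_number
from cellclock.simulate import simulate_cohort
from cellclock.intervals import build_intervals, summarize_intervals

params, render = make_fixture("REF-A37")
for s in find_locked_states(params):
    kind = "attractor" if s.stable else "repeller"
    print(f"{kind}: theta* = {s.theta_star:.3f} rad, "
          f"lead time = {s.lead_time:.2f} h, slope = {s.map_slope:.2f}")
print(f"winding number: {winding_number(params, 100):.3f}")

events = simulate_cohort(params, 500, duration=72.0, seed=7)
table = build_intervals(events)
for kind, label in [("pp", "division-free circadian"),
                    ("pdp", "single-division circadian"),
                    ("dd_any", "cell cycle"),
                    ("dp", "division to next peak")]:
    s = summarize_intervals(table, kind)
    print(f"{label:28s} n={s.n:5d} mean={s.mean:6.2f} h  sd={s.sd:5.2f} h")
```

prints

```
repeller: theta* = 1.344 rad, lead time = 9.96 h, slope = 547.40
attractor: theta* = 4.944 rad, lead time = 5.00 h, slope = 0.29
winding number: 1.000
division-free circadian      n=   79 mean= 22.25 h  sd= 3.17 h
single-division circadian    n=  939 mean= 21.27 h  sd= 3.52 h
cell cycle                   n= 1177 mean= 21.27 h  sd= 3.88 h
division to next peak        n= 1405 mean=  4.88 h  sd= 3.61 h
```

Reading this: the noise-free system is 1:1 mode-locked (winding number
1.000) with an attracting section phase θ\* = 4.94 rad, i.e. divisions
lead the next circadian peak by 5.00 h.  In the stochastic cohort the
mean division-to-next-peak interval stays near 5 h, circadian intervals
containing a division are shorter than division-free ones (the
accelerating coupling at work), and cell-cycle durations track the
intrinsic 21.5-h period.

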
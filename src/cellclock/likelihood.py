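"""Monte-Carlo likelihood of event sequences under the coupled phase model.

The probability of one cell's ordered peak/division sequence factorizes
into causally independent terms: given the history up to an event, the
next observed event must be of the observed type and fall in its 0.5-h
time bin.  Each factor is estimated by an ensemble of hidden-phase
particles propagated with the stochastic dynamics; after each observed
event the ensemble is conditioned (resampled) on the outcome, and a
terminal factor scores the absence of further events before the window
end.  At the first event the observed phase is pinned exactly (theta = 0
at a peak, phi = 0 at a division) and the companion phase is drawn from
the model's stationary conditional distribution, estimated from a
pre-simulated ensemble.

Common random numbers: all noise and resampling variates derive from the
``seed`` argument only, so the likelihood is a deterministic function of
(params, data, seed) — which tames the Monte-Carlo noise seen by the
optimizer.  Per-trace noise streams derive from the trace's cell id, so a
trace's log-likelihood does not depend on which other traces are present.
"""

from __future__ import annotations

import hashlib
import math
from collections import OrderedDict
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .model import ModelParams
from .simulate import EventSequence
from . import _kernels

TWO_PI = 2.0 * math.pi

__all__ = ["FitConfig", "trace_loglik", "dataset_loglik", "DegeneracyError"]


class DegeneracyError(RuntimeError):
    """All particles lost under repeated conditioning; raise n_particles."""


@dataclass(frozen=True)
class FitConfig:
    """Likelihood and optimizer settings.

    ``delta`` must match the sampling cadence of the data (event times are
    discretized to this bin width).  ``sim_dt`` is the internal
    Euler–Maruyama step of the particle propagation; ``pre_burn`` hours of
    pre-simulation estimate the stationary phase distribution used to
    initialize the hidden phase at the first event.
    """

    n_particles: int = 2000
    delta: float = 0.5                  # event-time bin width [h]
    sim_dt: float = 0.1                 # particle propagation step [h]
    pre_burn: float = 96.0              # stationary pre-simulation [h]
    pre_particles: int = 2048
    cond_window: float = 0.3            # rad; conditional-init phase window
    table_n: int = 128                  # coupling-field grid (bilinear lookup)
    floor_factor: float = 10.0          # factor floor = 1/(floor_factor * N)
    # optimizer
    popsize: int = 16
    max_gens: int = 300
    sigma0: float = 0.3
    seed: int = 0
    n_bumps: tuple[int, int] = (2, 2)   # bumps per coupling function in fits
    # parameter box bounds (transformed coordinates are unbounded)
    period_bounds: tuple[float, float] = (12.0, 48.0)
    sigma_bounds: tuple[float, float] = (0.02, 0.8)
    width_bounds: tuple[float, float] = (0.2, 1.5)
    weight_bound: float = 12.0
    free: tuple[str, ...] = ("T1", "T2", "sigma1", "sigma2", "F1", "F2")

    def __post_init__(self):
        if self.sim_dt <= 0 or self.delta <= 0:
            raise ValueError("delta and sim_dt must be positive")
        n_sub = self.delta / self.sim_dt
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError("delta must be an integer multiple of sim_dt")

    @property
    def n_sub(self) -> int:
        return int(round(self.delta / self.sim_dt))

    @property
    def floor(self) -> float:
        return 1.0 / (self.floor_factor * self.n_particles)


@njit(cache=True, fastmath=True)
def _particle_factors(th, ph, ev_bin, ev_type, n_ev, first_bin, n_bins,
                      n_sub, dt, noise_t, noise_p, resamp_u, floor,
                      om1, om2, s1, s2, tab1, tab2):
    """Particle-filter factors for one trace.

    th/ph: (N,) initial particle phases (unwrapped) at the right edge of
    ``first_bin`` (or at t=0 when the trace has no events, first_bin=-1).
    noise_*: (n_bins*n_sub, N) standard normals indexed by absolute step.
    resamp_u: (n_ev+1, N) uniforms for conditioning resamples.
    Returns (factors, zero_flags): probability per factor (index e scores
    observed event e >= 1; index n_ev the terminal survival factor).
    """
    N = th.size
    sqdt = math.sqrt(dt)
    factors = np.ones(n_ev + 1)
    zeros = np.zeros(n_ev + 1, dtype=np.bool_)
    rec_type = np.full(N, -1, dtype=np.int8)
    rec_bin = np.full(N, -1, dtype=np.int32)
    thr_t = np.empty(N)
    thr_p = np.empty(N)
    for j in range(N):
        thr_t[j] = TWO_PI * (math.floor(th[j] / TWO_PI + 1e-12) + 1.0)
        thr_p[j] = TWO_PI * (math.floor(ph[j] / TWO_PI + 1e-12) + 1.0)
    matches = np.empty(N, dtype=np.int32)
    new_th = np.empty(N)
    new_ph = np.empty(N)

    cur_bin = first_bin
    e0 = 1 if n_ev > 0 else 0
    for e in range(e0, n_ev + 1):
        if e < n_ev:
            target_bin = ev_bin[e]
            target_type = ev_type[e]
        else:
            target_bin = n_bins - 1
            target_type = -1  # terminal survival: no event at all
        # propagate from right edge of cur_bin to right edge of target_bin
        step0 = (cur_bin + 1) * n_sub
        step1 = (target_bin + 1) * n_sub
        for k in range(step0, step1):
            b = k // n_sub  # crossing during step k lands in bin b
            for j in range(N):
                d1 = om1 + _kernels.table_lookup(th[j], ph[j], tab1)
                d2 = om2 + _kernels.table_lookup(th[j], ph[j], tab2)
                th[j] = th[j] + d1 * dt + s1 * sqdt * noise_t[k, j]
                ph[j] = ph[j] + d2 * dt + s2 * sqdt * noise_p[k, j]
                if rec_type[j] < 0:
                    if th[j] >= thr_t[j]:
                        rec_type[j] = 0
                        rec_bin[j] = b
                    elif ph[j] >= thr_p[j]:
                        rec_type[j] = 1
                        rec_bin[j] = b
        # score the factor
        n_match = 0
        if e < n_ev:
            for j in range(N):
                if rec_type[j] == target_type and rec_bin[j] == target_bin:
                    matches[n_match] = j
                    n_match += 1
        else:
            for j in range(N):
                if rec_type[j] < 0:
                    matches[n_match] = j
                    n_match += 1
        p_hat = n_match / N
        if p_hat < floor:
            p_hat = floor
            if n_match == 0:
                zeros[e] = True
        factors[e] = p_hat
        if e == n_ev:
            break
        # condition the ensemble on the observed outcome
        if n_match > 0:
            for j in range(N):
                u = resamp_u[e, j]
                idx = matches[min(int(u * n_match), n_match - 1)]
                new_th[j] = th[idx]
                new_ph[j] = ph[idx]
            for j in range(N):
                th[j] = new_th[j]
                ph[j] = new_ph[j]
        else:
            # degenerate: re-pin the observed coordinate at its nearest level
            for j in range(N):
                if target_type == 0:
                    th[j] = TWO_PI * round(th[j] / TWO_PI)
                else:
                    ph[j] = TWO_PI * round(ph[j] / TWO_PI)
        for j in range(N):
            thr_t[j] = TWO_PI * (math.floor(th[j] / TWO_PI + 1e-12) + 1.0)
            thr_p[j] = TWO_PI * (math.floor(ph[j] / TWO_PI + 1e-12) + 1.0)
            rec_type[j] = -1
            rec_bin[j] = -1
        cur_bin = target_bin
    return factors, zeros


def _trace_entropy(seed: int, cell_id: str) -> np.random.SeedSequence:
    h = hashlib.sha256(cell_id.encode()).digest()[:8]
    return np.random.SeedSequence([int(seed), int.from_bytes(h, "little")])


#: small caches for the random variates, keyed by seed and shapes; with
#: common random numbers a whole optimizer generation shares one bank
_PRESIM_CACHE: "OrderedDict" = OrderedDict()
_BANK_CACHE: "OrderedDict" = OrderedDict()
_CACHE_SIZE = 3


def _presim_draws(config: FitConfig, seed: int):
    M = config.pre_particles
    n_steps = int(round(config.pre_burn / config.sim_dt))
    key = (int(seed), M, n_steps)
    if key not in _PRESIM_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x57A7]))
        _PRESIM_CACHE[key] = (rng.uniform(0.0, TWO_PI, M),
                              rng.uniform(0.0, TWO_PI, M),
                              rng.standard_normal((n_steps, M)),
                              rng.standard_normal((n_steps, M)))
        while len(_PRESIM_CACHE) > _CACHE_SIZE:
            _PRESIM_CACHE.popitem(last=False)
    return _PRESIM_CACHE[key]


def _coupling_tables(params: ModelParams, n: int):
    """Coupling fields sampled on an n x n torus grid for bilinear lookup.

    The particle filter's drift uses these tables; the interpolation error
    (~(grid step)^2 curvature) is far below the Monte-Carlo noise of the
    factor estimates for widths within the fit bounds."""
    from .model import eval_coupling

    g = np.arange(n) * (TWO_PI / n)
    th, ph = np.meshgrid(g, g, indexing="ij")
    t1 = np.ascontiguousarray(np.atleast_2d(eval_coupling(params.F1, th, ph)))
    t2 = np.ascontiguousarray(np.atleast_2d(eval_coupling(params.F2, th, ph)))
    if t1.shape != (n, n):
        t1 = np.zeros((n, n)) + t1
    if t2.shape != (n, n):
        t2 = np.zeros((n, n)) + t2
    return t1, t2


def _stationary_cloud(params: ModelParams, config: FitConfig, seed: int,
                      tables=None):
    """Wrapped (theta, phi) ensemble after a pre-burn run from uniform phases."""
    th0, ph0, zt, zp = _presim_draws(config, seed)
    tab1, tab2 = tables if tables is not None else _coupling_tables(
        params, config.table_n)
    th, ph = _kernels.em_paths_tab(th0, ph0, zt, zp, config.sim_dt,
                                   math.sqrt(config.sim_dt),
                                   params.omega1, params.omega2,
                                   params.sigma1, params.sigma2, tab1, tab2)
    return th % TWO_PI, ph % TWO_PI


def _dataset_bank(dataset, config: FitConfig, seed: int):
    """Per-trace random variates (init uniforms, noise, resample uniforms).

    Deterministic per (seed, cell_id, shapes) and independent of model
    parameters, so a CMA generation evaluating many parameter vectors with
    one seed reuses a single bank.
    """
    key = (int(seed), config.n_particles, config.n_sub,
           tuple((ev.cell_id, len(ev.events), ev.t_start, ev.t_end)
                 for ev in dataset))
    if key not in _BANK_CACHE:
        N = config.n_particles
        bank = []
        for ev in dataset:
            n_bins = int(round((ev.t_end - ev.t_start) / config.delta))
            n_steps = n_bins * config.n_sub
            rng = np.random.default_rng(_trace_entropy(seed, ev.cell_id))
            bank.append((rng.random(N),
                         rng.standard_normal((n_steps, N)),
                         rng.standard_normal((n_steps, N)),
                         rng.random((len(ev.events) + 1, N))))
        _BANK_CACHE[key] = bank
        while len(_BANK_CACHE) > _CACHE_SIZE:
            _BANK_CACHE.popitem(last=False)
    return _BANK_CACHE[key]


def _conditional_init(cloud, pinned: str, config: FitConfig,
                      u: np.ndarray):
    """Companion phases from the stationary conditional at the pinned event.

    ``u`` are pre-drawn uniforms, so the same bank serves every parameter
    vector (common random numbers)."""
    th_c, ph_c = cloud
    obs, comp = (th_c, ph_c) if pinned == "p" else (ph_c, th_c)
    w = config.cond_window
    dist = np.abs((obs + math.pi) % TWO_PI - math.pi)
    sel = np.nonzero(dist < w)[0]
    while len(sel) < 20 and w < math.pi:
        w *= 2.0
        sel = np.nonzero(dist < w)[0]
    if len(sel) == 0:
        sel = np.arange(len(obs))
    picks = comp[sel[np.minimum((u * len(sel)).astype(np.int64),
                                len(sel) - 1)]]
    zero = np.zeros(len(u))
    return (zero, picks) if pinned == "p" else (picks, zero)


def _events_to_bins(ev: EventSequence, delta: float, n_bins: int):
    bins = []
    types = []
    for t, k in ev.events:
        b = min(int((t - ev.t_start) / delta), n_bins - 1)
        bins.append(b)
        types.append(0 if k == "p" else 1)
    return np.asarray(bins, dtype=np.int64), np.asarray(types, dtype=np.int64)


def dataset_loglik(params: ModelParams, dataset: list[EventSequence],
                   config: FitConfig | None = None, seed: int = 0,
                   return_factors: bool = False, strict: bool = False):
    """Total and per-trace log-likelihood of a set of event sequences.

    Deterministic in (params, dataset, seed).  With ``return_factors``,
    also returns the per-factor probabilities per trace (index 0 is the
    unscored pinning factor; the last entry the terminal survival factor).
    With ``strict``, a trace whose ensemble collapses repeatedly raises
    :class:`DegeneracyError`; otherwise the floored factors stand (a very
    low likelihood), which is what an optimizer should see.
    """
    config = config or FitConfig()
    if not dataset:
        raise ValueError("empty dataset")
    tab1, tab2 = _coupling_tables(params, config.table_n)
    cloud = _stationary_cloud(params, config, seed, tables=(tab1, tab2))
    bank = _dataset_bank(dataset, config, seed)
    delta, n_sub, dt = config.delta, config.n_sub, config.sim_dt
    N = config.n_particles
    per_trace = np.empty(len(dataset))
    all_factors = []
    for i, ev in enumerate(dataset):
        t_span = ev.t_end - ev.t_start
        n_bins = int(round(t_span / delta))
        u_init, zt, zp, ru = bank[i]
        bins, types = _events_to_bins(ev, delta, n_bins)
        n_ev = len(bins)
        if n_ev > 0:
            first_bin = int(bins[0])
            pinned = "p" if types[0] == 0 else "d"
            th0, ph0 = _conditional_init(cloud, pinned, config, u_init)
        else:
            first_bin = -1
            idx = np.minimum((u_init * len(cloud[0])).astype(np.int64),
                             len(cloud[0]) - 1)
            th0, ph0 = cloud[0][idx].copy(), cloud[1][idx].copy()
        factors, zeros = _particle_factors(
            th0.astype(float).copy(), ph0.astype(float).copy(),
            bins, types, n_ev, first_bin, n_bins, n_sub, dt, zt, zp, ru,
            config.floor, params.omega1, params.omega2,
            params.sigma1, params.sigma2, tab1, tab2)
        if strict and zeros.sum() > max(2, n_ev // 2):
            raise DegeneracyError(
                f"trace {ev.cell_id}: ensemble degenerate at "
                f"{int(zeros.sum())}/{n_ev + 1} factors; increase n_particles")
        per_trace[i] = float(np.log(factors).sum())
        if return_factors:
            all_factors.append(factors)
    total = float(per_trace.sum())
    if return_factors:
        return total, per_trace, all_factors
    return total, per_trace


def trace_loglik(params: ModelParams, events: EventSequence,
                 config: FitConfig | None = None, seed: int = 0,
                 strict: bool = True) -> float:
    """Log-likelihood of a single trace (sum of log conditional factors).

    Raises :class:`DegeneracyError` if the particle ensemble collapses at
    most of the conditioning steps (suggesting more particles).
    """
    total, _ = dataset_loglik(params, [events], config=config, seed=seed,
                              strict=strict)
    return total
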
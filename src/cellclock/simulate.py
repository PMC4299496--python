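"""Stochastic integration of the coupled phase model and event extraction.

Paths are integrated by Euler–Maruyama on the unwrapped phases; circadian
peaks and divisions are the first-passage times of the respective phase
through successive multiples of 2*pi.  First-passage (running-maximum)
crossings — rather than every up-crossing of the diffusing phase — are what
make the uncoupled interval distribution exactly inverse-Gaussian, which is
the analytic oracle used throughout the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import ModelParams

TWO_PI = 2.0 * math.pi

__all__ = ["PhasePath", "EventSequence", "simulate_sde", "extract_events",
           "simulate_cohort"]

#: fixed block length (steps) for per-cell noise generation; part of the
#: seeding contract — per-cell streams do not depend on cohort chunking.
_NOISE_BLOCK = 4000


@dataclass
class PhasePath:
    """A sampled (theta, phi) trajectory on a uniform time grid (unwrapped)."""

    times: np.ndarray
    theta: np.ndarray  # unwrapped, rad
    phi: np.ndarray    # unwrapped, rad
    dt: float
    seed: int | None = None

    def __post_init__(self):
        if not (len(self.times) == len(self.theta) == len(self.phi)):
            raise ValueError("times, theta, phi must have equal length")

    @property
    def theta_wrapped(self):
        return self.theta % TWO_PI

    @property
    def phi_wrapped(self):
        return self.phi % TWO_PI


@dataclass
class EventSequence:
    """Ordered, typed events of one cell: circadian peaks 'p', divisions 'd'."""

    cell_id: str
    events: list[tuple[float, str]] = field(default_factory=list)
    t_start: float = 0.0
    t_end: float = math.inf

    def __post_init__(self):
        self.events = sorted((float(t), str(k)) for t, k in self.events)
        times = [t for t, _ in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if times and (times[0] < self.t_start or times[-1] > self.t_end):
            raise ValueError("events outside the observation window")

    def times_of(self, kind: str) -> np.ndarray:
        return np.array([t for t, k in self.events if k == kind])

    def __len__(self):
        return len(self.events)


def _validate_dt(dt: float, t_end: float):
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 h for the stochastic integrator")


def simulate_sde(params: ModelParams, x0=(0.0, 0.0), t_end: float = 72.0,
                 dt: float = 0.02, seed: int = 0) -> PhasePath:
    """Euler–Maruyama realization of the coupled model from a fixed start.

    Same seed, same arguments => bit-identical path.
    """
    _validate_dt(dt, t_end)
    n_steps = int(round(t_end / dt))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_steps, 2))
    th, ph = _kernels.em_paths(
        np.array([float(x0[0])]), np.array([float(x0[1])]),
        np.ascontiguousarray(z[:, :1]), np.ascontiguousarray(z[:, 1:]),
        dt, math.sqrt(dt), params.omega1, params.omega2,
        params.sigma1, params.sigma2,
        *params.kernel_args()[2:], True)
    times = np.arange(n_steps + 1) * dt
    return PhasePath(times=times, theta=th[:, 0], phi=ph[:, 0], dt=dt, seed=seed)


def _first_passage_times(times: np.ndarray, x: np.ndarray) -> list[float]:
    """Times at which the running maximum of x first crosses multiples of 2*pi.

    Linear interpolation between the bracketing samples; the initial level is
    set by x[0] so a start exactly on a multiple emits no event at t=0.
    """
    runmax = np.maximum.accumulate(x)
    lev = np.floor(runmax / TWO_PI + 1e-9).astype(np.int64)
    out: list[float] = []
    jumps = np.nonzero(np.diff(lev) > 0)[0]
    for i in jumps:
        for level in range(lev[i] + 1, lev[i + 1] + 1):
            target = level * TWO_PI
            # first passage happens inside (t_i, t_{i+1}]: x[i+1] >= target > runmax[i]
            frac = (target - x[i]) / (x[i + 1] - x[i])
            frac = min(max(frac, 0.0), 1.0)
            out.append(float(times[i] + frac * (times[i + 1] - times[i])))
    return out


def extract_events(path: PhasePath, cell_id: str = "cell") -> EventSequence:
    """Typed event sequence from an unwrapped phase path (first passages)."""
    peaks = [(t, "p") for t in _first_passage_times(path.times, path.theta)]
    divs = [(t, "d") for t in _first_passage_times(path.times, path.phi)]
    ev = sorted(peaks + divs)
    # break exact ties deterministically (measure-zero; keep strict ordering)
    for i in range(1, len(ev)):
        if ev[i][0] <= ev[i - 1][0]:
            ev[i] = (np.nextafter(ev[i - 1][0], math.inf), ev[i][1])
    return EventSequence(cell_id=cell_id, events=ev,
                         t_start=float(path.times[0]), t_end=float(path.times[-1]))


def _cell_seeds(seed: int, n_cells: int):
    return np.random.SeedSequence(seed).spawn(n_cells)


def simulate_cohort(params: ModelParams, n_cells: int, duration: float = 72.0,
                    dt: float = 0.02, seed: int = 0, burn_in: float = 240.0,
                    return_paths: bool = False, chunk: int = 512):
    """Simulate a cohort and return one EventSequence per cell.

    Initial phases are uniform on the torus; ``burn_in`` hours are then
    simulated and discarded so the observation window starts at the model's
    stationary joint phase distribution.  Per-cell noise streams derive from
    the master seed via SeedSequence spawning (cell i's stream is the same
    for any cohort size), and time is blocked in fixed-length noise blocks,
    so results are independent of internal chunking.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    _validate_dt(dt, duration)
    n_burn = int(round(burn_in / dt))
    n_obs = int(round(duration / dt))
    times = np.arange(n_obs + 1) * dt
    seeds = _cell_seeds(seed, n_cells)
    out_events: list[EventSequence] = []
    out_paths: list[PhasePath] = []
    karg = params.kernel_args()
    for lo in range(0, n_cells, chunk):
        hi = min(lo + chunk, n_cells)
        rngs = [np.random.default_rng(s) for s in seeds[lo:hi]]
        m = hi - lo
        init = np.stack([r.uniform(0.0, TWO_PI, 2) for r in rngs])  # (m, 2)
        th = np.ascontiguousarray(init[:, 0])
        ph = np.ascontiguousarray(init[:, 1])

        def draw_block(nsteps):
            zt = np.empty((nsteps, m))
            zp = np.empty((nsteps, m))
            for j, r in enumerate(rngs):
                z = r.standard_normal((nsteps, 2))
                zt[:, j] = z[:, 0]
                zp[:, j] = z[:, 1]
            return zt, zp

        done = 0
        while done < n_burn:
            nb = min(_NOISE_BLOCK, n_burn - done)
            zt, zp = draw_block(nb)
            th_o, ph_o = _kernels.em_paths(th, ph, zt, zp, dt, math.sqrt(dt),
                                           karg[0], karg[1], params.sigma1,
                                           params.sigma2, *karg[2:], False)
            th, ph = th_o[0].copy(), ph_o[0].copy()
            done += nb
        # wrap back to keep unwrapped magnitudes small in the window
        off_t = np.floor(th / TWO_PI) * TWO_PI
        off_p = np.floor(ph / TWO_PI) * TWO_PI
        th -= off_t
        ph -= off_p

        zt, zp = draw_block(n_obs)
        th_o, ph_o = _kernels.em_paths(th, ph, zt, zp, dt, math.sqrt(dt),
                                       karg[0], karg[1], params.sigma1,
                                       params.sigma2, *karg[2:], True)
        for j in range(m):
            cid = f"cell{lo + j:05d}"
            p = PhasePath(times=times, theta=th_o[:, j], phi=ph_o[:, j], dt=dt)
            out_events.append(extract_events(p, cell_id=cid))
            if return_paths:
                out_paths.append(p)
    if return_paths:
        return out_events, out_paths
    return out_events
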
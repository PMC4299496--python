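"""Instantaneous circadian phase and amplitude by Viterbi decoding.

The hidden state is the pair (phase, amplitude) on a product grid: the
phase follows Brownian motion with drift 2*pi/T (wrapped Gaussian one-step
kernel), the amplitude an Ornstein–Uhlenbeck process (exact one-step
kernel between bin centers), and the observation is a raised cosine
y = b + A (1 + cos theta)/2 with Gaussian noise.  The decoder returns the
jointly most probable state sequence; phase is unwrapped by accumulating
the minimal signed bin difference with ties broken toward the drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * math.pi

__all__ = ["HMMSpec", "DecodedPath", "viterbi_decode",
           "instantaneous_velocity", "velocity_profile"]


@dataclass(frozen=True)
class HMMSpec:
    """Discretization and process parameters of the phase-amplitude HMM."""

    n_theta: int = 48
    n_amp: int = 15
    period: float = 24.0          # drift period prior T [h]
    sigma: float = 0.17           # phase diffusion [rad/sqrt(h)]
    amp_mean: float = 100.0       # OU mean A0
    amp_reversion: float = 0.1    # lambda_A [1/h]
    amp_noise: float = 8.944      # OU noise
    obs_noise: float = 5.0        # emission SD sigma_e
    baseline: float = 50.0        # b

    def __post_init__(self):
        if self.n_theta < 24:
            raise ValueError("need at least 24 phase bins")
        if min(self.sigma, self.amp_reversion, self.amp_noise, self.obs_noise,
               self.period) <= 0:
            raise ValueError("process rates must be positive")

    @property
    def theta_centers(self) -> np.ndarray:
        return np.arange(self.n_theta) * TWO_PI / self.n_theta

    @property
    def amp_centers(self) -> np.ndarray:
        return np.geomspace(self.amp_mean / 4.0, self.amp_mean * 4.0, self.n_amp)


@dataclass
class DecodedPath:
    """Viterbi-decoded phase/amplitude trajectory on the trace grid."""

    times: np.ndarray
    theta_hat: np.ndarray   # unwrapped, rad
    amp_hat: np.ndarray
    logp: np.ndarray        # per-step contribution of the decoded path
    spec: HMMSpec | None = None

    @property
    def theta_wrapped(self):
        return self.theta_hat % TWO_PI


def _phase_log_kernel(spec: HMMSpec, dt: float) -> np.ndarray:
    """log transition matrix over phase bins: wrapped Gaussian with drift."""
    n = spec.n_theta
    centers = spec.theta_centers
    shift = TWO_PI * dt / spec.period
    var = spec.sigma ** 2 * dt
    d = centers[None, :] - centers[:, None] - shift
    p = np.zeros((n, n))
    for k in (-1, 0, 1):
        p += np.exp(-((d + k * TWO_PI) ** 2) / (2.0 * var))
    p /= p.sum(axis=1, keepdims=True)
    return np.log(p + 1e-300)


def _amp_log_kernel(spec: HMMSpec, dt: float) -> np.ndarray:
    """log transition matrix over amplitude bins: exact OU one-step kernel."""
    a = spec.amp_centers
    rho = math.exp(-spec.amp_reversion * dt)
    var = spec.amp_noise ** 2 * (1.0 - rho * rho) / (2.0 * spec.amp_reversion)
    mean = spec.amp_mean + rho * (a[:, None] - spec.amp_mean)
    # geometric bins: weight by bin width so the discrete kernel integrates
    widths = np.gradient(a)
    p = np.exp(-((a[None, :] - mean) ** 2) / (2.0 * var)) * widths[None, :]
    p /= p.sum(axis=1, keepdims=True)
    return np.log(p + 1e-300)


def viterbi_decode(trace, times, spec: HMMSpec | None = None,
                   mask_times=None, mask_radius: int = 1) -> DecodedPath:
    """Most probable (phase, amplitude) sequence for one trace.

    ``mask_times`` (e.g. detected divisions) makes the emission
    uninformative within ``mask_radius`` samples, so division dips do not
    corrupt the phase estimate.
    """
    spec = spec or HMMSpec()
    y = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    dts = np.diff(times)
    if not np.allclose(dts, dts[0]):
        raise ValueError("times must be uniformly sampled")
    dt = float(dts[0])
    n_t, n_a = spec.n_theta, spec.n_amp
    log_tt = _phase_log_kernel(spec, dt)
    log_ta = _amp_log_kernel(spec, dt)

    theta_c = spec.theta_centers
    amp_c = spec.amp_centers
    mean_obs = spec.baseline + amp_c[None, :] * (1.0 + np.cos(theta_c))[:, None] / 2.0
    inv2v = 1.0 / (2.0 * spec.obs_noise ** 2)
    log_norm = -math.log(spec.obs_noise * math.sqrt(TWO_PI))

    masked = np.zeros(len(y), dtype=bool)
    if mask_times is not None:
        for t_m in np.atleast_1d(mask_times):
            i = int(round((t_m - times[0]) / dt))
            lo, hi = max(0, i - mask_radius), min(len(y), i + mask_radius + 1)
            masked[lo:hi] = True

    def emission(k):
        if masked[k]:
            return np.zeros((n_t, n_a))
        e = log_norm - (y[k] - mean_obs) ** 2 * inv2v
        if not np.all(np.isfinite(e)):
            raise FloatingPointError(
                "emission underflow: zero-noise spec inconsistent with the data; "
                "increase obs_noise")
        return e

    delta = emission(0)  # uniform prior over states
    bp_t = np.empty((len(y), n_t, n_a), dtype=np.int32)
    bp_a = np.empty((len(y), n_t, n_a), dtype=np.int32)
    for k in range(1, len(y)):
        # max over previous phase j for each (theta', a)
        m = delta[:, None, :] + log_tt[:, :, None]         # (j, theta', a)
        jstar = np.argmax(m, axis=0)                        # (theta', a)
        tmp = np.take_along_axis(m, jstar[None], axis=0)[0]
        # max over previous amp a for each (theta', a')
        m2 = tmp[:, :, None] + log_ta[None, :, :]           # (theta', a, a')
        astar = np.argmax(m2, axis=1)                       # (theta', a')
        delta = np.take_along_axis(m2, astar[:, None, :], axis=1)[:, 0, :] + emission(k)
        bp_t[k] = jstar
        bp_a[k] = astar
    # backtrace
    flat = int(np.argmax(delta))
    ti, ai = np.unravel_index(flat, (n_t, n_a))
    theta_bins = np.empty(len(y), dtype=int)
    amp_bins = np.empty(len(y), dtype=int)
    logp = np.empty(len(y))
    theta_bins[-1], amp_bins[-1] = ti, ai
    for k in range(len(y) - 1, 0, -1):
        ai_prev = bp_a[k][theta_bins[k], amp_bins[k]]
        ti_prev = bp_t[k][theta_bins[k], ai_prev]
        theta_bins[k - 1], amp_bins[k - 1] = ti_prev, ai_prev
    # per-step log contribution along the decoded path
    for k in range(len(y)):
        e = emission(k)[theta_bins[k], amp_bins[k]]
        if k == 0:
            logp[k] = e
        else:
            logp[k] = (e + log_tt[theta_bins[k - 1], theta_bins[k]]
                       + log_ta[amp_bins[k - 1], amp_bins[k]])
    # unwrap: minimal signed bin difference, ties toward the drift direction
    dbin = np.diff(theta_bins)
    dbin = (dbin + n_t // 2 - 1) % n_t - (n_t // 2 - 1)  # in (-n/2, n/2]
    theta_hat = theta_c[theta_bins[0]] + np.concatenate(
        [[0.0], np.cumsum(dbin) * TWO_PI / n_t])
    return DecodedPath(times=times, theta_hat=theta_hat,
                       amp_hat=amp_c[amp_bins], logp=logp, spec=spec)


def instantaneous_velocity(path: DecodedPath) -> np.ndarray:
    """Centered finite-difference phase velocity [rad/h] on the trace grid."""
    if len(path.times) < 3:
        raise ValueError("need at least 3 decoded samples")
    return np.gradient(path.theta_hat, path.times)


def default_cohort_rule(norm_phase: float | None) -> str:
    """Division-free / early-division / late-division interval classifier."""
    if norm_phase is None:
        return "free"
    return "early" if norm_phase < 0.5 else "late"


def velocity_profile(decoded: list[DecodedPath], events_list,
                     n_bins: int = 24, cohort_rule=default_cohort_rule,
                     peak_source: str = "events") -> dict:
    """Phase-binned mean velocity per division-timing cohort, centered on the
    division-free cohort.

    Each circadian interval (between consecutive peaks) is assigned to a
    cohort from its enclosed division's normalized timing (none, early,
    late); decoded velocities inside the interval are accumulated in wrapped
    phase bins.  Returns {cohort: dict(bin_centers, mean, se, n,
    mean_centered)}; cohorts with no data are omitted.
    """
    edges = np.linspace(0.0, TWO_PI, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    acc: dict[str, list] = {}
    for path, ev in zip(decoded, events_list):
        v = instantaneous_velocity(path)
        wrapped = path.theta_hat % TWO_PI
        peaks = ev.times_of("p")
        divs = ev.times_of("d")
        for t0, t1 in zip(peaks[:-1], peaks[1:]):
            inside = divs[(divs > t0) & (divs < t1)]
            if len(inside) > 1:
                continue
            np_phase = None if len(inside) == 0 else float((inside[0] - t0) / (t1 - t0))
            cohort = cohort_rule(np_phase)
            sel = (path.times >= t0) & (path.times <= t1)
            acc.setdefault(cohort, [[], []])
            acc[cohort][0].append(wrapped[sel])
            acc[cohort][1].append(v[sel])
    out = {}
    for cohort, (phs, vels) in acc.items():
        ph = np.concatenate(phs)
        ve = np.concatenate(vels)
        idx = np.clip(np.digitize(ph, edges) - 1, 0, n_bins - 1)
        mean = np.full(n_bins, np.nan)
        se = np.full(n_bins, np.nan)
        n = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            sel = idx == b
            n[b] = sel.sum()
            if n[b] > 0:
                mean[b] = ve[sel].mean()
            if n[b] > 1:
                se[b] = ve[sel].std(ddof=1) / math.sqrt(n[b])
        out[cohort] = {"bin_centers": centers, "mean": mean, "se": se, "n": n}
    if "free" in out:
        base = out["free"]["mean"]
        for cohort in out:
            out[cohort]["mean_centered"] = out[cohort]["mean"] - base
    return out
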
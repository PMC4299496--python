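"""Coupled circadian / cell-cycle phase model.

Two noisy phase oscillators on the torus: the circadian phase ``theta``
(zero at the reporter peak) and the cell-cycle phase ``phi`` (zero at
mitosis), both increasing with time:

    d(theta) = (2*pi/T1 + F1(theta, phi)) dt + sigma1 dW_t
    d(phi)   = (2*pi/T2 + F2(theta, phi)) dt + sigma2 dY_t

``F1`` carries the influence of the cell cycle on the clock (positive
regions accelerate the circadian phase), ``F2`` the reverse influence.
Each coupling function is a signed mixture of two-dimensional Gaussian
bumps with diagonal covariance, periodized on the torus by summing the
3x3 nearest periodic images of each center.

This module owns the parameterization and the noise-free skeleton of the
dynamics: the mitosis-section Poincaré map, its fixed points (mode-locked
states, attractor/repeller pairs) and the winding number.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels

TWO_PI = 2.0 * math.pi

__all__ = [
    "CouplingBump",
    "CouplingFunction",
    "ModelParams",
    "LockedState",
    "InvalidParameterError",
    "NoReturnMapError",
    "eval_coupling",
    "drift",
    "poincare_map",
    "find_locked_states",
    "winding_number",
]


class InvalidParameterError(ValueError):
    """Raised for non-physical model parameters (e.g. non-positive widths)."""


class NoReturnMapError(RuntimeError):
    """Raised when the noise-free cell-cycle velocity stalls (no Poincaré map)."""


def _wrap(x):
    return np.asarray(x, dtype=float) % TWO_PI


@dataclass(frozen=True)
class CouplingBump:
    """One signed Gaussian bump of a coupling function.

    K is the signed amplitude in rad/h; ``center`` the (mu_theta, mu_phi)
    location in radians (wrapped into [0, 2*pi)); ``widths`` the standard
    deviations (s_theta, s_phi) in radians, strictly positive.
    """

    K: float
    center: tuple[float, float]
    widths: tuple[float, float]

    def __post_init__(self):
        if not (self.widths[0] > 0 and self.widths[1] > 0):
            raise InvalidParameterError(f"bump widths must be > 0, got {self.widths}")
        object.__setattr__(self, "center", (float(self.center[0]) % TWO_PI,
                                            float(self.center[1]) % TWO_PI))
        object.__setattr__(self, "widths", (float(self.widths[0]), float(self.widths[1])))
        object.__setattr__(self, "K", float(self.K))


@dataclass(frozen=True)
class CouplingFunction:
    """Signed mixture of periodized Gaussian bumps, F(theta, phi) = sum K_i G_i."""

    bumps: tuple[CouplingBump, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "bumps", tuple(self.bumps))

    @staticmethod
    def zero() -> "CouplingFunction":
        return CouplingFunction(())

    def arrays(self):
        """Flat parameter arrays (K, mu_theta, mu_phi, s_theta, s_phi)."""
        n = len(self.bumps)
        K = np.empty(n)
        mut = np.empty(n)
        mup = np.empty(n)
        st = np.empty(n)
        sp = np.empty(n)
        for i, b in enumerate(self.bumps):
            K[i] = b.K
            mut[i], mup[i] = b.center
            st[i], sp[i] = b.widths
        return K, mut, mup, st, sp

    def __call__(self, theta, phi):
        return eval_coupling(self, theta, phi)

    def max_abs(self, n_grid: int = 96) -> float:
        """Maximum |F| on an n_grid x n_grid torus grid (display/threshold helper)."""
        g = np.linspace(0.0, TWO_PI, n_grid, endpoint=False)
        th, ph = np.meshgrid(g, g, indexing="ij")
        return float(np.max(np.abs(eval_coupling(self, th, ph))))


def _as_coupling(F) -> CouplingFunction:
    if isinstance(F, CouplingFunction):
        return F
    if F is None:
        return CouplingFunction.zero()
    return CouplingFunction(tuple(F))


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of the coupled stochastic phase model.

    Periods in hours (math.inf disables an oscillator: zero drift), phase
    diffusion coefficients in rad/sqrt(h).
    """

    T1: float
    T2: float
    sigma1: float
    sigma2: float
    F1: CouplingFunction = field(default_factory=CouplingFunction.zero)
    F2: CouplingFunction = field(default_factory=CouplingFunction.zero)

    def __post_init__(self):
        object.__setattr__(self, "F1", _as_coupling(self.F1))
        object.__setattr__(self, "F2", _as_coupling(self.F2))
        if not (self.T1 > 0 and self.T2 > 0):
            raise InvalidParameterError("periods must be positive")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise InvalidParameterError("diffusion coefficients must be >= 0")

    @property
    def omega1(self) -> float:
        return 0.0 if math.isinf(self.T1) else TWO_PI / self.T1

    @property
    def omega2(self) -> float:
        return 0.0 if math.isinf(self.T2) else TWO_PI / self.T2

    def kernel_args(self):
        """(om1, om2, F1 arrays..., F2 arrays...) in kernel order."""
        K1, mut1, mup1, st1, sp1 = self.F1.arrays()
        K2, mut2, mup2, st2, sp2 = self.F2.arrays()
        return (self.omega1, self.omega2,
                K1, mut1, mup1, st1, sp1, K2, mut2, mup2, st2, sp2)

    # -- lossless JSON (de)serialization ------------------------------------
    def to_dict(self) -> dict:
        def fun(F: CouplingFunction):
            return [
                {"K": b.K, "mu_theta": b.center[0], "mu_phi": b.center[1],
                 "s_theta": b.widths[0], "s_phi": b.widths[1]}
                for b in F.bumps
            ]
        return {"T1": self.T1, "T2": self.T2, "sigma1": self.sigma1,
                "sigma2": self.sigma2, "F1": fun(self.F1), "F2": fun(self.F2)}

    @staticmethod
    def from_dict(d: dict) -> "ModelParams":
        def fun(rows) -> CouplingFunction:
            return CouplingFunction(tuple(
                CouplingBump(r["K"], (r["mu_theta"], r["mu_phi"]),
                             (r["s_theta"], r["s_phi"]))
                for r in rows
            ))
        return ModelParams(d["T1"], d["T2"], d["sigma1"], d["sigma2"],
                           fun(d.get("F1", [])), fun(d.get("F2", [])))

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @staticmethod
    def from_json(source) -> "ModelParams":
        try:
            d = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                d = json.load(fh)
        return ModelParams.from_dict(d)


@dataclass(frozen=True)
class LockedState:
    """A fixed point of the mitosis-section Poincaré map.

    ``theta_star`` is the circadian phase at mitosis; ``stable`` marks the
    attractor (map slope < 1); ``lead_time`` the noise-free time from a
    division to the next circadian peak on the locked trajectory.
    """

    theta_star: float
    stable: bool
    lead_time: float
    map_slope: float = float("nan")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def eval_coupling(F: CouplingFunction, theta, phi):
    """Evaluate a coupling function (rad/h), 2*pi-periodic in both arguments.

    Accepts scalars or broadcastable arrays; bump Gaussians are summed over
    the 3x3 nearest periodic images of each center.
    """
    F = _as_coupling(F)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.zeros(np.broadcast(theta, phi).shape)
    for b in F.bumps:
        dx = (theta - b.center[0] + math.pi) % TWO_PI - math.pi
        dy = (phi - b.center[1] + math.pi) % TWO_PI - math.pi
        gx = sum(np.exp(-((dx + k * TWO_PI) ** 2) / (2.0 * b.widths[0] ** 2))
                 for k in (-1, 0, 1))
        gy = sum(np.exp(-((dy + k * TWO_PI) ** 2) / (2.0 * b.widths[1] ** 2))
                 for k in (-1, 0, 1))
        out = out + b.K * gx * gy
    if out.ndim == 0:
        return float(out)
    return out


def drift(params: ModelParams, theta, phi):
    """Deterministic phase velocities (d theta/dt, d phi/dt) in rad/h."""
    d1 = params.omega1 + eval_coupling(params.F1, theta, phi)
    d2 = params.omega2 + eval_coupling(params.F2, theta, phi)
    return d1, d2


_MAP_DT = 0.01  # h; fixed RK4 step for all noise-free integrations


def _max_return_time(params: ModelParams) -> float:
    if math.isinf(params.T2):
        return 100.0
    return 25.0 * params.T2


def poincare_map(params: ModelParams, theta0, dt: float = _MAP_DT):
    """Circadian phase after one full cell cycle, noise-free.

    Integrates from (theta0, phi=0) until phi reaches 2*pi and returns
    theta mod 2*pi.  Raises :class:`NoReturnMapError` if the cell-cycle
    velocity stalls or the section is never reached.
    """
    theta0 = np.atleast_1d(np.asarray(theta0, dtype=float))
    th, _, ok = _kernels.poincare_batch(theta0, dt, _max_return_time(params),
                                        *params.kernel_args())
    if not np.all(ok):
        raise NoReturnMapError("cell-cycle velocity stalled; Poincaré map undefined")
    th = th % TWO_PI
    return float(th[0]) if th.size == 1 else th


def _map_lift(params: ModelParams, theta0: np.ndarray, dt: float = _MAP_DT):
    """Unwrapped section values (continuous lift), with return times."""
    th, t, ok = _kernels.poincare_batch(np.asarray(theta0, dtype=float), dt,
                                        _max_return_time(params), *params.kernel_args())
    if not np.all(ok):
        raise NoReturnMapError("cell-cycle velocity stalled; Poincaré map undefined")
    return th, t


def _lead_time(params: ModelParams, theta_star: float, dt: float = _MAP_DT) -> float:
    """Noise-free time from a division at theta_star to the next reporter peak."""
    th0 = theta_star % TWO_PI
    target = TWO_PI * math.ceil(th0 / TWO_PI + 1e-12)
    if target <= th0:
        target += TWO_PI
    t = _kernels.time_to_theta_crossing(th0, 0.0, target, dt,
                                        _max_return_time(params) * 2.0,
                                        *params.kernel_args())
    if math.isnan(t):
        raise NoReturnMapError("circadian phase never completes; no peak after division")
    return float(t)


def find_locked_states(params: ModelParams, n_scan: int = 720,
                       tol: float = 1e-9) -> list[LockedState]:
    """Locate all fixed points of the Poincaré map.

    Dense scan of the displacement g(theta) = lift(theta) - theta (mod 2*pi,
    centered) followed by bisection on each sign-change bracket.  Stability
    from the numerical map slope; lead time measured on the locked
    trajectory.
    """
    grid = np.linspace(0.0, TWO_PI, n_scan, endpoint=False)
    lift, _ = _map_lift(params, grid)
    g = (lift - grid + math.pi) % TWO_PI - math.pi

    states: list[LockedState] = []
    roots: list[float] = []
    for i in range(n_scan):
        j = (i + 1) % n_scan
        gi, gj = g[i], g[j]
        if gi == 0.0:
            roots.append(grid[i])
            continue
        if gi * gj < 0 and abs(gj - gi) < math.pi:  # true zero crossing, not a wrap
            a, b_ = grid[i], grid[i] + TWO_PI / n_scan
            ga = gi
            while (b_ - a) > tol:
                m = 0.5 * (a + b_)
                lm, _ = _map_lift(params, np.array([m]))
                gm = (lm[0] - m + math.pi) % TWO_PI - math.pi
                if ga * gm <= 0:
                    b_ = m
                else:
                    a, ga = m, gm
            roots.append(0.5 * (a + b_))

    h = 1e-4
    for r in roots:
        lp, _ = _map_lift(params, np.array([r - h, r + h]))
        slope = (lp[1] - lp[0]) / (2 * h)
        states.append(LockedState(theta_star=r % TWO_PI, stable=bool(abs(slope) < 1.0),
                                  lead_time=_lead_time(params, r), map_slope=float(slope)))
    states.sort(key=lambda s: s.theta_star)
    return states


def winding_number(params: ModelParams, n_cycles: int = 100,
                   transient_cycles: int = 10, dt: float = _MAP_DT) -> float:
    """Cell cycles completed per circadian cycle, noise-free, long run.

    Integrates for ``transient_cycles`` circadian cycles (discarded), then
    measures the phase displacement ratio over ``n_cycles`` further cycles.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    om1 = params.omega1
    if om1 <= 0:
        raise NoReturnMapError("circadian oscillator disabled; winding number undefined")
    args = params.kernel_args()
    # crude per-cycle duration bound to size the fixed-step integration
    t_cycle = TWO_PI / om1 * 3.0
    th, ph = 0.1, 0.0
    # transient
    n_steps = int((transient_cycles * t_cycle) / dt)
    th, ph = _kernels.flow_advance(th, ph, n_steps, dt, *args)
    th0, ph0 = th, ph
    target = th0 + TWO_PI * n_cycles
    t = _kernels.time_to_theta_crossing(th0, ph0, target, dt,
                                        n_cycles * t_cycle * 2.0, *args)
    if math.isnan(t):
        raise NoReturnMapError("circadian phase stalled during winding-number run")
    n_steps = int(t / dt)
    th_e, ph_e = _kernels.flow_advance(th0, ph0, n_steps, dt, *args)
    # finish the fractional step to land exactly on the target circadian phase
    th_f, ph_f = _kernels.rk4_step(th_e, ph_e, t - n_steps * dt, *args)
    return float((ph_f - ph0) / (TWO_PI * n_cycles))
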
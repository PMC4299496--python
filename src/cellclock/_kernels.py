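"""Numba-compiled numerical kernels.

Everything here operates on flat ``float64`` arrays describing one coupling
function per oscillator: ``(K, mu_theta, mu_phi, s_theta, s_phi)`` vectors of
equal length.  Disabled oscillators are encoded upstream as zero angular
velocity (infinite period) and zero diffusion.

The kernels are deliberately free of Python objects so that the same code
paths serve the deterministic integrator (Poincaré sections, locked states),
the stochastic cohort simulator and the particle-filter likelihood.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True, fastmath=True, inline="always")
def coupling_scalar(th, ph, K, mut, mup, st, sp):
    """Sum of periodized Gaussian bumps at a single point.

    Each bump is evaluated over the 3x3 nearest periodic images of its
    center; the separable form needs six exponentials per bump.
    """
    out = 0.0
    for i in range(K.size):
        dx = (th - mut[i] + np.pi) % TWO_PI - np.pi
        dy = (ph - mup[i] + np.pi) % TWO_PI - np.pi
        inv2sx = 1.0 / (2.0 * st[i] * st[i])
        inv2sy = 1.0 / (2.0 * sp[i] * sp[i])
        gx = (
            np.exp(-dx * dx * inv2sx)
            + np.exp(-(dx - TWO_PI) * (dx - TWO_PI) * inv2sx)
            + np.exp(-(dx + TWO_PI) * (dx + TWO_PI) * inv2sx)
        )
        gy = (
            np.exp(-dy * dy * inv2sy)
            + np.exp(-(dy - TWO_PI) * (dy - TWO_PI) * inv2sy)
            + np.exp(-(dy + TWO_PI) * (dy + TWO_PI) * inv2sy)
        )
        out += K[i] * gx * gy
    return out


@njit(cache=True, fastmath=True, inline="always")
def drift_scalar(th, ph, om1, om2, K1, mut1, mup1, st1, sp1, K2, mut2, mup2, st2, sp2):
    d1 = om1 + coupling_scalar(th, ph, K1, mut1, mup1, st1, sp1)
    d2 = om2 + coupling_scalar(th, ph, K2, mut2, mup2, st2, sp2)
    return d1, d2


@njit(cache=True, fastmath=True, inline="always")
def rk4_step(th, ph, dt, om1, om2, K1, mut1, mup1, st1, sp1, K2, mut2, mup2, st2, sp2):
    a1, b1 = drift_scalar(th, ph, om1, om2, K1, mut1, mup1, st1, sp1, K2, mut2, mup2, st2, sp2)
    a2, b2 = drift_scalar(
        th + 0.5 * dt * a1, ph + 0.5 * dt * b1,
        om1, om2, K1, mut1, mup1, st1, sp1, K2, mut2, mup2, st2, sp2,
    )
    a3, b3 = drift_scalar(
        th + 0.5 * dt * a2, ph + 0.5 * dt * b2,
        om1, om2, K1, mut1, mup1, st1, sp1, K2, mut2, mup2, st2, sp2,
    )
    a4, b4 = drift_scalar(
        th + dt * a3, ph + dt * b3,
        om1, om2, K1, mut1, mup1, st1, sp1, K2, mut2, mup2, st2, sp2,
    )
    return (
        th + dt * (a1 + 2.0 * a2 + 2.0 * a3 + a4) / 6.0,
        ph + dt * (b1 + 2.0 * b2 + 2.0 * b3 + b4) / 6.0,
    )


@njit(cache=True, fastmath=True)
def poincare_batch(theta0, dt, max_time,
                   om1, om2, K1, mut1, mup1, st1, sp1, K2, mut2, mup2, st2, sp2):
    """Integrate from (theta0_i, phi=0) until phi = 2*pi.

    Returns (theta_at_section, return_time, ok) per start point.  ``ok`` is
    False where the cell-cycle velocity becomes non-positive (stalled map)
    or the section is not reached within ``max_time``.
    """
    n = theta0.size
    out_th = np.empty(n)
    out_t = np.empty(n)
    ok = np.ones(n, dtype=np.bool_)
    for i in range(n):
        th = theta0[i]
        ph = 0.0
        t = 0.0
        reached = False
        while t < max_time:
            _, dphi = drift_scalar(th, ph, om1, om2, K1, mut1, mup1, st1, sp1,
                                   K2, mut2, mup2, st2, sp2)
            if dphi <= 0.0:
                ok[i] = False
                break
            th_n, ph_n = rk4_step(th, ph, dt, om1, om2, K1, mut1, mup1, st1, sp1,
                                  K2, mut2, mup2, st2, sp2)
            if ph_n >= TWO_PI:
                # refine the partial step to land exactly on the section
                h = dt * (TWO_PI - ph) / (ph_n - ph)
                for _ in range(3):
                    th_e, ph_e = rk4_step(th, ph, h, om1, om2, K1, mut1, mup1, st1, sp1,
                                          K2, mut2, mup2, st2, sp2)
                    _, dphi_e = drift_scalar(th_e, ph_e, om1, om2, K1, mut1, mup1, st1,
                                             sp1, K2, mut2, mup2, st2, sp2)
                    h += (TWO_PI - ph_e) / dphi_e
                th_n, ph_n = rk4_step(th, ph, h, om1, om2, K1, mut1, mup1, st1, sp1,
                                      K2, mut2, mup2, st2, sp2)
                out_th[i] = th_n
                out_t[i] = t + h
                reached = True
                break
            th, ph = th_n, ph_n
            t += dt
        if not reached and ok[i]:
            ok[i] = False
        if not ok[i]:
            out_th[i] = np.nan
            out_t[i] = np.nan
    return out_th, out_t, ok


@njit(cache=True, fastmath=True)
def time_to_theta_crossing(theta0, phi0, target, dt, max_time,
                           om1, om2, K1, mut1, mup1, st1, sp1, K2, mut2, mup2, st2, sp2):
    """Time for the noise-free flow from (theta0, phi0) to reach theta = target.

    Returns nan if theta does not reach the target within ``max_time``.
    """
    th = theta0
    ph = phi0
    t = 0.0
    while t < max_time:
        th_n, ph_n = rk4_step(th, ph, dt, om1, om2, K1, mut1, mup1, st1, sp1,
                              K2, mut2, mup2, st2, sp2)
        if th_n >= target:
            h = dt * (target - th) / (th_n - th)
            for _ in range(3):
                th_e, ph_e = rk4_step(th, ph, h, om1, om2, K1, mut1, mup1, st1, sp1,
                                      K2, mut2, mup2, st2, sp2)
                dth_e, _ = drift_scalar(th_e, ph_e, om1, om2, K1, mut1, mup1, st1, sp1,
                                        K2, mut2, mup2, st2, sp2)
                h += (target - th_e) / dth_e
            return t + h
        th, ph = th_n, ph_n
        t += dt
    return np.nan


@njit(cache=True, fastmath=True)
def flow_advance(theta, phi, n_steps, dt,
                 om1, om2, K1, mut1, mup1, st1, sp1, K2, mut2, mup2, st2, sp2):
    """Advance the noise-free flow by n_steps fixed RK4 steps (scalar state)."""
    th = theta
    ph = phi
    for _ in range(n_steps):
        th, ph = rk4_step(th, ph, dt, om1, om2, K1, mut1, mup1, st1, sp1,
                          K2, mut2, mup2, st2, sp2)
    return th, ph


@njit(cache=True, fastmath=True)
def em_paths(theta0, phi0, noise_th, noise_ph, dt, sqdt,
             om1, om2, s1, s2, K1, mut1, mup1, st1, sp1, K2, mut2, mup2, st2, sp2,
             record):
    """Euler–Maruyama integration of a batch of cells.

    theta0/phi0: (n_cells,) initial unwrapped phases.
    noise_*:     (n_steps, n_cells) standard-normal increments.
    record:      if True, return full paths of shape (n_steps+1, n_cells);
                 otherwise return only the final state as shape (1, n_cells).
    """
    n_steps, n_cells = noise_th.shape
    if record:
        th_out = np.empty((n_steps + 1, n_cells))
        ph_out = np.empty((n_steps + 1, n_cells))
        th_out[0] = theta0
        ph_out[0] = phi0
    else:
        th_out = np.empty((1, n_cells))
        ph_out = np.empty((1, n_cells))
    th = theta0.copy()
    ph = phi0.copy()
    for k in range(n_steps):
        for j in range(n_cells):
            d1, d2 = drift_scalar(th[j], ph[j], om1, om2, K1, mut1, mup1, st1, sp1,
                                  K2, mut2, mup2, st2, sp2)
            th[j] = th[j] + d1 * dt + s1 * sqdt * noise_th[k, j]
            ph[j] = ph[j] + d2 * dt + s2 * sqdt * noise_ph[k, j]
        if record:
            th_out[k + 1] = th
            ph_out[k + 1] = ph
    if not record:
        th_out[0] = th
        ph_out[0] = ph
    return th_out, ph_out


@njit(cache=True, fastmath=True, inline="always")
def table_lookup(th, ph, tab):
    """Bilinear periodic interpolation of a torus-gridded field."""
    n = tab.shape[0]
    x = (th % TWO_PI) / TWO_PI * n
    y = (ph % TWO_PI) / TWO_PI * n
    i0 = int(x)
    j0 = int(y)
    fx = x - i0
    fy = y - j0
    i0 = i0 % n
    j0 = j0 % n
    i1 = (i0 + 1) % n
    j1 = (j0 + 1) % n
    return ((1.0 - fx) * (1.0 - fy) * tab[i0, j0]
            + fx * (1.0 - fy) * tab[i1, j0]
            + (1.0 - fx) * fy * tab[i0, j1]
            + fx * fy * tab[i1, j1])


@njit(cache=True, fastmath=True)
def em_paths_tab(theta0, phi0, noise_th, noise_ph, dt, sqdt,
                 om1, om2, s1, s2, tab1, tab2):
    """Euler–Maruyama batch advance using tabulated coupling fields.

    Returns only the final state (used for the stationary pre-simulation)."""
    n_steps, n_cells = noise_th.shape
    th = theta0.copy()
    ph = phi0.copy()
    for k in range(n_steps):
        for j in range(n_cells):
            d1 = om1 + table_lookup(th[j], ph[j], tab1)
            d2 = om2 + table_lookup(th[j], ph[j], tab2)
            th[j] = th[j] + d1 * dt + s1 * sqdt * noise_th[k, j]
            ph[j] = ph[j] + d2 * dt + s2 * sqdt * noise_ph[k, j]
    return th, ph
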
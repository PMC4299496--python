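"""Synchronization order parameters and Granger-causality direction calls.

Kuramoto-style order parameters: R_theta = |mean exp(i theta)| over cells
(0 for fully random phases, 1 for identical phases), R_phi likewise for the
cell-cycle phase, and the 1:1 relative-phase index R_rel on theta - phi.
Granger direction: bivariate VAR with information-criterion lag selection
and Wald tests on the cross-lag coefficients in both directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.signal import detrend as _detrend
from statsmodels.tsa.api import VAR

__all__ = ["sync_index", "relative_sync_index", "sync_over_time", "SyncSeries",
           "granger_direction", "GrangerResult", "granger_table"]


def sync_index(phases) -> float:
    """Modulus of the population-mean unit phasor |N^-1 sum exp(i theta_k)|."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("need at least one phase")
    # clamp: rounding can push identical phases to 1 + eps
    return float(min(np.abs(np.exp(1j * phases).mean()), 1.0))


def relative_sync_index(thetas, phis) -> float:
    """1:1 relative-phase order parameter |N^-1 sum exp(i (theta_k - phi_k))|."""
    thetas = np.asarray(thetas, dtype=float)
    phis = np.asarray(phis, dtype=float)
    if thetas.shape != phis.shape:
        raise ValueError("phase arrays must have equal shape")
    if thetas.size < 2:
        raise ValueError("need at least two phase pairs")
    return sync_index(thetas - phis)


@dataclass
class SyncSeries:
    """Time courses of the three synchronization indices with bootstrap SDs."""

    times: np.ndarray
    R_theta: np.ndarray
    R_phi: np.ndarray
    R_rel: np.ndarray
    sd_theta: np.ndarray
    sd_phi: np.ndarray
    sd_rel: np.ndarray
    n_cells: int
    low_n: bool = False


def sync_over_time(theta: np.ndarray, phi: np.ndarray, times,
                   n_boot: int = 200, seed: int = 0) -> SyncSeries:
    """All three indices per time point for a cohort on a common grid.

    ``theta``/``phi``: arrays of shape (n_cells, n_times), radians.  SDs by
    bootstrap over cells; cohorts of fewer than 10 cells are flagged.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    times = np.asarray(times, dtype=float)
    n_cells = theta.shape[0]
    zt = np.exp(1j * theta)
    zp = np.exp(1j * phi)
    zr = np.exp(1j * (theta - phi))
    R = [np.abs(z.mean(axis=0)) for z in (zt, zp, zr)]
    rng = np.random.default_rng(seed)
    boots = np.empty((3, n_boot, theta.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n_cells, n_cells)
        for j, z in enumerate((zt, zp, zr)):
            boots[j, b] = np.abs(z[idx].mean(axis=0))
    sd = boots.std(axis=1, ddof=1)
    return SyncSeries(times=times, R_theta=R[0], R_phi=R[1], R_rel=R[2],
                      sd_theta=sd[0], sd_phi=sd[1], sd_rel=sd[2],
                      n_cells=n_cells, low_n=n_cells < 10)


class GrangerResult(NamedTuple):
    p_xy: float          # x Granger-causes y
    p_yx: float          # y Granger-causes x
    call: str            # 'x->y', 'y->x', 'both', 'none'
    lag: int


def granger_direction(x, y, max_lag: int = 8, alpha: float = 1e-3,
                      ic: str = "aic", mode: str = "threshold") -> GrangerResult:
    """Directional Granger-causality calls between two equal-length series.

    Both series are linearly detrended and standardized; a bivariate VAR
    of order selected by ``ic`` over 1..max_lag is fit, and Wald tests on
    the joint nullity of the cross-lag coefficients give a p-value per
    direction.  mode='threshold' calls each direction at p < alpha;
    mode='stronger' calls only the direction with the smaller p-value
    (still requiring p < alpha).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series must be finite")
    if len(x) < 60 + max_lag:
        raise ValueError("need at least 60 samples after lag trimming")

    def prep(s):
        s = _detrend(s)
        sd = s.std()
        return s / sd if sd > 0 else s

    data = np.column_stack([prep(x), prep(y)])
    model = VAR(data)
    sel = model.select_order(maxlags=max_lag)
    p = int(getattr(sel, ic))
    p = max(p, 1)
    res = model.fit(p)
    p_xy = float(res.test_causality(caused=1, causing=0, kind="wald").pvalue)
    p_yx = float(res.test_causality(caused=0, causing=1, kind="wald").pvalue)
    sig_xy, sig_yx = p_xy < alpha, p_yx < alpha
    if mode == "stronger":
        if sig_xy and (not sig_yx or p_xy <= p_yx):
            call = "x->y"
        elif sig_yx:
            call = "y->x"
        else:
            call = "none"
    else:
        call = {(True, True): "both", (True, False): "x->y",
                (False, True): "y->x", (False, False): "none"}[(sig_xy, sig_yx)]
    return GrangerResult(p_xy, p_yx, call, p)


def granger_table(traces, max_lag: int = 8, alpha: float = 1e-3,
                  mode: str = "threshold"):
    """Per-cell Granger calls, nuclear size (x) vs reporter (y), for a TraceSet.

    Returns a pandas DataFrame: cell_id, p_xy, p_yx, call, lag.
    """
    import pandas as pd

    rows = []
    for i, cid in enumerate(traces.cell_ids):
        r = granger_direction(traces.nuc_size[i], traces.yfp[i],
                              max_lag=max_lag, alpha=alpha, mode=mode)
        rows.append((cid, r.p_xy, r.p_yx, r.call, r.lag))
    return pd.DataFrame(rows, columns=["cell_id", "p_xy", "p_yx", "call", "lag"])
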
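"""Interval statistics on typed event sequences.

Builds the interval bookkeeping of circadian peak (p) and division (d)
events: division-free circadian intervals (p,p), single-division intervals
(p,d,p) with their normalized division phase, the sub-intervals (p,d) and
(d,p), cell-cycle durations (d,d)/(d,p,d), group comparisons, the
temperature coefficient Q10, and the correlation of successive circadian
and cell-cycle durations.

Circadian intervals enclosing two or more divisions (and cell cycles
enclosing two or more peaks) are kept with audit types ``pp_multi`` /
``dd_multi`` and excluded from the standard summaries.
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import EventSequence

__all__ = ["build_intervals", "summarize_intervals", "compare_interval_groups",
           "q10", "successive_interval_r2", "successive_pairs",
           "IntervalSummary", "TYPE_GROUPS"]

#: convenience selections: all cell-cycle durations / all circadian intervals
TYPE_GROUPS = {
    "dd_any": ("dd", "dpd", "dd_multi"),
    "pp_any": ("pp", "pdp", "pp_multi"),
}


class IntervalSummary(NamedTuple):
    n: int
    mean: float
    sd: float


def build_intervals(events: EventSequence | Iterable[EventSequence]) -> pd.DataFrame:
    """Interval table from one or many event sequences.

    Columns: cell_id, kind, duration [h], t_open, t_close, division_time
    (enclosed division, pdp rows), division_phase (normalized, pdp rows).
    """
    if isinstance(events, EventSequence):
        events = [events]
    rows = []
    for ev in events:
        ts = [t for t, _ in ev.events]
        if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
            raise ValueError("events must be sorted with strictly increasing times")
        seq = ev.events
        # adjacent mixed pairs
        for (t1, k1), (t2, k2) in zip(seq, seq[1:]):
            if k1 != k2:
                rows.append((ev.cell_id, k1 + k2, t2 - t1, t1, t2, np.nan, np.nan))
        # consecutive same-type pairs with enclosed opposite events
        for kind, other in (("p", "d"), ("d", "p")):
            own = [(i, t) for i, (t, k) in enumerate(seq) if k == kind]
            for (i1, t1), (i2, t2) in zip(own, own[1:]):
                enclosed = [t for t, k in seq[i1 + 1:i2] if k == other]
                if len(enclosed) == 0:
                    name = kind + kind
                    rows.append((ev.cell_id, name, t2 - t1, t1, t2, np.nan, np.nan))
                elif len(enclosed) == 1:
                    name = kind + other + kind
                    phase = (enclosed[0] - t1) / (t2 - t1) if kind == "p" else np.nan
                    rows.append((ev.cell_id, name, t2 - t1, t1, t2,
                                 enclosed[0] if kind == "p" else np.nan, phase))
                else:
                    rows.append((ev.cell_id, kind + kind + "_multi",
                                 t2 - t1, t1, t2, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["cell_id", "kind", "duration", "t_open",
                                       "t_close", "division_time",
                                       "division_phase"])


def _select(table: pd.DataFrame, kind) -> pd.Series:
    kinds = TYPE_GROUPS.get(kind, (kind,) if isinstance(kind, str) else tuple(kind))
    return table.loc[table["kind"].isin(kinds), "duration"]


def summarize_intervals(table: pd.DataFrame, kind) -> IntervalSummary:
    """(n, mean, sample SD) of the durations of one interval type.

    ``kind`` may be a type name, a tuple of names, or a group alias
    ('pp_any', 'dd_any').  Undefined statistics are NaN sentinels.
    """
    d = _select(table, kind)
    n = len(d)
    if n == 0:
        return IntervalSummary(0, math.nan, math.nan)
    if n == 1:
        return IntervalSummary(1, float(d.iloc[0]), math.nan)
    return IntervalSummary(n, float(d.mean()), float(d.std(ddof=1)))


def compare_interval_groups(a, b):
    """Welch t-test and two-sample KS test on two duration samples.

    Returns (t_statistic, p_value, ks_statistic, ks_p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    t_res = stats.ttest_ind(a, b, equal_var=False)
    ks_res = stats.ks_2samp(a, b)
    return (float(t_res.statistic), float(t_res.pvalue),
            float(ks_res.statistic), float(ks_res.pvalue))


def q10(period_low: float, temp_low: float, period_high: float,
        temp_high: float) -> float:
    """Temperature coefficient of a rate from periods at two temperatures.

    Q10 = (period at the lower temperature / period at the higher
    temperature) ** (10 / dT); Q10 > 1 means the process speeds up with
    temperature, Q10 < 1 overcompensation.
    """
    if temp_high <= temp_low:
        raise ValueError("temp_high must exceed temp_low")
    if period_low <= 0 or period_high <= 0:
        raise ValueError("periods must be positive")
    return (period_low / period_high) ** (10.0 / (temp_high - temp_low))


def successive_pairs(events: EventSequence | Iterable[EventSequence]) -> np.ndarray:
    """Paired successive (circadian, cell-cycle) durations from quadruples.

    Scans each cell's ordered events for patterns (p1,d1,p2,d2) and
    (d1,p1,d2,p2); each match contributes one (p2-p1, d2-d1) pair.
    """
    if isinstance(events, EventSequence):
        events = [events]
    pairs = []
    for ev in events:
        seq = ev.events
        for i in range(len(seq) - 3):
            kinds = tuple(k for _, k in seq[i:i + 4])
            t = [tt for tt, _ in seq[i:i + 4]]
            if kinds == ("p", "d", "p", "d") or kinds == ("d", "p", "d", "p"):
                first = t[2] - t[0]
                second = t[3] - t[1]
                if kinds[0] == "p":
                    pairs.append((first, second))   # (circadian, cell cycle)
                else:
                    pairs.append((second, first))
    return np.asarray(pairs, dtype=float).reshape(-1, 2)


def successive_interval_r2(pairs: np.ndarray) -> tuple[float, int]:
    """Squared Pearson correlation of paired successive durations.

    Returns (R^2, n); NaN sentinel if either margin has zero variance or
    fewer than 3 pairs are available.
    """
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
    n = len(pairs)
    if n < 3:
        return math.nan, n
    x, y = pairs[:, 0], pairs[:, 1]
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan, n
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r, n
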
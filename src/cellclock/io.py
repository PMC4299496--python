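"""File formats: CSV/JSON artifacts with lossless round-trips.

All CSVs carry a header row, UTF-8, '.' decimal; times in hours, angles in
radians.  Event tables ship with a JSON sidecar holding the observation
window and seed metadata.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .likelihood import FitConfig
from .model import ModelParams
from .simulate import EventSequence
from .synth import RenderSpec, TraceSet
from .syncstats import SyncSeries

__all__ = ["write_events", "read_events", "write_traces", "read_traces",
           "write_intervals", "read_intervals", "write_params", "read_params",
           "write_fit_result", "write_sync", "read_sync", "load_config",
           "sidecar_path"]


def sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json")


class FormatError(ValueError):
    """Malformed artifact file."""


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")


def write_events(events: list[EventSequence], path, meta: dict | None = None):
    rows = [(ev.cell_id, t, k) for ev in events for t, k in ev.events]
    df = pd.DataFrame(rows, columns=["cell_id", "time_h", "event_type"])
    df.to_csv(path, index=False)
    windows = {ev.cell_id: [ev.t_start, ev.t_end] for ev in events}
    side = {"windows": windows, "meta": meta or {}}
    sidecar_path(path).write_text(json.dumps(side, indent=1) + "\n")


def read_events(path) -> list[EventSequence]:
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "time_h", "event_type"], path)
    bad = ~df["event_type"].isin(["p", "d"])
    if bad.any():
        row = df.index[bad][0]
        raise FormatError(f"{path}: row {row}: event_type must be 'p' or 'd'")
    windows = {}
    sp = sidecar_path(path)
    if sp.exists():
        windows = json.loads(sp.read_text()).get("windows", {})
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        w = windows.get(str(cid))
        ev = [(float(t), str(k)) for t, k in zip(grp["time_h"], grp["event_type"])]
        out.append(EventSequence(
            cell_id=str(cid), events=ev,
            t_start=w[0] if w else 0.0,
            t_end=w[1] if w else (max(t for t, _ in ev) if ev else math.inf)))
    return out


def write_traces(traces: TraceSet, path, write_truth: bool = True):
    rows = []
    for i, cid in enumerate(traces.cell_ids):
        for j, t in enumerate(traces.times):
            rows.append((cid, t, traces.yfp[i, j], traces.nuc_size[i, j]))
    pd.DataFrame(rows, columns=["cell_id", "time_h", "yfp", "nuc_size"]) \
        .to_csv(path, index=False)
    if write_truth and traces.events is not None:
        write_events(traces.events, Path(path).with_suffix(".events.csv"),
                     meta={"fixture": traces.fixture, "seed": traces.seed})
    if traces.params is not None:
        traces.params.to_json(Path(path).with_suffix(".params.json"))


def read_traces(path) -> TraceSet:
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "time_h", "yfp", "nuc_size"], path)
    cell_ids = list(dict.fromkeys(df["cell_id"].astype(str)))
    times = None
    yfp, nuc = [], []
    for cid in cell_ids:
        grp = df[df["cell_id"].astype(str) == cid]
        t = grp["time_h"].to_numpy(dtype=float)
        if times is None:
            times = t
        elif len(t) != len(times) or not np.allclose(t, times):
            raise FormatError(f"{path}: cell {cid}: inconsistent time grid")
        yfp.append(grp["yfp"].to_numpy(dtype=float))
        nuc.append(grp["nuc_size"].to_numpy(dtype=float))
    return TraceSet(times=times, cell_ids=cell_ids, yfp=np.array(yfp),
                    nuc_size=np.array(nuc))


def write_intervals(table: pd.DataFrame, path):
    table.to_csv(path, index=False)


def read_intervals(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "kind", "duration"], path)
    return df


def write_params(params: ModelParams, path):
    params.to_json(path)


def read_params(path) -> ModelParams:
    return ModelParams.from_json(path)


def write_fit_result(result, path):
    Path(path).write_text(json.dumps(result.to_dict(), indent=1) + "\n")


def write_sync(series: SyncSeries, path):
    pd.DataFrame({
        "time_h": series.times,
        "R_theta": series.R_theta, "R_phi": series.R_phi, "R_rel": series.R_rel,
        "sd_theta": series.sd_theta, "sd_phi": series.sd_phi,
        "sd_rel": series.sd_rel,
    }).to_csv(path, index=False)


def read_sync(path) -> SyncSeries:
    df = pd.read_csv(path)
    _require_columns(df, ["time_h", "R_theta", "R_phi", "R_rel"], path)
    return SyncSeries(times=df["time_h"].to_numpy(),
                      R_theta=df["R_theta"].to_numpy(),
                      R_phi=df["R_phi"].to_numpy(),
                      R_rel=df["R_rel"].to_numpy(),
                      sd_theta=df.get("sd_theta", pd.Series()).to_numpy(),
                      sd_phi=df.get("sd_phi", pd.Series()).to_numpy(),
                      sd_rel=df.get("sd_rel", pd.Series()).to_numpy(),
                      n_cells=-1)


def load_config(path) -> FitConfig:
    """FitConfig from a YAML file with a versioned schema key."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    doc.pop("schema", None)
    fields = {f.name for f in dataclasses.fields(FitConfig)}
    unknown = set(doc) - fields
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("n_bumps", "free"):
        if key in doc and isinstance(doc[key], list):
            doc[key] = tuple(doc[key])
    return FitConfig(**doc)
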
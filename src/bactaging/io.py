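"""Tidy delimited-table input/output for traces, truths and results.

All tables are plain CSV.  Trace tables are long format with columns
``cell_id, strain, medium, time_h, length_um, width_um, gfp_au, pi_au``;
growth tables are ``strain, medium, replicate, time_h, od600``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import GrowthCurve
from .lineage import LineageTrace
from .synth import GroundTruth

__all__ = [
    "traces_to_frame",
    "write_traces",
    "read_traces",
    "truths_to_frame",
    "write_truths",
    "growth_curves_to_frame",
    "write_growth_curves",
    "read_growth_curves",
]


def traces_to_frame(traces: Sequence[LineageTrace]) -> pd.DataFrame:
    frames = []
    for tr in traces:
        n = tr.n_frames
        frames.append(pd.DataFrame({
            "cell_id": np.repeat(tr.cell_id, n),
            "strain": np.repeat(tr.strain, n),
            "medium": np.repeat(tr.medium, n),
            "time_h": tr.times,
            "length_um": tr.length,
            "width_um": tr.width if tr.width is not None else np.nan,
            "gfp_au": tr.gfp if tr.gfp is not None else np.nan,
            "pi_au": tr.pi if tr.pi is not None else np.nan,
        }))
    return pd.concat(frames, ignore_index=True)


def write_traces(traces: Sequence[LineageTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[LineageTrace]:
    df = pd.read_csv(path)
    required = {"cell_id", "time_h", "length_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace table must have columns {sorted(required)}")
    traces = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("time_h")

        def channel(col):
            if col not in g.columns or g[col].isna().all():
                return None
            return g[col].to_numpy(dtype=float)

        traces.append(LineageTrace(
            cell_id=str(cell_id),
            times=g["time_h"].to_numpy(dtype=float),
            length=g["length_um"].to_numpy(dtype=float),
            width=channel("width_um"),
            gfp=channel("gfp_au"),
            pi=channel("pi_au"),
            strain=str(g["strain"].iloc[0]) if "strain" in g.columns else "",
            medium=str(g["medium"].iloc[0]) if "medium" in g.columns else ""))
    return traces


def truths_to_frame(truths: Sequence[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_id": gt.cell_id,
        "lifespan_h": gt.lifespan,
        "n_generations": gt.n_generations,
        "phenotype": gt.phenotype,
        "prl_h": gt.prl_duration,
        "lysis_time_h": gt.lysis_time,
        "censored": gt.censored,
        "division_times_h": ";".join(f"{t:.6f}" for t in gt.division_times),
    } for gt in truths])


def write_truths(truths: Sequence[GroundTruth], path: str | Path) -> None:
    truths_to_frame(truths).to_csv(path, index=False)


def growth_curves_to_frame(curves: Sequence[GrowthCurve]) -> pd.DataFrame:
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "strain": np.repeat(c.strain, c.times.size),
            "medium": np.repeat(c.medium, c.times.size),
            "replicate": np.repeat(c.replicate, c.times.size),
            "time_h": c.times,
            "od600": c.od,
        }))
    return pd.concat(frames, ignore_index=True)


def write_growth_curves(curves: Sequence[GrowthCurve],
                        path: str | Path) -> None:
    growth_curves_to_frame(curves).to_csv(path, index=False)


def read_growth_curves(path: str | Path) -> list[GrowthCurve]:
    df = pd.read_csv(path)
    required = {"strain", "medium", "time_h", "od600"}
    if not required.issubset(df.columns):
        raise ValueError(f"growth table must have columns {sorted(required)}")
    if "replicate" not in df.columns:
        df = df.assign(replicate="r1")
    curves = []
    for (strain, medium, rep), g in df.groupby(
            ["strain", "medium", "replicate"], sort=False):
        g = g.sort_values("time_h")
        curves.append(GrowthCurve(
            strain=str(strain), medium=str(medium), replicate=str(rep),
            times=g["time_h"].to_numpy(dtype=float),
            od=g["od600"].to_numpy(dtype=float)))
    return curves
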
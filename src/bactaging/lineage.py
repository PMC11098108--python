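"""Single-cell lineage segmentation and per-cycle growth statistics.

A mother-machine trace is a sawtooth of cell length over time: exponential
elongation within each cell cycle, reset by division.  This module detects
division events from frame-to-frame length drops, cuts the trace into cell
cycles, and extracts for each completed cycle its birth length (BL),
exponential elongation rate (EER, the slope of ln length vs time), and
doubling rate (DR, the inverse cycle duration).  Per-generation statistics
can then be aligned to the last replicative cycle — generation zero is the
last cycle with growth above a small threshold — to expose end-of-life
changes that calendar-time averaging would wash out, since a trapped cell's
age at trap entry is unknowable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LineageTrace",
    "CellCycle",
    "CycleExtraction",
    "detect_divisions",
    "extract_cycles",
    "align_to_last_replicative",
    "population_summary",
]


@dataclass
class LineageTrace:
    """One cell's multi-channel time series from the mother machine.

    ``times`` in hours, ``length`` in micrometres; ``gfp`` is the
    chromosome-label fluorescence (e.g. GFP-Fis) and ``pi`` the viability-dye
    (propidium iodide) channel, both in arbitrary units.
    """

    cell_id: str
    times: np.ndarray
    length: np.ndarray
    width: np.ndarray | None = None
    gfp: np.ndarray | None = None
    pi: np.ndarray | None = None
    strain: str = ""
    medium: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("times must be a non-empty 1-d array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.length.shape != self.times.shape:
            raise ValueError("length must match times in shape")
        if np.any(self.length <= 0):
            raise ValueError("length must be strictly positive")
        for name in ("width", "gfp", "pi"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                if ch.shape != self.times.shape:
                    raise ValueError(f"{name} must match times in shape")
                setattr(self, name, ch)

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass
class CellCycle:
    """One birth-to-division interval of a tracked cell."""

    cell_id: str
    birth_time: float
    division_time: float
    birth_length: float
    final_length: float
    eer: float           # exponential elongation rate, 1/h
    dr: float            # doubling rate = 1/cycle duration, 1/h
    n_frames: int
    partial_start: bool = False  # truncated by movie/trap-entry start
    terminal: bool = False       # final non-dividing segment
    generation_index: int | None = None

    @property
    def duration(self) -> float:
        return self.division_time - self.birth_time


@dataclass
class CycleExtraction:
    """Cycles cut from one trace: completed interior cycles, the flagged
    partial first segment, the terminal non-dividing segment, and the count
    of segments dropped for having too few frames."""

    cell_id: str
    cycles: list          # completed cycles usable for BL/EER/DR statistics
    first_partial: CellCycle | None
    terminal: CellCycle | None
    n_dropped_short: int
    warning: str | None = None


def detect_divisions(trace: LineageTrace, drop_fraction: float = 0.25) -> np.ndarray:
    """Indices of post-division frames.

    A division is any frame-to-frame relative length decrease of at least
    ``drop_fraction``.  Divisions roughly halve the length while measurement
    noise rarely produces 25% single-frame drops, hence the default.
    """
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must be in (0, 1)")
    if trace.n_frames < 2:
        raise ValueError("need at least 2 frames to detect divisions")
    L = trace.length
    rel_drop = -np.diff(L) / L[:-1]
    return np.flatnonzero(rel_drop >= drop_fraction) + 1


def _segment_stats(trace: LineageTrace, lo: int, hi: int):
    """ln-linear least-squares elongation rate over frames [lo, hi)."""
    t = trace.times[lo:hi]
    y = np.log(trace.length[lo:hi])
    if t.size < 2:
        return 0.0
    tc = t - t.mean()
    denom = np.dot(tc, tc)
    if denom == 0:
        return 0.0
    return float(np.dot(tc, y - y.mean()) / denom)


def extract_cycles(trace: LineageTrace, divisions: np.ndarray,
                   min_frames: int = 4) -> CycleExtraction:
    """Cut a trace at the division indices into :class:`CellCycle` objects.

    The segment before the first division is flagged partial (the cell's age
    at trap entry is unknown) and the final non-dividing segment is retained
    separately as the terminal segment; neither enters BL/EER/DR statistics.
    Interior segments with fewer than ``min_frames`` frames are dropped and
    counted.  EER is the least-squares slope of ln(length) vs time over the
    segment's frames; DR is the inverse of the cycle duration measured
    between consecutive post-division frames.
    """
    divisions = np.asarray(divisions, dtype=int)
    if divisions.size and (np.any(np.diff(divisions) <= 0)
                           or divisions[0] < 1
                           or divisions[-1] >= trace.n_frames):
        raise ValueError("divisions must be strictly increasing valid indices")

    warning = None
    if divisions.size == 0:
        # no divisions: the whole trace is one segment; report it as the
        # terminal segment (it never completed) unless it shows no growth
        eer = _segment_stats(trace, 0, trace.n_frames)
        seg = CellCycle(
            cell_id=trace.cell_id,
            birth_time=float(trace.times[0]),
            division_time=float(trace.times[-1]),
            birth_length=float(trace.length[0]),
            final_length=float(trace.length[-1]),
            eer=eer, dr=np.nan, n_frames=trace.n_frames,
            partial_start=True, terminal=True)
        if eer <= 0:
            warning = "no divisions and no terminal growth"
        return CycleExtraction(trace.cell_id, [], None, seg, 0, warning)

    bounds = np.concatenate(([0], divisions, [trace.n_frames]))
    cycles: list[CellCycle] = []
    first_partial = None
    terminal = None
    n_dropped = 0
    for j in range(len(bounds) - 1):
        lo, hi = int(bounds[j]), int(bounds[j + 1])
        is_first = j == 0
        is_last = j == len(bounds) - 2
        if hi - lo < min_frames and not is_first and not is_last:
            n_dropped += 1
            continue
        if is_last:
            birth_t = float(trace.times[lo])
            div_t = float(trace.times[-1])
            dr = np.nan
        else:
            birth_t = float(trace.times[lo])
            div_t = float(trace.times[hi])
            dr = 1.0 / (div_t - birth_t)
        cyc = CellCycle(
            cell_id=trace.cell_id,
            birth_time=birth_t,
            division_time=div_t,
            birth_length=float(trace.length[lo]),
            final_length=float(trace.length[hi - 1]),
            eer=_segment_stats(trace, lo, hi),
            dr=dr,
            n_frames=hi - lo,
            partial_start=is_first,
            terminal=is_last)
        if is_first:
            first_partial = cyc
        elif is_last:
            terminal = cyc
        else:
            cycles.append(cyc)
    return CycleExtraction(trace.cell_id, cycles, first_partial, terminal,
                           n_dropped, warning)


def align_to_last_replicative(cycles_by_cell: Mapping[str, Sequence[CellCycle]],
                              eps_growth: float = 0.01
                              ) -> tuple[pd.DataFrame, dict, int]:
    """Index each cell's cycles relative to its last replicative cycle.

    Generation 0 is the last cycle with EER above ``eps_growth`` (the
    operational meaning of "nonzero growth rate"); earlier cycles get
    indices -1, -2, ...  Returns per-index aggregates (mean, SD, n) of BL,
    EER and DR, the reference means computed over all generations except the
    last three (indices <= -3), and the count of cells excluded for having
    no growing cycle.  Alignment is a pure re-indexing: the multiset of
    cycles is unchanged.
    """
    if eps_growth < 0:
        raise ValueError("eps_growth must be >= 0")
    rows = []
    n_excluded = 0
    for cell_id, cycles in cycles_by_cell.items():
        if len(cycles) == 0:
            n_excluded += 1
            continue
        growing = [i for i, c in enumerate(cycles) if c.eer > eps_growth]
        if not growing:
            n_excluded += 1
            continue
        zero = growing[-1]
        for i, c in enumerate(cycles):
            c.generation_index = i - zero
            rows.append({"cell_id": cell_id, "generation_index": i - zero,
                         "bl": c.birth_length, "eer": c.eer, "dr": c.dr})
    if not rows:
        raise ValueError("no cells with a growing cycle to align")
    df = pd.DataFrame(rows)
    agg = df.groupby("generation_index").agg(
        bl_mean=("bl", "mean"), bl_sd=("bl", "std"),
        eer_mean=("eer", "mean"), eer_sd=("eer", "std"),
        dr_mean=("dr", "mean"), dr_sd=("dr", "std"),
        n=("bl", "size"))
    ref_rows = df[df["generation_index"] <= -3]
    if len(ref_rows):
        reference = {"bl": float(ref_rows["bl"].mean()),
                     "eer": float(ref_rows["eer"].mean()),
                     "dr": float(ref_rows["dr"].mean())}
    else:
        reference = {"bl": np.nan, "eer": np.nan, "dr": np.nan}
    return agg, reference, n_excluded


def population_summary(cycles: pd.DataFrame,
                       stats: Sequence[str] = ("dr", "bl", "width")
                       ) -> pd.DataFrame:
    """Mean, population SD and CV of per-cycle statistics per strain x medium.

    CV = SD/mean quantifies growth-rate heterogeneity; it is reported as
    missing when the mean is zero.  Input is a tidy cycle table with at
    least the requested statistic columns; grouping columns default to
    (strain, medium) when present.
    """
    if len(cycles) < 2:
        raise ValueError("need at least 2 cycles for a population summary")
    group_cols = [c for c in ("strain", "medium") if c in cycles.columns]
    present = [s for s in stats if s in cycles.columns]
    if not present:
        raise ValueError(f"none of the statistics {stats} found in table")

    def summarize(g):
        out = {}
        for s in present:
            vals = g[s].dropna().to_numpy(dtype=float)
            mean = vals.mean() if vals.size else np.nan
            sd = vals.std(ddof=0) if vals.size else np.nan
            out[f"{s}_mean"] = mean
            out[f"{s}_sd"] = sd
            out[f"{s}_cv"] = sd / mean if mean not in (0.0,) and np.isfinite(mean) and mean != 0 else np.nan
        out["n"] = len(g)
        return pd.Series(out)

    if group_cols:
        return cycles.groupby(group_cols).apply(summarize, include_groups=False)
    return summarize(cycles).to_frame().T
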
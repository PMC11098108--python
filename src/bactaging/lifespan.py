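"""aRL/PRL lifespan decomposition and death-phenotype classification.

A trapped cell's observable lifespan splits into the *apparent replicative
lifespan* (aRL, the proliferation period — "apparent" because divisions
before trap entry are invisible) and the *post-replicative lifespan* (PRL,
from the last division or growth arrest until the viability dye enters the
permeabilized membrane, marking lysis).

Death phenotypes are assigned from morphology and the chromosome-label
channel, in a fixed decision order:

* **excluded** — the chromosome signal disappears during the aRL well
  before the final cycle while the cell keeps dividing: a plasmid-loss
  artifact of the labelling system, not a death mode;
* **II** — replicative crisis: the cell filaments, i.e. its length during
  the final cycle or PRL exceeds ``filament_factor`` (default 3) times the
  cohort mean length;
* **Ia** — the chromosome signal collapses in a single frame coincident
  with the last division (chromosome lost to the sibling);
* **Ib** — residual class: chromosome retained, decaying only gradually
  during the PRL.

Cells whose lysis is censored by the movie end keep the label
``I-unresolved`` unless they are already filamented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .lineage import LineageTrace

__all__ = [
    "LifespanRecord",
    "detect_pi_entry",
    "segment_lifespan",
    "classify_phenotype",
    "phenotype_fractions",
    "records_to_frame",
]

RESOLVED_PHENOTYPES = ("Ia", "Ib", "II")


@dataclass
class LifespanRecord:
    """Per-cell lifespan decomposition.

    Durations in hours relative to the trace start; for uncensored cells
    ``arl_h + prl_h`` equals the lysis time.
    """

    cell_id: str
    arl_h: float
    arl_generations: int
    prl_h: float
    lysis_time: float | None
    censored: bool
    phenotype: str | None = None
    strain: str = ""
    medium: str = ""


def detect_pi_entry(trace: LineageTrace, k_sigma: float = 5.0,
                    sustain_frames: int = 2, n_baseline: int = 30
                    ) -> float | None:
    """First time the viability dye exceeds baseline mean + k_sigma * SD
    for ``sustain_frames`` consecutive frames; None if never (censored).

    The baseline is each cell's own first ``n_baseline`` frames, so
    per-trap illumination offsets cancel; requiring a sustained exceedance
    rejects single-frame speckle.  The default 30-frame window keeps the
    baseline SD estimate tight enough that the k-sigma threshold retains
    its nominal false-positive rate over movie-length records (a 10-frame
    window underestimates the SD often enough to fire spuriously).
    """
    if trace.pi is None:
        raise ValueError("trace has no PI channel")
    if k_sigma <= 0 or sustain_frames < 1:
        raise ValueError("k_sigma must be > 0 and sustain_frames >= 1")
    if n_baseline < 10:
        raise ValueError("need at least 10 baseline frames")
    if trace.n_frames < n_baseline + sustain_frames:
        raise ValueError(f"need >= {n_baseline + sustain_frames} frames")
    base = trace.pi[:n_baseline]
    threshold = base.mean() + k_sigma * base.std(ddof=1)
    above = trace.pi > threshold
    if sustain_frames > 1:
        run = np.convolve(above.astype(int),
                          np.ones(sustain_frames, dtype=int), mode="valid")
        hits = np.flatnonzero(run == sustain_frames)
    else:
        hits = np.flatnonzero(above)
    if hits.size == 0:
        return None
    return float(trace.times[hits[0]])


def segment_lifespan(trace: LineageTrace, divisions: np.ndarray,
                     lysis_time: float | None, eps_growth: float = 0.01
                     ) -> LifespanRecord:
    """Split a trace into aRL and PRL.

    The aRL ends at the last detected division; for traces with no
    division it ends at the last frame showing relative growth above
    ``eps_growth``.  PRL runs from the aRL end to lysis; when lysis was
    never observed the PRL is a lower bound and the record is censored.
    """
    divisions = np.asarray(divisions, dtype=int)
    t0 = float(trace.times[0])
    if lysis_time is not None and lysis_time < t0:
        raise ValueError("lysis before the first frame")
    if divisions.size:
        arl_end = float(trace.times[divisions[-1]])
    else:
        # frame-wise growth rate d(ln L)/dt
        rate = np.diff(np.log(trace.length)) / np.diff(trace.times)
        growing = np.flatnonzero(rate > eps_growth)
        arl_end = float(trace.times[growing[-1] + 1]) if growing.size else t0
    censored = lysis_time is None
    end = float(trace.times[-1]) if censored else float(lysis_time)
    if end < arl_end:
        # dye entered before the last division was scored; clamp PRL at 0
        arl_end = end
    return LifespanRecord(
        cell_id=trace.cell_id,
        arl_h=arl_end - t0,
        arl_generations=int(divisions.size),
        prl_h=end - arl_end,
        lysis_time=None if censored else end,
        censored=censored,
        strain=trace.strain,
        medium=trace.medium)


def _first_sustained_low(values: np.ndarray, threshold: float,
                         sustain: int = 2) -> int | None:
    below = values < threshold
    run = np.convolve(below.astype(int), np.ones(sustain, dtype=int),
                      mode="valid")
    hits = np.flatnonzero(run == sustain)
    return int(hits[0]) if hits.size else None


def classify_phenotype(trace: LineageTrace, record: LifespanRecord,
                       divisions: np.ndarray, mean_length: float,
                       filament_factor: float = 3.0,
                       gfp_drop_fraction: float = 0.5,
                       plasmid_loss_fraction: float = 0.25,
                       n_baseline: int = 10) -> str:
    """Assign the death phenotype for one segmented cell.

    ``mean_length`` is the cohort mean cell length for the same strain and
    medium (filamentation is defined relative to it).  See the module
    docstring for the decision order.
    """
    if filament_factor <= 0:
        raise ValueError("filament_factor must be > 0")
    if not 0 < gfp_drop_fraction < 1:
        raise ValueError("gfp_drop_fraction must be in (0, 1)")
    if mean_length <= 0:
        raise ValueError("mean_length must be > 0")
    divisions = np.asarray(divisions, dtype=int)
    gfp = trace.gfp

    # (i) plasmid-loss exclusion: label signal lost before the final cycle
    # while divisions continued
    if gfp is not None and divisions.size >= 2:
        baseline = float(np.median(gfp[:n_baseline]))
        if baseline > 0:
            i_low = _first_sustained_low(
                gfp, plasmid_loss_fraction * baseline, sustain=2)
            if i_low is not None and i_low < divisions[-2]:
                return "excluded"

    # (ii) filamentation in the final cycle or PRL
    start = int(divisions[-2]) if divisions.size >= 2 else 0
    if float(trace.length[start:].max()) > filament_factor * mean_length:
        return "II"

    if record.censored:
        return "I-unresolved"
    if gfp is None:
        return "I-unresolved"

    # (iii) sudden single-frame chromosome loss at the last division
    if divisions.size:
        i_div = int(divisions[-1])
        for j in range(max(i_div - 1, 1), min(i_div + 2, trace.n_frames)):
            prev = gfp[j - 1]
            if prev > 0 and (prev - gfp[j]) / prev >= gfp_drop_fraction:
                return "Ia"

    # (iv) residual: chromosome retained through the lifespan
    return "Ib"


def records_to_frame(records: Sequence[LifespanRecord]) -> pd.DataFrame:
    """Tidy lifespan table (one row per cell)."""
    return pd.DataFrame([{
        "cell_id": r.cell_id, "strain": r.strain, "medium": r.medium,
        "arl_h": r.arl_h, "arl_generations": r.arl_generations,
        "prl_h": r.prl_h, "lysis_time": r.lysis_time,
        "censored": r.censored, "phenotype": r.phenotype,
    } for r in records])


def phenotype_fractions(records: pd.DataFrame) -> pd.DataFrame:
    """Phenotype fractions per strain x medium over non-excluded cells.

    Fractions sum to 1 within each group; plasmid-loss exclusions are
    reported as a separate count.  Groups containing only excluded cells
    yield missing fractions with the count preserved.
    """
    if "phenotype" not in records.columns:
        raise ValueError("records table needs a 'phenotype' column")
    group_cols = [c for c in ("strain", "medium") if c in records.columns]
    labels = list(RESOLVED_PHENOTYPES) + ["I-unresolved"]

    def summarize(g):
        excluded = int((g["phenotype"] == "excluded").sum())
        kept = g[g["phenotype"] != "excluded"]
        out = {}
        denom = len(kept)
        for lab in labels:
            out[f"frac_{lab}"] = (float((kept["phenotype"] == lab).sum())
                                  / denom) if denom else np.nan
        out["n"] = denom
        out["n_excluded"] = excluded
        return pd.Series(out)

    if group_cols:
        return records.groupby(group_cols).apply(summarize,
                                                 include_groups=False)
    return summarize(records).to_frame().T
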
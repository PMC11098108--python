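"""End-to-end helpers chaining segmentation, lifespans and classification.

These convenience functions run the per-cell pipeline (division detection
-> cycle extraction -> PI entry -> aRL/PRL segmentation -> phenotype) over
a cohort of traces and return tidy tables, which is what the CLI and the
worked examples use.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .lineage import (CycleExtraction, LineageTrace, detect_divisions,
                      extract_cycles)
from .lifespan import (LifespanRecord, classify_phenotype, detect_pi_entry,
                       records_to_frame, segment_lifespan)

__all__ = ["analyze_cohort", "cycles_to_frame", "cohort_mean_length"]


def cohort_mean_length(traces: Sequence[LineageTrace],
                       divisions: Sequence[np.ndarray] | None = None
                       ) -> float:
    """Average cell length in the cohort, the filamentation reference.

    The average is taken over each cell's replicative frames (up to its
    last detected division): post-replicative and filamented frames would
    otherwise inflate the reference that defines filamentation itself.
    Cells with no detected division contribute all frames.  Pass per
    strain x medium cohorts separately.
    """
    if divisions is None:
        divisions = [detect_divisions(tr) for tr in traces]
    parts = []
    for tr, div in zip(traces, divisions):
        end = int(div[-1]) + 1 if len(div) else tr.n_frames
        parts.append(tr.length[:end])
    return float(np.mean(np.concatenate(parts)))


def cycles_to_frame(extractions: Sequence[CycleExtraction],
                    traces: Sequence[LineageTrace]) -> pd.DataFrame:
    """Tidy table of completed cycles (one row per cycle)."""
    meta = {tr.cell_id: tr for tr in traces}
    rows = []
    for ex in extractions:
        tr = meta.get(ex.cell_id)
        width = float(np.mean(tr.width)) if tr is not None and tr.width is not None else np.nan
        for c in ex.cycles:
            rows.append({
                "cell_id": ex.cell_id,
                "strain": tr.strain if tr is not None else "",
                "medium": tr.medium if tr is not None else "",
                "generation_index": c.generation_index,
                "birth_time": c.birth_time,
                "division_time": c.division_time,
                "bl": c.birth_length,
                "eer": c.eer,
                "dr": c.dr,
                "width": width,
            })
    return pd.DataFrame(rows)


def analyze_cohort(traces: Sequence[LineageTrace],
                   drop_fraction: float = 0.25,
                   eps_growth: float = 0.01,
                   k_sigma: float = 5.0,
                   sustain_frames: int = 2,
                   filament_factor: float = 3.0,
                   gfp_drop_fraction: float = 0.5,
                   mean_length: float | None = None
                   ) -> tuple[pd.DataFrame, list[CycleExtraction]]:
    """Run the full single-cell pipeline over a cohort.

    Returns the lifespan table (with phenotypes) and the per-cell cycle
    extractions.  ``mean_length`` defaults to the cohort mean, which is the
    reference for the filamentation rule.
    """
    all_divisions = [detect_divisions(tr, drop_fraction=drop_fraction)
                     for tr in traces]
    if mean_length is None:
        mean_length = cohort_mean_length(traces, all_divisions)
    records: list[LifespanRecord] = []
    extractions: list[CycleExtraction] = []
    for tr, divisions in zip(traces, all_divisions):
        extractions.append(extract_cycles(tr, divisions))
        lysis = detect_pi_entry(tr, k_sigma=k_sigma,
                                sustain_frames=sustain_frames) \
            if tr.pi is not None else None
        rec = segment_lifespan(tr, divisions, lysis, eps_growth=eps_growth)
        rec.phenotype = classify_phenotype(
            tr, rec, divisions, mean_length,
            filament_factor=filament_factor,
            gfp_drop_fraction=gfp_drop_fraction)
        records.append(rec)
    return records_to_frame(records), extractions
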
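"""1.5-LOD-drop support intervals and their aggregation across weeks.

The weekly interval around a QTL peak is the contiguous run of markers whose
LOD stays within ``drop`` of the top marker's LOD, extended outward to the
first marker beyond the run on each side (or the chromosome's terminal marker
when the run reaches the end). Because the run must be contiguous, disjoint
secondary peaks never extend an interval. The final QTL region takes the
smallest start and the highest end across the selected weeks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .scan import WeeklyScanResult


@dataclass(frozen=True)
class WeeklyInterval:
    week: int
    chromosome: str
    top_marker: str
    top_lod: float
    start_bp: int
    end_bp: int
    significant: bool = False


@dataclass(frozen=True)
class AggregateQtl:
    chromosome: str
    final_start_bp: int
    final_end_bp: int
    top_marker: str
    top_lod: float
    significant_weeks: tuple
    weeks_used: tuple


def lod_drop_interval(week_scan: WeeklyScanResult, chromosome: str,
                      drop: float = 1.5, threshold: Optional[float] = None,
                      marker_ids: Optional[Sequence[str]] = None
                      ) -> WeeklyInterval:
    """Walk-outward LOD-drop interval on one chromosome for one week.

    ``marker_ids`` optionally restricts the walk to a marker subset (the
    study design computes the drop on the array-genotyped stage only).
    ``threshold`` sets the interval's ``significant`` flag from the top LOD.
    """
    t = week_scan.table
    sel = (t["chromosome"] == chromosome) & t["tested"]
    if marker_ids is not None:
        sel &= t["marker_id"].isin(set(marker_ids))
    sub = t[sel].sort_values("position_bp")
    if sub.empty:
        raise ValueError(f"no tested markers on chromosome {chromosome}")
    pos = sub["position_bp"].to_numpy()
    lod = sub["lod"].to_numpy()
    ids = sub["marker_id"].to_numpy()
    # top marker; ties by smaller p (== higher lod) then smaller bp
    top = int(np.lexsort((pos, -lod))[0])
    cut = lod[top] - drop
    lo = top
    while lo - 1 >= 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = top
    while hi + 1 < len(lod) and lod[hi + 1] >= cut:
        hi += 1
    start = pos[lo - 1] if lo > 0 else pos[0]
    end = pos[hi + 1] if hi < len(lod) - 1 else pos[-1]
    significant = bool(threshold is not None and lod[top] >= threshold)
    return WeeklyInterval(week=week_scan.week, chromosome=chromosome,
                          top_marker=str(ids[top]), top_lod=float(lod[top]),
                          start_bp=int(start), end_bp=int(end),
                          significant=significant)


def aggregate_intervals(weekly: Sequence[WeeklyInterval],
                        only_significant: bool = True) -> AggregateQtl:
    """Union of weekly intervals: smallest start, highest end.

    By default only significant weeks contribute to the span (a flat-profile
    week would otherwise widen the region to the whole chromosome); pass
    ``only_significant=False`` to span all weeks. Non-contributing weeks stay
    listed in the record.
    """
    if not weekly:
        raise ValueError("no weekly intervals given")
    chroms = {w.chromosome for w in weekly}
    if len(chroms) != 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    selected = [w for w in weekly if w.significant] if only_significant else list(weekly)
    if not selected:
        raise ValueError("no significant weeks to aggregate")
    best = max(selected, key=lambda w: (w.top_lod, -w.start_bp))
    return AggregateQtl(
        chromosome=best.chromosome,
        final_start_bp=min(w.start_bp for w in selected),
        final_end_bp=max(w.end_bp for w in selected),
        top_marker=best.top_marker, top_lod=best.top_lod,
        significant_weeks=tuple(w.week for w in weekly if w.significant),
        weeks_used=tuple(w.week for w in selected))


def significance_span(weekly: Sequence[WeeklyInterval],
                      threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of consecutive weeks whose top LOD reaches the threshold.

    Input must be sorted by week; a gap in the week numbering breaks a run.
    """
    runs: list[tuple[int, int]] = []
    current: Optional[list[int]] = None
    prev_week = None
    for w in weekly:
        if prev_week is not None and w.week < prev_week:
            raise ValueError("weekly intervals must be sorted by week")
        hit = w.top_lod >= threshold
        contiguous = prev_week is not None and w.week == prev_week + 1
        if hit:
            if current is not None and contiguous:
                current[1] = w.week
            else:
                if current is not None:
                    runs.append(tuple(current))
                current = [w.week, w.week]
        else:
            if current is not None:
                runs.append(tuple(current))
                current = None
        prev_week = w.week
    if current is not None:
        runs.append(tuple(current))
    return runs
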
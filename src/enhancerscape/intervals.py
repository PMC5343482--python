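"""Genomic interval arithmetic on (chrom, start, end) DataFrames.

All coordinates are 0-based, half-open.  Intervals are held in plain pandas
DataFrames with at least ``chrom``, ``start`` and ``end`` columns; functions
return new frames sorted by (chrom, start) and never mutate their inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CORE_COLS = ["chrom", "start", "end"]


def as_frame(intervals) -> pd.DataFrame:
    """Coerce a sequence of (chrom, start, end[, ...]) tuples to a frame."""
    if isinstance(intervals, pd.DataFrame):
        return intervals
    return pd.DataFrame(list(intervals), columns=CORE_COLS)


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Union of intervals; intervals separated by <= ``gap`` bp are joined.

    With ``gap=0`` touching intervals ([0,10) and [10,20)) merge, matching the
    half-open convention.
    """
    if len(df) == 0:
        return pd.DataFrame(columns=CORE_COLS)
    df = sort_intervals(df[CORE_COLS])
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        run_start = starts[0]
        run_end = ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s - run_end <= gap:
                run_end = max(run_end, e)
            else:
                out.append((chrom, run_start, run_end))
                run_start, run_end = s, e
        out.append((chrom, run_start, run_end))
    return pd.DataFrame(out, columns=CORE_COLS)


def subtract_intervals(df: pd.DataFrame, mask: pd.DataFrame) -> pd.DataFrame:
    """Portions of ``df`` intervals not covered by ``mask`` intervals."""
    if len(df) == 0:
        return pd.DataFrame(columns=CORE_COLS)
    if len(mask) == 0:
        return sort_intervals(df[CORE_COLS].copy())
    mask = merge_intervals(mask)
    out = []
    mask_by_chrom = dict(tuple(mask.groupby("chrom", sort=False)))
    for row in sort_intervals(df[CORE_COLS]).itertuples(index=False):
        sub = mask_by_chrom.get(row.chrom)
        if sub is None:
            out.append((row.chrom, row.start, row.end))
            continue
        cur = row.start
        for ms, me in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            if me <= cur:
                continue
            if ms >= row.end:
                break
            if ms > cur:
                out.append((row.chrom, cur, min(ms, row.end)))
            cur = max(cur, me)
            if cur >= row.end:
                break
        if cur < row.end:
            out.append((row.chrom, cur, row.end))
    return pd.DataFrame(out, columns=CORE_COLS)


def coverage_components(interval_sets: list[pd.DataFrame], min_sets: int) -> pd.DataFrame:
    """Union components supported by intervals from >= ``min_sets`` input sets.

    Computes the union of all intervals, then keeps each union component iff
    intervals from at least ``min_sets`` distinct input sets overlap it.
    """
    nonempty = [s for s in interval_sets if len(s) > 0]
    if not nonempty:
        return pd.DataFrame(columns=CORE_COLS)
    union = merge_intervals(pd.concat([s[CORE_COLS] for s in nonempty]))
    support = np.zeros(len(union), dtype=int)
    for s in nonempty:
        hit = np.zeros(len(union), dtype=bool)
        idx_a, _ = overlap_pairs(union, s)
        hit[np.unique(idx_a)] = True
        support += hit
    return union[support >= min_sets].reset_index(drop=True)


def overlap_pairs(a: pd.DataFrame, b: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Indices (into a, into b) of all overlapping interval pairs."""
    ia: list[int] = []
    ib: list[int] = []
    if len(a) == 0 or len(b) == 0:
        return np.array(ia, dtype=int), np.array(ib, dtype=int)
    a_sorted = a[CORE_COLS].reset_index()
    b_sorted = b[CORE_COLS].reset_index()
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        sa = a_sorted[a_sorted["chrom"] == chrom].sort_values("start")
        sb = b_sorted[b_sorted["chrom"] == chrom].sort_values("start")
        bs = sb["start"].to_numpy()
        be = sb["end"].to_numpy()
        bi = sb["index"].to_numpy()
        for _, arow in sa.iterrows():
            lo = np.searchsorted(be, arow["start"], side="right")
            hi = np.searchsorted(bs, arow["end"], side="left")
            for j in range(lo, hi):
                if be[j] > arow["start"] and bs[j] < arow["end"]:
                    ia.append(arow["index"])
                    ib.append(bi[j])
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def interval_distance(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Minimal bp separation between two half-open intervals (0 if overlapping)."""
    if start_a < end_b and start_b < end_a:
        return 0
    if start_a >= end_b:
        return start_a - end_b
    return start_b - end_a


def nearest_distance(df: pd.DataFrame, points_or_intervals: pd.DataFrame) -> np.ndarray:
    """For each interval in ``df``, minimal separation to the other set.

    The second frame may carry intervals (start/end) or points (a ``pos``
    column, treated as width-1 intervals).  Distance is 0 for overlap and
    ``inf`` when the chromosome has no features.
    """
    other = points_or_intervals.copy()
    if "pos" in other.columns and "start" not in other.columns:
        other["start"] = other["pos"]
        other["end"] = other["pos"] + 1
    out = np.full(len(df), np.inf)
    by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in other.groupby("chrom", sort=False)
    }
    for i, row in enumerate(df.itertuples(index=False)):
        feats = by_chrom.get(row.chrom)
        if feats is None:
            continue
        starts, ends = feats
        gap_left = row.start - ends  # >= 0 when feature entirely left of row
        gap_right = starts - row.end
        d = np.maximum(np.maximum(gap_left, gap_right), 0)
        out[i] = d.min()
    return out
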
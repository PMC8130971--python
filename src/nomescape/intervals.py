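"""Sorted-array interval arithmetic on 0-based half-open coordinates.

All functions take parallel ``starts``/``ends`` numpy arrays for a single
chromosome; the per-chromosome bookkeeping lives with the callers, which hold
intervals in DataFrames with a ``chrom`` column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def merge_intervals(starts, ends):
    """Merge overlapping or touching intervals; returns sorted disjoint arrays."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def total_length(starts, ends) -> int:
    s, e = merge_intervals(starts, ends)
    return int((e - s).sum())


def intersect_length(a_starts, a_ends, b_starts, b_ends) -> int:
    """Total overlap in bases between two interval sets (each merged first)."""
    a_s, a_e = merge_intervals(a_starts, a_ends)
    b_s, b_e = merge_intervals(b_starts, b_ends)
    i = j = 0
    total = 0
    while i < len(a_s) and j < len(b_s):
        lo = max(a_s[i], b_s[j])
        hi = min(a_e[i], b_e[j])
        if lo < hi:
            total += hi - lo
        if a_e[i] < b_e[j]:
            i += 1
        else:
            j += 1
    return int(total)


def overlaps_any(q_starts, q_ends, ref_starts, ref_ends):
    """Boolean array: does each query interval overlap (>=1 bp) any reference?"""
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    r_s, r_e = merge_intervals(ref_starts, ref_ends)
    if r_s.size == 0:
        return np.zeros(q_starts.shape, dtype=bool)
    # reference interval that could overlap: the last one starting before q_end
    idx = np.searchsorted(r_s, q_ends, side="left") - 1
    hit = np.zeros(q_starts.shape, dtype=bool)
    ok = idx >= 0
    hit[ok] = r_e[idx[ok]] > q_starts[ok]
    return hit


def complement(starts, ends, chrom_length: int):
    """Intervals of [0, chrom_length) not covered by the input set."""
    s, e = merge_intervals(starts, ends)
    gap_s, gap_e = [], []
    cursor = 0
    for a, b in zip(s, e):
        if a > cursor:
            gap_s.append(cursor)
            gap_e.append(a)
        cursor = max(cursor, b)
    if cursor < chrom_length:
        gap_s.append(cursor)
        gap_e.append(chrom_length)
    return np.array(gap_s, dtype=np.int64), np.array(gap_e, dtype=np.int64)


def frame_total_length(frame: pd.DataFrame) -> int:
    """Merged base count of a (chrom, start, end) DataFrame."""
    return sum(
        total_length(g["start"].to_numpy(), g["end"].to_numpy())
        for _, g in frame.groupby("chrom")
    )


def frame_intersect_length(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Merged overlap base count between two (chrom, start, end) DataFrames."""
    total = 0
    b_by_chrom = dict(tuple(b.groupby("chrom")))
    for chrom, ga in a.groupby("chrom"):
        gb = b_by_chrom.get(chrom)
        if gb is None:
            continue
        total += intersect_length(
            ga["start"].to_numpy(), ga["end"].to_numpy(),
            gb["start"].to_numpy(), gb["end"].to_numpy(),
        )
    return total
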
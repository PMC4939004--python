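"""Minimal interval engine (0-based half-open, numpy-backed).

Overlap semantics are >= 1 shared bp everywhere: book-ended intervals
([10,20) and [20,30)) do not overlap.
"""
from __future__ import annotations

from typing import List, Tuple

import numpy as np
import pandas as pd

BED_COLS = ["chrom", "start", "end"]


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge intervals that share >= 1 bp into maximal runs (mergeBed-like)."""
    if len(df) == 0:
        return pd.DataFrame(columns=BED_COLS)
    df = sort_intervals(df[BED_COLS])
    out: List[Tuple[str, int, int]] = []
    cur = None
    for chrom, start, end in df.itertuples(index=False):
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur = (cur[0], cur[1], max(cur[2], end))
        else:
            if cur is not None:
                out.append(cur)
            cur = (chrom, int(start), int(end))
    out.append(cur)
    return pd.DataFrame(out, columns=BED_COLS)


def overlap_join(a: pd.DataFrame, b: pd.DataFrame,
                 suffixes=("_a", "_b")) -> pd.DataFrame:
    """All pairs (row of a, row of b) sharing >= 1 bp on the same chromosome.

    Sweep-line; suitable for the desk-scale inputs used here. Input frames
    need chrom/start/end columns; all other columns are carried through.
    """
    pieces = []
    for chrom in a["chrom"].unique():
        av = a[a["chrom"] == chrom].sort_values("start")
        bv = b[b["chrom"] == chrom].sort_values("start")
        if len(av) == 0 or len(bv) == 0:
            continue
        b_start = bv["start"].to_numpy()
        b_end = bv["end"].to_numpy()
        order = np.argsort(b_end, kind="mergesort")
        b_end_sorted = b_end[order]
        for _, arow in av.iterrows():
            # candidates: b_start < a.end and b_end > a.start
            hi = np.searchsorted(b_start, arow["end"], side="left")
            lo_mask = b_end[:hi] > arow["start"]
            idx = np.flatnonzero(lo_mask)
            for j in idx:
                brow = bv.iloc[j]
                merged = {f"{k}{suffixes[0]}": v for k, v in arow.items()}
                merged.update({f"{k}{suffixes[1]}": v for k, v in brow.items()})
                pieces.append(merged)
    return pd.DataFrame(pieces)


def assign_points(points_chrom: np.ndarray, points_pos: np.ndarray,
                  sites: pd.DataFrame) -> np.ndarray:
    """Index of the (sorted, non-overlapping) site containing each point,
    or -1. Vectorised per chromosome."""
    result = np.full(len(points_pos), -1, dtype=np.int64)
    for chrom in np.unique(points_chrom):
        sub = sites[sites["chrom"] == chrom]
        if len(sub) == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        sel = points_chrom == chrom
        pos = points_pos[sel]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        site_idx = np.where(ok, sub.index.to_numpy()[np.clip(idx, 0, len(ends) - 1)], -1)
        result[sel] = site_idx
    return result


def check_non_overlapping(df: pd.DataFrame) -> None:
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping intervals on {chrom}")
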
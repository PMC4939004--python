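"""Accessible-chromatin peak calling, replicate reproducibility filtering,
cross-strain union, and fragment counting.

Peaks are contiguous runs of a Gaussian kernel density of fragment
midpoints (sigma = feature_length / 6, evaluated per bp in units of
fragments per bp) above a closed-form background threshold: for n
fragments placed uniformly on L bp the density at a point has mean n / L
and variance n/L * (1 / (2 sqrt(pi) sigma) - 1/L); the threshold is
mean + peak_threshold_sd * SD. The default multiplier (7) controls the
maximum of the smoothed null field over a megabase-scale genome, not the
per-position rate.
"""
from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .intervals import check_non_overlapping, merge_intervals

PEAK_COLS = ["chrom", "start", "end", "score", "summit"]


def background_threshold(n_fragments: int, genome_length: int, sigma: float,
                         n_sd: float = 4.0) -> float:
    mu = n_fragments / genome_length
    var = n_fragments / genome_length * (1.0 / (2.0 * np.sqrt(np.pi) * sigma)
                                         - 1.0 / genome_length)
    return float(mu + n_sd * np.sqrt(max(var, 0.0)))


def fragment_density(fragments: pd.DataFrame, chrom_length: int,
                     feature_length: int) -> np.ndarray:
    """Per-bp Gaussian kernel density (fragments per bp) of fragment
    midpoints on one chromosome."""
    sigma = feature_length / 6.0
    mid = ((fragments["start"].to_numpy() + fragments["end"].to_numpy()) // 2)
    hist = np.bincount(mid.astype(np.int64), minlength=chrom_length).astype(float)
    return gaussian_filter1d(hist, sigma=sigma, mode="constant")


def call_peaks(fragments: pd.DataFrame, chrom: str, chrom_length: int,
               feature_length: int = 400, n_sd: float = 7.0,
               n_total_fragments: int | None = None,
               total_genome_length: int | None = None) -> pd.DataFrame:
    """Call peaks on one chromosome from fragment intervals.

    ``n_total_fragments`` / ``total_genome_length`` let the background
    threshold reflect the whole library when calling chromosome by
    chromosome; they default to this chromosome's values.
    """
    if feature_length <= 0:
        raise ValueError("feature_length must be > 0")
    if feature_length < 50:
        raise ValueError("feature_length must be >= 50")
    if chrom_length <= 0:
        raise ValueError("empty genome")
    if len(fragments) == 0:
        return pd.DataFrame(columns=PEAK_COLS)
    sigma = feature_length / 6.0
    density = fragment_density(fragments, chrom_length, feature_length)
    n_bg = n_total_fragments if n_total_fragments is not None else len(fragments)
    L_bg = total_genome_length if total_genome_length is not None else chrom_length
    thr = background_threshold(n_bg, L_bg, sigma, n_sd)
    above = density > thr
    if not above.any():
        return pd.DataFrame(columns=PEAK_COLS)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [chrom_length]])
    rows = []
    for s, e in zip(starts, ends):
        summit = s + int(np.argmax(density[s:e]))
        rows.append((chrom, int(s), int(e), float(density[summit]), summit))
    return pd.DataFrame(rows, columns=PEAK_COLS)


def call_peaks_genome(fragments: pd.DataFrame, chrom_lengths: Dict[str, int],
                      feature_length: int = 400, n_sd: float = 7.0) -> pd.DataFrame:
    total_len = sum(chrom_lengths.values())
    n_total = len(fragments)
    parts = []
    for chrom, clen in chrom_lengths.items():
        sub = fragments[fragments["chrom"] == chrom]
        parts.append(call_peaks(sub, chrom, clen, feature_length, n_sd,
                                n_total_fragments=n_total,
                                total_genome_length=total_len))
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=PEAK_COLS)
    return out


def reproducible_peaks(peaks_rep1: pd.DataFrame, peaks_rep2: pd.DataFrame,
                       window: int = 20, discordance_cutoff: float = 0.5) -> pd.DataFrame:
    """Rank-concordance reproducibility filter (an IDR-style surrogate).

    Candidates are rep1 peaks overlapping a rep2 peak (matched to the
    rep2 peak with the largest overlap). Candidates are walked in
    decreasing rep1-score order; the retained prefix ends where the
    rolling mean (over ``window``) of |normalized rank difference| between
    replicate scores exceeds ``discordance_cutoff``. Retained peaks get
    the union of the matched pair's coordinates.
    """
    for df in (peaks_rep1, peaks_rep2):
        if len(df) and ("score" not in df.columns or df["score"].isna().any()):
            raise ValueError("peaks must carry scores")
    if len(peaks_rep1) == 0 or len(peaks_rep2) == 0:
        return pd.DataFrame(columns=PEAK_COLS)

    matches = []
    for chrom in peaks_rep1["chrom"].unique():
        p1 = peaks_rep1[peaks_rep1["chrom"] == chrom]
        p2 = peaks_rep2[peaks_rep2["chrom"] == chrom].sort_values("start")
        if len(p2) == 0:
            continue
        s2 = p2["start"].to_numpy()
        e2 = p2["end"].to_numpy()
        for _, row in p1.iterrows():
            ov = np.minimum(e2, row["end"]) - np.maximum(s2, row["start"])
            j = int(np.argmax(ov))
            if ov[j] > 0:
                matches.append((row, p2.iloc[j]))
    if not matches:
        return pd.DataFrame(columns=PEAK_COLS)

    score1 = np.array([m[0]["score"] for m in matches])
    score2 = np.array([m[1]["score"] for m in matches])
    n = len(matches)
    order = np.argsort(-score1, kind="mergesort")
    # ranks (0 = best) of each candidate's scores within the candidate set
    r1 = np.empty(n); r1[np.argsort(-score1, kind="mergesort")] = np.arange(n)
    r2 = np.empty(n); r2[np.argsort(-score2, kind="mergesort")] = np.arange(n)
    disc = np.abs(r1 - r2) / n
    disc_sorted = disc[order]
    keep_until = n
    for i in range(window - 1, n):   # rolling mean needs a full window
        if disc_sorted[i - window + 1:i + 1].mean() > discordance_cutoff:
            keep_until = i
            break
    kept = order[:keep_until]
    rows = []
    for idx in kept:
        a, b = matches[idx]
        rows.append((a["chrom"], int(min(a["start"], b["start"])),
                     int(max(a["end"], b["end"])), float(a["score"]),
                     int(a["summit"]) if "summit" in a else int((a["start"] + a["end"]) // 2)))
    out = pd.DataFrame(rows, columns=PEAK_COLS)
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def union_sites(peak_lists: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Merge >= 1 bp overlapping peaks across lists into maximal runs."""
    frames = [p[["chrom", "start", "end"]] for p in peak_lists if len(p)]
    if not frames:
        return pd.DataFrame(columns=["site_id", "chrom", "start", "end"])
    merged = merge_intervals(pd.concat(frames, ignore_index=True))
    merged.insert(0, "site_id", np.arange(len(merged)))
    return merged


def count_fragments(fragments: pd.DataFrame, sites: pd.DataFrame) -> np.ndarray:
    """Fragment counts per union site; a fragment counts for the site
    containing its midpoint (each fragment at most once)."""
    check_non_overlapping(sites)
    counts = np.zeros(len(sites), dtype=np.int64)
    for chrom in fragments["chrom"].unique():
        sub = sites[sites["chrom"] == chrom]
        if len(sub) == 0:
            continue
        frag = fragments[fragments["chrom"] == chrom]
        mid = (frag["start"].to_numpy() + frag["end"].to_numpy()) // 2
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, mid, side="right") - 1
        ok = (idx >= 0) & (mid < ends[np.clip(idx, 0, len(ends) - 1)])
        hits = np.bincount(idx[ok], minlength=len(sub))
        counts[sub.index.to_numpy()] += hits
    return counts


def count_matrix(per_library_fragments: Dict[str, pd.DataFrame],
                 sites: pd.DataFrame) -> np.ndarray:
    mat = np.zeros((len(sites), len(per_library_fragments)), dtype=np.int64)
    for j, (_, frags) in enumerate(per_library_fragments.items()):
        mat[:, j] = count_fragments(frags, sites)
    return mat
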
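"""Strain pseudo-genomes and exact k-mer mappability.

The mappability score of a position is 1 / (number of genomic positions,
on either strand, whose k-mer lies within the allowed Hamming distance of
that position's forward k-mer, the position itself included). Scores are
computed exactly with a seed-and-verify scheme: with at most ``m``
mismatches allowed, any matching pair of k-mers must agree exactly on at
least one of ``m + 1`` disjoint seed chunks (pigeonhole), so candidate
pairs are found by hashing chunks and then verified by a full Hamming
comparison. Hash collisions only add verification work, never errors.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .types import GenomeSequence, SnpTable

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
_CODE[ord("N")] = 4

_COMP = {0: 3, 1: 2, 2: 1, 3: 0, 4: 4}


def encode(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGTN")
    return arr


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    lut = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    return lut[codes[::-1]]


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ------------------------------------------------------------ pseudo-genome

def build_pseudo_genome(reference: GenomeSequence, snps: SnpTable,
                        strain: str) -> GenomeSequence:
    """Substitute the strain's alt alleles into the reference.

    Output chromosomes keep reference length and coordinates; position p
    carries the alt base iff the strain's allele code is 1 there.
    """
    if strain not in snps.strains:
        raise ValueError(f"unknown strain {strain!r}")
    snps.validate_against(reference)
    out = GenomeSequence()
    for chrom, seq in reference.items():
        sub = snps.for_chrom(chrom)
        carried = sub[sub[strain] == 1]
        if len(carried) == 0:
            out[chrom] = seq
            continue
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        arr[carried["pos"].to_numpy()] = carried["alt"].str.encode("ascii").to_numpy()
        out[chrom] = arr.tobytes().decode()
    return out


def diff_genomes(a: GenomeSequence, b: GenomeSequence) -> List[Tuple[str, int, str, str]]:
    """Positions where two equal-length genomes differ: (chrom, pos, a_base, b_base)."""
    diffs = []
    for chrom in a:
        xa = np.frombuffer(a[chrom].encode(), dtype="S1")
        xb = np.frombuffer(b[chrom].encode(), dtype="S1")
        for p in np.flatnonzero(xa != xb):
            diffs.append((chrom, int(p), a[chrom][p], b[chrom][p]))
    return diffs


# ------------------------------------------------------------- mappability

@dataclass
class MappabilityTrack:
    """Per-position scores; for each chromosome the array covers positions
    0 .. len - k (positions with a full k-mer remaining)."""

    scores: Dict[str, np.ndarray]
    kmer_length: int
    max_mismatches: int

    def as_bedgraph_track(self) -> Dict[str, np.ndarray]:
        return self.scores


_HASH_BASE = np.uint64(1099511628211)


def _rolling_hashes(codes: np.ndarray, length: int) -> np.ndarray:
    """hash of codes[i:i+length] for every valid i (wrapping uint64 poly hash)."""
    n = codes.size
    if n < length:
        return np.empty(0, dtype=np.uint64)
    x = codes.astype(np.uint64) + np.uint64(1)
    # window hash = sum_j x[i+j] * B^(length-1-j), computed as `length`
    # shifted, power-weighted array additions (wrapping arithmetic).
    powers = np.empty(length, dtype=np.uint64)
    p = np.uint64(1)
    for j in range(length - 1, -1, -1):
        powers[j] = p
        with np.errstate(over="ignore"):
            p = p * _HASH_BASE
    n_win = n - length + 1
    out = np.zeros(n_win, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(length):
            out += x[j:j + n_win] * powers[j]
    return out


def _window_has_n(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean per valid start: window contains an N."""
    isn = (codes == 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(isn)])
    return (cs[k:] - cs[:-k]) > 0


def mappability_track(genome: GenomeSequence, kmer_length: int,
                      max_mismatches: int, max_total_bp: int = 5_000_000,
                      max_candidate_pairs: int = 100_000_000) -> MappabilityTrack:
    """Exact mappability for every position with a full k-mer.

    Both strands count toward the match tally. Windows containing N get no
    score (NaN) and do not count as matches. Intended for desk-scale
    genomes (hard cap ``max_total_bp``); extremely repetitive input can
    exceed ``max_candidate_pairs`` and raises rather than thrashing.
    """
    k = int(kmer_length)
    mm = int(max_mismatches)
    total = genome.total_length
    if total > max_total_bp:
        raise ValueError(f"genome of {total} bp exceeds exact-algorithm cap {max_total_bp}")
    for chrom, seq in genome.items():
        if len(seq) < k:
            raise ValueError(f"kmer_length {k} exceeds chromosome {chrom!r} length")

    chroms = list(genome)
    fwd_codes = {c: encode(genome[c]) for c in chroms}
    rev_codes = {c: revcomp_codes(fwd_codes[c]) for c in chroms}

    # Global window registry: forward windows first (these are the scored
    # queries), then reverse-strand windows; each window is (array, offset).
    win_arrays: List[np.ndarray] = []
    win_offsets: List[np.ndarray] = []   # global window id -> start within its array
    arr_of_win: List[np.ndarray] = []    # global window id -> array index
    has_n_all: List[np.ndarray] = []
    n_fwd_windows = 0
    arrays: List[np.ndarray] = []

    def _register(codes: np.ndarray):
        nonlocal arrays
        arrays.append(codes)
        n_win = codes.size - k + 1
        win_offsets.append(np.arange(n_win, dtype=np.int64))
        arr_of_win.append(np.full(n_win, len(arrays) - 1, dtype=np.int32))
        has_n_all.append(_window_has_n(codes, k))

    for c in chroms:
        _register(fwd_codes[c])
    n_fwd_windows = sum(a.size - k + 1 for a in arrays)
    for c in chroms:
        _register(rev_codes[c])

    offsets = np.concatenate(win_offsets)
    arr_idx = np.concatenate(arr_of_win)
    has_n = np.concatenate(has_n_all)
    n_windows = offsets.size

    chunk = k // (mm + 1)
    chunk_starts = [i * chunk for i in range(mm + 1)]

    # every valid forward window matches itself; candidate pairs below
    # exclude the self pair, so start the tally at 1
    counts = np.zeros(n_windows, dtype=np.int64)
    valid = ~has_n
    counts[:n_fwd_windows][valid[:n_fwd_windows]] = 1
    pair_sets: List[np.ndarray] = []
    for cs in chunk_starts:
        keys = np.empty(n_windows, dtype=np.uint64)
        for ai, codes in enumerate(arrays):
            h = _rolling_hashes(codes, chunk)
            sel = arr_idx == ai
            keys[sel] = h[offsets[sel] + cs]
        # group windows by key; emit candidate pairs (i fwd query, j any)
        order = np.argsort(keys, kind="mergesort")
        ks = keys[order]
        boundaries = np.flatnonzero(np.diff(ks) != 0) + 1
        group_starts = np.concatenate([[0], boundaries])
        group_ends = np.concatenate([boundaries, [n_windows]])
        sizes = group_ends - group_starts
        big = sizes > 1
        est_pairs = int(np.sum(sizes[big].astype(np.int64) ** 2))
        if est_pairs > max_candidate_pairs:
            raise ValueError("input too repetitive for the exact mappability algorithm")
        qi: List[np.ndarray] = []
        sj: List[np.ndarray] = []
        for gs, ge in zip(group_starts[big], group_ends[big]):
            members = order[gs:ge]
            members = members[valid[members]]
            queries = members[members < n_fwd_windows]
            if queries.size == 0 or members.size < 2:
                continue
            Q, S = np.meshgrid(queries, members, indexing="ij")
            qi.append(Q.ravel())
            sj.append(S.ravel())
        if qi:
            pair_sets.append(np.stack([np.concatenate(qi), np.concatenate(sj)]))

    if pair_sets:
        pairs = np.concatenate(pair_sets, axis=1)
        combined = pairs[0] * np.int64(n_windows) + pairs[1]
        combined = np.unique(combined)
        q = (combined // n_windows).astype(np.int64)
        s = (combined % n_windows).astype(np.int64)
        keep = q != s
        q, s = q[keep], s[keep]
        # verify in batches
        batch = 200_000
        views = [np.lib.stride_tricks.sliding_window_view(a, k) for a in arrays]
        for lo in range(0, q.size, batch):
            qb = q[lo:lo + batch]
            sb = s[lo:lo + batch]
            hd = np.empty(qb.size, dtype=np.int32)
            # group by (query array, subject array) to index the right views
            key = arr_idx[qb].astype(np.int64) * len(arrays) + arr_idx[sb]
            for kk in np.unique(key):
                m = key == kk
                a1 = int(kk // len(arrays))
                a2 = int(kk % len(arrays))
                w1 = views[a1][offsets[qb[m]]]
                w2 = views[a2][offsets[sb[m]]]
                hd[m] = (w1 != w2).sum(axis=1)
            ok = hd <= mm
            np.add.at(counts, qb[ok], 1)

    # assemble per-chromosome forward scores
    scores: Dict[str, np.ndarray] = {}
    pos = 0
    for c in chroms:
        n_win = len(genome[c]) - k + 1
        cnt = counts[pos:pos + n_win].astype(float)
        sc = np.where(cnt > 0, 1.0 / np.maximum(cnt, 1), np.nan)
        sc[has_n[pos:pos + n_win]] = np.nan
        scores[c] = sc
        pos += n_win
    return MappabilityTrack(scores=scores, kmer_length=k, max_mismatches=mm)


def mappability_oracle(seq: str, kmer_length: int, max_mismatches: int) -> np.ndarray:
    """Brute-force single-chromosome mappability via sliding-offset Hamming
    sums. Independent of the seed-and-verify path; O(L^2) — test scale only.

    For each alignment shift the per-base mismatch indicator between the
    genome and a shifted copy (forward or reverse-complement) is summed
    over k-length windows with a cumulative sum; a window pair matches when
    the sum is <= max_mismatches.
    """
    k, mm = int(kmer_length), int(max_mismatches)
    f = encode(seq)
    L = f.size
    P = L - k + 1
    counts = np.zeros(P, dtype=np.int64)
    for other in (f, revcomp_codes(f)):
        for s in range(-(L - k), L - k + 1):
            if s >= 0:
                diff = (f[: L - s] != other[s:]).astype(np.int32)
                qi0 = 0
            else:
                diff = (f[-s:] != other[: L + s]).astype(np.int32)
                qi0 = -s
            if diff.size < k:
                continue
            cs = np.concatenate([[0], np.cumsum(diff)])
            w = cs[k:] - cs[:-k]          # w[t]: query window qi0+t vs subject
            hit = w <= mm
            counts[qi0:qi0 + hit.size] += hit
    return 1.0 / counts


def oracle_match_count(seq: str, position: int, kmer_length: int,
                       max_mismatches: int) -> int:
    """Match tally of one position's forward k-mer against all genome
    positions on both strands (brute force, O(L*k))."""
    k, mm = int(kmer_length), int(max_mismatches)
    f = encode(seq)
    r = revcomp_codes(f)
    target = f[position:position + k]
    total = 0
    for other in (f, r):
        mism = (np.lib.stride_tricks.sliding_window_view(other, k) != target).sum(axis=1)
        total += int(np.sum(mism <= mm))
    return total
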
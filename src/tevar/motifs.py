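"""PWM scanning, GC-matched backgrounds, and known-motif enrichment.

A PWM is a 4 x L base-count matrix; scoring uses base-2 log-odds with
pseudocount smoothing against a background base composition, and a hit is
any window (either strand) scoring at least ``score_threshold`` times the
maximal attainable score. Enrichment of sequence-level motif occurrence in
targets vs a GC-matched background is tested with the one-sided
hypergeometric tail; a motif is selected when p < 0.01 and it occurs in
more than 10% of the target sequences.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .genome import encode
from .stats import hypergeom_p_ge

log = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass
class Pwm:
    name: str
    counts: np.ndarray                       # (4, L) counts, rows A,C,G,T
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.5
    score_threshold: float = 0.8             # fraction of maximal log-odds

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("PWM counts must have 4 rows (A, C, G, T)")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError("PWM column sums must be > 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        col_tot = self.counts.sum(axis=0)
        probs = (self.counts + self.pseudocount * self.background[:, None]) \
            / (col_tot + self.pseudocount)
        return np.log2(probs / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))

    @classmethod
    def from_consensus(cls, name: str, consensus: str, weight: float = 100.0,
                       off_weight: float = 1.0, **kw) -> "Pwm":
        counts = np.full((4, len(consensus)), off_weight)
        for j, b in enumerate(consensus.upper()):
            counts[BASES.index(b), j] = weight
        return cls(name=name, counts=counts, **kw)


def read_pwm_file(path) -> List[Pwm]:
    """Read a JASPAR-style PWM text file: '>name' header then four rows of
    counts (optionally prefixed 'A [ ... ]' style)."""
    pwms = []
    name, rows = None, []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    for ln in lines + [">__end__"]:
        if ln.startswith(">"):
            if name is not None:
                if len(rows) != 4:
                    raise ValueError(f"PWM {name!r}: expected 4 count rows")
                pwms.append(Pwm(name=name, counts=np.array(rows)))
            name, rows = ln[1:].split()[0], []
        else:
            cleaned = ln
            for ch in "ACGT[]":
                cleaned = cleaned.replace(ch, " ")
            rows.append([float(x) for x in cleaned.split()])
    return pwms


def write_pwm_file(pwms: Sequence[Pwm], path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.name}\n")
            for b, row in zip(BASES, p.counts):
                fh.write(f"{b} [ " + " ".join(f"{x:g}" for x in row) + " ]\n")


def scan_pwm(sequence: str, pwm: Pwm) -> pd.DataFrame:
    """Log-odds scan of both strands; hits where score >= threshold
    fraction of the maximum. Reverse-strand hits are reported in forward
    coordinates. Windows containing N are skipped."""
    L = pwm.length
    if len(sequence) < L:
        return pd.DataFrame(columns=["position", "strand", "score"])
    codes = encode(sequence.upper())
    lo = pwm.log_odds
    lo_rc = lo[::-1, ::-1]      # scoring the reverse strand on forward windows
    wins = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = ~(wins == 4).any(axis=1)
    cols = np.arange(L)
    safe = np.minimum(wins, 3)
    fwd = lo[safe, cols].sum(axis=1)
    rev = lo_rc[safe, cols].sum(axis=1)
    cutoff = pwm.score_threshold * pwm.max_score
    rows = []
    for pos in np.flatnonzero(valid & (fwd >= cutoff - 1e-12)):
        rows.append((int(pos), "+", float(fwd[pos])))
    for pos in np.flatnonzero(valid & (rev >= cutoff - 1e-12)):
        rows.append((int(pos), "-", float(rev[pos])))
    out = pd.DataFrame(rows, columns=["position", "strand", "score"])
    return out.sort_values(["position", "strand"]).reset_index(drop=True)


def has_motif(sequence: str, pwm: Pwm) -> bool:
    return len(scan_pwm(sequence, pwm)) > 0


def gc_fraction(sequence: str) -> float:
    acgt = sum(sequence.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (sequence.count("G") + sequence.count("C")) / acgt


def gc_matched_background(targets: Sequence[str], pool: Sequence[str], seed: int,
                          ratio: int = 2, bin_width: float = 0.05) -> List[str]:
    """Sample pool sequences without replacement to match the targets' GC
    histogram (bin width 5 GC percentage points, ``ratio`` backgrounds per
    target). Unmatchable bins relax to adjacent bins with a log message."""
    if len(pool) < 5 * len(targets):
        raise ValueError("pool must be >= 5x the number of targets")
    rng = np.random.default_rng(seed)
    n_bins = int(np.ceil(1.0 / bin_width)) + 1
    pool_bins: Dict[int, List[int]] = {}
    for i, s in enumerate(pool):
        pool_bins.setdefault(min(int(gc_fraction(s) / bin_width), n_bins - 1), []).append(i)
    for b in pool_bins:
        pool_bins[b] = list(rng.permutation(pool_bins[b]))
    chosen: List[int] = []
    target_bins = [min(int(gc_fraction(s) / bin_width), n_bins - 1) for s in targets]
    for b in sorted(set(target_bins)):
        want = ratio * target_bins.count(b)
        got = 0
        for delta in range(n_bins):
            for bb in ({b} if delta == 0 else {b - delta, b + delta}):
                avail = pool_bins.get(bb, [])
                take = min(want - got, len(avail))
                if take > 0:
                    if delta > 0:
                        log.info("gc_matched_background: bin %d relaxed to %d "
                                 "for %d sequences", b, bb, take)
                    chosen.extend(avail[:take])
                    pool_bins[bb] = avail[take:]
                    got += take
                if got >= want:
                    break
            if got >= want:
                break
        if got < want:
            raise ValueError(f"cannot match GC bin {b}: pool exhausted")
    return [pool[i] for i in sorted(chosen)]


def motif_enrichment(targets: Sequence[str], background: Sequence[str],
                     pwms: Sequence[Pwm], p_threshold: float = 0.01,
                     occurrence_fraction: float = 0.10) -> pd.DataFrame:
    """Per-motif sequence-level occurrence in targets vs targets+background
    with one-sided hypergeometric enrichment p; ``selected`` motifs pass
    both the p and the target-occurrence-fraction cutoffs."""
    if len(targets) == 0:
        raise ValueError("empty target set")
    n_t, n_b = len(targets), len(background)
    rows = []
    for pwm in pwms:
        k_t = sum(has_motif(s, pwm) for s in targets)
        k_b = sum(has_motif(s, pwm) for s in background)
        total, successes = n_t + n_b, k_t + k_b
        p = hypergeom_p_ge(k_t, total, successes, n_t) if successes else 1.0
        frac_t = k_t / n_t
        frac_b = k_b / n_b if n_b else 0.0
        rows.append({"motif": pwm.name, "target_hits": k_t, "target_fraction": frac_t,
                     "background_hits": k_b, "background_fraction": frac_b, "p": p,
                     "selected": bool(p < p_threshold and frac_t > occurrence_fraction)})
    return pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)


def scan_genome(genome: Dict[str, str], pwm: Pwm) -> pd.DataFrame:
    """Genome-wide motif hits as chrom/start/end/strand/score."""
    rows = []
    for chrom, seq in genome.items():
        hits = scan_pwm(seq, pwm)
        for h in hits.itertuples(index=False):
            rows.append((chrom, h.position, h.position + pwm.length, h.strand, h.score))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "score"])


def predicted_binding_sites(hits: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Motif hits fully contained in an accessible site (containment, not
    mere overlap: a hit straddling a site edge is dropped)."""
    if len(hits) == 0:
        return hits.copy()
    keep = []
    for chrom in hits["chrom"].unique():
        h = hits[hits["chrom"] == chrom]
        s = sites[sites["chrom"] == chrom].sort_values("start")
        if len(s) == 0:
            continue
        starts = s["start"].to_numpy()
        ends = s["end"].to_numpy()
        idx = np.searchsorted(starts, h["start"].to_numpy(), side="right") - 1
        ok = (idx >= 0) & (h["end"].to_numpy() <= ends[np.clip(idx, 0, len(ends) - 1)])
        keep.append(h[ok])
    if not keep:
        return hits.iloc[0:0]
    return pd.concat(keep).sort_values(["chrom", "start"]).reset_index(drop=True)
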
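"""Shared domain containers.

Coordinate convention: everything in memory is 0-based, half-open
``[start, end)``. Formats that are 1-based on disk (VCF, RepeatMasker .out)
are converted at the parser boundary and converted back on write.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA", "Other")


class GenomeSequence(dict):
    """Ordered mapping of chromosome name -> uppercase sequence string."""

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.values())


@dataclass
class TEInstance:
    """One annotated repeat copy.

    ``divergence`` is the fraction of bases differing from the subfamily
    consensus (RepeatMasker's percent column / 100). ``age`` in years is
    derived as divergence / substitution_rate and is kept consistent with
    ``divergence`` by :meth:`with_age`.
    """

    chrom: str
    start: int
    end: int
    strand: str
    te_class: str
    family: str
    subfamily: str
    divergence: float
    age: Optional[float] = None
    te_id: Optional[int] = None
    polymorphic: bool = False
    carrier_strains: Optional[tuple] = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"TE interval start >= end: {self.start} >= {self.end}")
        if self.divergence < 0:
            raise ValueError(f"negative divergence: {self.divergence}")
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def te_list_to_frame(tes: Sequence[TEInstance]) -> pd.DataFrame:
    rows = [
        dict(
            te_id=(t.te_id if t.te_id is not None else i),
            chrom=t.chrom, start=t.start, end=t.end, strand=t.strand,
            te_class=t.te_class, family=t.family, subfamily=t.subfamily,
            divergence=t.divergence, age=t.age,
            polymorphic=t.polymorphic,
            carrier_strains=",".join(t.carrier_strains) if t.carrier_strains else "",
        )
        for i, t in enumerate(tes)
    ]
    cols = ["te_id", "chrom", "start", "end", "strand", "te_class", "family",
            "subfamily", "divergence", "age", "polymorphic", "carrier_strains"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class SnpTable:
    """Biallelic SNVs with homozygous per-strain allele codes (0=ref, 1=alt).

    ``frame`` columns: chrom, pos (0-based), ref, alt, one 0/1 column per
    strain in ``strains``.
    """

    frame: pd.DataFrame
    strains: List[str]

    def __post_init__(self):
        required = ["chrom", "pos", "ref", "alt"] + list(self.strains)
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"SnpTable missing columns: {missing}")
        dup = self.frame.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate (chrom, pos) in SnpTable")
        if (self.frame["ref"] == self.frame["alt"]).any():
            raise ValueError("SNP with ref == alt")

    def __len__(self) -> int:
        return len(self.frame)

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.frame[self.frame["chrom"] == chrom]

    def validate_against(self, genome: GenomeSequence) -> None:
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            seq = genome.get(chrom)
            if seq is None:
                raise ValueError(f"SNP chromosome {chrom!r} absent from genome")
            arr = np.frombuffer(seq.encode(), dtype="S1")
            pos = sub["pos"].to_numpy()
            ref = sub["ref"].str.encode("ascii").to_numpy()
            bad = arr[pos] != ref
            if bad.any():
                p = int(pos[bad][0])
                raise ValueError(
                    f"ref allele mismatch at {chrom}:{p}: table says "
                    f"{sub['ref'].to_numpy()[bad][0]}, genome has {seq[p]}"
                )


@dataclass
class SiteMatrix:
    """Union accessible sites x libraries count matrix with annotations.

    ``sites``: DataFrame(site_id, chrom, start, end), sorted, non-overlapping.
    ``counts``: (n_sites, n_libraries) raw counts.
    ``normalized``: same shape after quantile normalization (or None).
    ``libraries``: DataFrame(library, strain, replicate) in column order.
    ``results``: per-site test results / labels (or None).
    """

    sites: pd.DataFrame
    counts: np.ndarray
    libraries: pd.DataFrame
    normalized: Optional[np.ndarray] = None
    results: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if self.counts.shape != (len(self.sites), len(self.libraries)):
            raise ValueError("counts shape does not match sites x libraries")

    @property
    def strains(self) -> List[str]:
        return list(dict.fromkeys(self.libraries["strain"]))

    def strain_means(self, normalized: bool = True) -> pd.DataFrame:
        """Replicate-averaged signal per strain (sites x strains)."""
        mat = self.normalized if (normalized and self.normalized is not None) else self.counts
        out = {}
        for strain in self.strains:
            cols = np.flatnonzero((self.libraries["strain"] == strain).to_numpy())
            out[strain] = mat[:, cols].mean(axis=1)
        return pd.DataFrame(out, index=self.sites["site_id"].to_numpy())


@dataclass
class CpGTable:
    """CpG positions x strains methylation fractions.

    ``frame`` columns: chrom, pos, one column per strain (floats in [0,1],
    NaN for missing calls).
    """

    frame: pd.DataFrame
    strains: List[str]

    def __post_init__(self):
        vals = self.frame[self.strains].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise ValueError("methylation fractions must be in [0, 1]")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class SimTruth:
    """Ground-truth labels emitted by the synthetic-data generators."""

    variable_site_ids: Set[int] = field(default_factory=set)
    common_site_ids: Set[int] = field(default_factory=set)
    snp_driven: Dict[int, float] = field(default_factory=dict)     # site -> fold
    methylation_driven: Dict[int, int] = field(default_factory=dict)  # site -> cpg id
    te_target_age: Dict[int, float] = field(default_factory=dict)  # te_id -> years
    planted_peaks: Optional[pd.DataFrame] = None
    polymorphic_te_ids: Dict[int, tuple] = field(default_factory=dict)
    planted_motifs: Optional[pd.DataFrame] = None   # motif, chrom, start, end, strand
    dm_cpg_ids: Set[int] = field(default_factory=set)

    def validate(self) -> None:
        if self.variable_site_ids & self.common_site_ids:
            raise ValueError("variable and common site sets overlap")
        drivers = set(self.snp_driven) | set(self.methylation_driven)
        if not drivers <= self.variable_site_ids:
            raise ValueError("driver-labelled sites must be variable sites")
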
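"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, VCF via pysam; BED/bedGraph/RepeatMasker .out/TSV are
simple enough to handle directly. All coordinates are converted to 0-based
half-open at this boundary (VCF and RepeatMasker .out are 1-based
inclusive on disk) and RepeatMasker percent divergence becomes a fraction.
"""
from __future__ import annotations

import logging
import re
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .types import CpGTable, GenomeSequence, SnpTable, TEInstance, te_list_to_frame

log = logging.getLogger(__name__)

_VALID_SEQ = re.compile(r"^[ACGTN]*$")


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> GenomeSequence:
    genome = GenomeSequence()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in genome:
            raise ValueError(f"duplicate chromosome name {rec.id!r}")
        if not seq:
            raise ValueError(f"empty record {rec.id!r}")
        if not _VALID_SEQ.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"non-nucleotide characters in {rec.id!r}: {bad}")
        genome[rec.id] = seq
    return genome


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ----------------------------------------------------- RepeatMasker .out

def read_repeatmasker_out(path) -> List[TEInstance]:
    """Parse a standard RepeatMasker .out file (3 header lines).

    Query coordinates are 1-based inclusive on disk; the class/family
    string (e.g. ``LINE/L1``) collapses to one of LINE/SINE/LTR/DNA/Other.
    """
    tes: List[TEInstance] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 11:
            raise ValueError(f"line {lineno}: expected >= 11 columns, got {len(parts)}")
        divergence = float(parts[1]) / 100.0
        chrom = parts[4]
        start1, end1 = int(parts[5]), int(parts[6])
        if start1 > end1:
            raise ValueError(f"line {lineno}: start > end")
        if divergence < 0:
            raise ValueError(f"line {lineno}: negative divergence")
        strand = "+" if parts[8] in ("+",) else "-"
        subfamily = parts[9]
        class_family = parts[10]
        te_class, family = _split_class_family(class_family)
        tes.append(TEInstance(
            chrom=chrom, start=start1 - 1, end=end1, strand=strand,
            te_class=te_class, family=family, subfamily=subfamily,
            divergence=divergence, te_id=len(tes),
        ))
    return tes


def _split_class_family(class_family: str):
    head, _, family = class_family.partition("/")
    base = head.rstrip("?")
    if base in ("LINE", "SINE", "LTR", "DNA"):
        return base, family or base
    return "Other", class_family


def write_repeatmasker_out(tes: Sequence[TEInstance], path) -> None:
    header = (
        "   SW  perc perc perc  query     position in query    matching"
        "  repeat         position in repeat\n"
        "score  div. del. ins.  sequence  begin end   (left)   repeat"
        "         class/family  begin end (left) ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for t in tes:
            cf = f"{t.te_class}/{t.family}" if t.te_class != "Other" else t.family
            fh.write(
                f"  225 {t.divergence * 100:5.1f}  0.0  0.0  {t.chrom} "
                f"{t.start + 1} {t.end} (0) {'+' if t.strand == '+' else 'C'} "
                f"{t.subfamily} {cf} 1 {t.length} (0) {t.te_id}\n"
            )


# ------------------------------------------------------------------ VCF

def read_snv_vcf(path, strain_names: Sequence[str]) -> SnpTable:
    """Read biallelic SNVs; non-SNV and heterozygous records are skipped
    (counts logged). Positions become 0-based."""
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    missing = [s for s in strain_names if s not in samples]
    if missing:
        raise ValueError(f"genotype columns missing for strains: {missing}")
    rows = []
    n_non_snv = n_het = 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            n_non_snv += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            n_non_snv += 1
            continue
        alleles = {}
        ok = True
        for strain in strain_names:
            gt = rec.samples[strain].get("GT")
            if gt is None or None in gt:
                ok = False
                break
            if len(set(gt)) > 1:
                n_het += 1
                ok = False
                break
            alleles[strain] = int(gt[0] != 0)
        if not ok:
            continue
        rows.append({"chrom": rec.chrom, "pos": rec.pos - 1, "ref": ref, "alt": alt,
                     **alleles})
    if n_non_snv:
        log.info("read_snv_vcf: skipped %d non-SNV records", n_non_snv)
    if n_het:
        log.info("read_snv_vcf: rejected %d heterozygous records", n_het)
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", *strain_names])
    return SnpTable(frame=frame, strains=list(strain_names))


def write_snv_vcf(snps: SnpTable, path, contig_lengths: Optional[Dict[str, int]] = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in snps.frame["chrom"].unique():
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(snps.strains) + "\n")
        for row in snps.frame.itertuples(index=False):
            gts = "\t".join(
                "1/1" if getattr(row, s) else "0/0" for s in snps.strains
            )
            fh.write(f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ------------------------------------------------------------ BED / bedGraph

def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :min(6, df.shape[1])]
    df.columns = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"]
            if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track: Dict[str, np.ndarray], path) -> None:
    """Write per-position tracks as bedGraph, merging runs of equal value.

    ``track`` maps chromosome -> 1D numeric array (value per bp, starting
    at position 0). NaN values are rejected.
    """
    with open(path, "w") as fh:
        for chrom, values in track.items():
            values = np.asarray(values, dtype=float)
            if values.size == 0:
                continue
            if np.isnan(values).any():
                raise ValueError(f"NaN in track for {chrom}")
            change = np.flatnonzero(np.diff(values) != 0)
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change + 1, [values.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{_fmt(values[s])}\n")


def _fmt(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:.6g}"


# ------------------------------------------------------------------ TSV

def write_counts_tsv(sites: pd.DataFrame, matrix: np.ndarray,
                     libraries: pd.DataFrame, path, float_format=None) -> None:
    df = sites[["site_id", "chrom", "start", "end"]].copy()
    for j, lib in enumerate(libraries["library"]):
        df[lib] = matrix[:, j]
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_counts_tsv(path):
    df = pd.read_csv(path, sep="\t")
    site_cols = ["site_id", "chrom", "start", "end"]
    libs = [c for c in df.columns if c not in site_cols]
    return df[site_cols], df[libs].to_numpy(), libs


def read_cpg_table(path, strains: Optional[Sequence[str]] = None) -> CpGTable:
    df = pd.read_csv(path, sep="\t")
    if strains is None:
        strains = [c for c in df.columns if c not in ("chrom", "pos", "cpg_id")]
    return CpGTable(frame=df, strains=list(strains))


def write_cpg_table(table: CpGTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def write_te_tsv(tes: Sequence[TEInstance], path) -> None:
    te_list_to_frame(tes).to_csv(path, sep="\t", index=False)
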
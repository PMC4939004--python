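"""Synthetic-data generators with ground truth.

Everything downstream of sequencing is exercisable on data these
generators emit: genomes carrying TE copies of controlled divergence
(hence age), strain SNP tables, FAIRE-like fragment libraries around
planted accessible sites, NB count matrices with planted variable /
common / SNP-driven / methylation-driven structure, and RRBS-like CpG
methylation tables with planted differential methylation. Every planted
label is recorded in a :class:`~tevar.types.SimTruth` and is verifiable
from the emitted data alone.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import GenomeSequence, SimTruth, SnpTable, TEInstance

BASES = np.frombuffer(b"ACGT", dtype="S1")
DEFAULT_SUBSTITUTION_RATE = 4.5e-9


@dataclass
class TESubfamilySpec:
    name: str
    te_class: str
    family: str
    length: int
    copies: int
    age_years: float
    consensus: Optional[str] = None


def _random_sequence(rng: np.random.Generator, length: int, gc: float = 0.42) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, p_sub: float) -> Tuple[str, float]:
    """Per-site substitution with probability p_sub (to a uniformly random
    different base). Returns (sequence, realized divergence)."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < p_sub
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode(), hit.mean()


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_genome(n_chroms: int, chrom_length: int,
                    te_spec: Sequence[TESubfamilySpec], seed: int,
                    gc: float = 0.42,
                    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE,
                    min_gap: int = 100):
    """Random background genome with non-overlapping TE copies planted in.

    Each copy is its subfamily consensus mutated at per-site probability
    age * substitution_rate (capped at 0.75, error above); realized
    divergence (fraction of mutated sites) is recorded per instance.
    Returns (GenomeSequence, [TEInstance], SimTruth with target ages).
    """
    rng = np.random.default_rng(seed)
    total_te = sum(s.length * s.copies for s in te_spec)
    if total_te > 0.6 * n_chroms * chrom_length:
        raise ValueError("TE copies exceed genome capacity")
    genome = GenomeSequence()
    chrom_arrays = {}
    for c in range(n_chroms):
        name = f"chr{c + 1}"
        chrom_arrays[name] = np.frombuffer(
            _random_sequence(rng, chrom_length, gc).encode(), dtype="S1").copy()
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_arrays}

    tes: List[TEInstance] = []
    truth = SimTruth()
    chrom_names = list(chrom_arrays)
    for spec in te_spec:
        p_sub = spec.age_years * substitution_rate
        if p_sub > 0.75:
            raise ValueError(f"target divergence {p_sub:.3f} > 0.75 for {spec.name}")
        consensus = spec.consensus or _random_sequence(rng, spec.length, gc)
        for _ in range(spec.copies):
            placed = False
            for _attempt in range(2000):
                chrom = chrom_names[rng.integers(len(chrom_names))]
                start = int(rng.integers(0, chrom_length - spec.length))
                end = start + spec.length
                if all(end + min_gap <= s or start >= e + min_gap
                       for s, e in occupied[chrom]):
                    placed = True
                    break
            if not placed:
                raise ValueError("could not place TE copy; genome too crowded")
            mutated, divergence = _mutate(rng, consensus, p_sub)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = mutated if strand == "+" else _revcomp(mutated)
            chrom_arrays[chrom][start:end] = np.frombuffer(inserted.encode(), dtype="S1")
            occupied[chrom].append((start, end))
            te_id = len(tes)
            tes.append(TEInstance(
                chrom=chrom, start=start, end=end, strand=strand,
                te_class=spec.te_class, family=spec.family, subfamily=spec.name,
                divergence=float(divergence),
                age=float(divergence) / substitution_rate, te_id=te_id))
            truth.te_target_age[te_id] = spec.age_years
    for name, arr in chrom_arrays.items():
        genome[name] = arr.tobytes().decode()
    return genome, tes, truth


def simulate_strains(reference: GenomeSequence, n_strains: int, snp_rate: float,
                     polymorphic_te_fraction: float, seed: int,
                     tes: Optional[Sequence[TEInstance]] = None,
                     strain_names: Optional[Sequence[str]] = None):
    """Uniformly placed SNPs with homozygous alleles carried by random
    nonempty proper strain subsets, plus a random fraction of TEs marked
    polymorphic with random carrier subsets.

    Returns (SnpTable, carrier table DataFrame(te_id, carriers)).
    """
    if n_strains <= 0:
        raise ValueError("need at least one strain")
    if snp_rate < 0 or snp_rate > 0.01:
        raise ValueError("snp_rate must be in [0, 0.01]")
    rng = np.random.default_rng(seed)
    strains = list(strain_names) if strain_names else [f"S{i + 1}" for i in range(n_strains)]
    rows = []
    for chrom, seq in reference.items():
        L = len(seq)
        n_snps = rng.binomial(L, snp_rate) if snp_rate > 0 else 0
        if n_snps == 0:
            continue
        pos = np.sort(rng.choice(L, size=n_snps, replace=False))
        arr = np.frombuffer(seq.encode(), dtype="S1")
        for p in pos:
            ref = arr[p].decode()
            if ref == "N":
                continue
            alt = rng.choice(BASES[BASES != arr[p]]).decode()
            k = int(rng.integers(1, n_strains))  # 1 .. n-1 carriers
            carriers = rng.choice(n_strains, size=k, replace=False)
            alleles = {s: 0 for s in strains}
            for ci in carriers:
                alleles[strains[ci]] = 1
            rows.append({"chrom": chrom, "pos": int(p), "ref": ref, "alt": alt, **alleles})
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", *strains])
    snps = SnpTable(frame=frame, strains=strains)

    carrier_rows = []
    if tes is not None and polymorphic_te_fraction > 0:
        n_poly = int(round(polymorphic_te_fraction * len(tes)))
        chosen = rng.choice(len(tes), size=n_poly, replace=False) if n_poly else []
        for i in chosen:
            k = int(rng.integers(1, n_strains))
            carriers = tuple(sorted(strains[c] for c in
                                    rng.choice(n_strains, size=k, replace=False)))
            tes[i].polymorphic = True
            tes[i].carrier_strains = carriers
            carrier_rows.append({"te_id": tes[i].te_id, "carriers": ",".join(carriers)})
    carrier_table = pd.DataFrame(carrier_rows, columns=["te_id", "carriers"])
    return snps, carrier_table


def simulate_fragments(genome: GenomeSequence, peak_plan: pd.DataFrame,
                       n_fragments: int, seed: int,
                       fragment_length_mean: float = 170.0,
                       fragment_length_sd: float = 3.0,
                       min_length: int = 20) -> pd.DataFrame:
    """One library of FAIRE-like fragments.

    Midpoints follow a mixture of a uniform background over the genome and
    truncated-normal components centred on each planned peak, with mixture
    weights proportional to (enrichment - 1) * width; fragment lengths are
    Normal(170, 3) rounded, floored at ``min_length``.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = {c: len(genome[c]) for c in chroms}
    if len(peak_plan) and (peak_plan["enrichment"] < 1).any():
        raise ValueError("enrichment must be >= 1")
    for row in peak_plan.itertuples(index=False):
        if row.start < 0 or row.end > lengths[row.chrom]:
            raise ValueError(f"peak outside genome: {row.chrom}:{row.start}-{row.end}")
    if n_fragments == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])

    total_len = sum(lengths.values())
    peak_w = ((peak_plan["enrichment"].to_numpy() - 1.0)
              * (peak_plan["end"] - peak_plan["start"]).to_numpy()) if len(peak_plan) else np.empty(0)
    weights = np.concatenate([[float(total_len)], peak_w])
    probs = weights / weights.sum()
    comp = rng.choice(len(probs), size=n_fragments, p=probs)

    mid_chrom = np.empty(n_fragments, dtype=object)
    mid_pos = np.empty(n_fragments, dtype=np.int64)
    bg = comp == 0
    n_bg = int(bg.sum())
    if n_bg:
        offs = np.concatenate([[0], np.cumsum([lengths[c] for c in chroms])])
        gpos = rng.integers(0, total_len, size=n_bg)
        ci = np.searchsorted(offs, gpos, side="right") - 1
        mid_chrom[bg] = np.array(chroms, dtype=object)[ci]
        mid_pos[bg] = gpos - offs[ci]
    for pi in range(len(peak_plan)):
        sel = comp == pi + 1
        n_p = int(sel.sum())
        if n_p == 0:
            continue
        row = peak_plan.iloc[pi]
        center = (row["start"] + row["end"]) / 2.0
        sd = max((row["end"] - row["start"]) / 8.0, 1.0)
        a = (row["start"] - center) / sd
        b = (row["end"] - center) / sd
        pos = sps.truncnorm.rvs(a, b, loc=center, scale=sd, size=n_p, random_state=rng)
        mid_chrom[sel] = row["chrom"]
        mid_pos[sel] = pos.astype(np.int64)

    frag_len = np.maximum(np.rint(rng.normal(fragment_length_mean, fragment_length_sd,
                                             size=n_fragments)), min_length).astype(np.int64)
    starts = mid_pos - frag_len // 2
    ends = starts + frag_len
    out = pd.DataFrame({"chrom": mid_chrom, "start": starts, "end": ends})
    for c in chroms:
        m = out["chrom"] == c
        out.loc[m, "start"] = out.loc[m, "start"].clip(0, lengths[c] - 1)
        out.loc[m, "end"] = out.loc[m, "end"].clip(1, lengths[c])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


@dataclass
class CountParams:
    """NB count-model parameters (variance = mu + alpha * mu^2)."""
    mu: float = 100.0
    alpha: float = 0.05
    background_subset_sizes: Tuple[int, ...] = (3, 4)
    background_fold_range: Tuple[float, float] = (2.0, 2.8)
    variable_subset_sizes: Tuple[int, ...] = (3, 4)
    variable_fold_range: Tuple[float, float] = (8.0, 12.0)
    snp_fold: float = 8.0
    meth_base: float = 0.1
    meth_span: float = 4.0

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.alpha == 0:
            raise ValueError("alpha = 0 requested: use the Poisson limit alpha = 1e-8")


@dataclass
class TruthPlan:
    """Which planted role each site plays in the simulated count matrix.

    ``variable``: site ids with generic strong strain effects.
    ``common``: site ids with no strain effect at all.
    ``snp_driven``: site id -> genotype vector (per-strain 0/1).
    ``meth_driven``: site id -> (cpg_id, per-strain methylation fractions).
    Remaining sites are background with moderate strain effects.
    """
    variable: set = field(default_factory=set)
    common: set = field(default_factory=set)
    snp_driven: Dict[int, np.ndarray] = field(default_factory=dict)
    meth_driven: Dict[int, Tuple[int, np.ndarray]] = field(default_factory=dict)


def _log_uniform(rng, lo, hi, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def simulate_counts(union_sites: pd.DataFrame, strains: Sequence[str], reps: int,
                    params: CountParams, truth_plan: TruthPlan, seed: int):
    """NB counts per library at the union sites with planted structure.

    Background sites get fold-changes from ``background_fold_range`` in a
    random strain subset; planted variable sites get strong folds;
    SNP-driven sites follow mu * snp_fold ** genotype; methylation-driven
    sites follow mu * (meth_base + meth_span * (1 - methylation)).
    Returns (counts matrix, libraries DataFrame, SimTruth).
    """
    rng = np.random.default_rng(seed)
    n_sites = len(union_sites)
    S = len(strains)
    site_ids = union_sites["site_id"].to_numpy()
    means = np.full((n_sites, S), params.mu, dtype=float)
    truth = SimTruth()
    truth.variable_site_ids = set(truth_plan.variable)
    truth.common_site_ids = set(truth_plan.common)

    for i, sid in enumerate(site_ids):
        if sid in truth_plan.common:
            continue
        if sid in truth_plan.snp_driven:
            g = np.asarray(truth_plan.snp_driven[sid], dtype=float)
            means[i] = params.mu * params.snp_fold ** g
            truth.snp_driven[sid] = params.snp_fold
        elif sid in truth_plan.meth_driven:
            cpg_id, meth = truth_plan.meth_driven[sid]
            meth = np.asarray(meth, dtype=float)
            means[i] = params.mu * (params.meth_base + params.meth_span * (1.0 - meth))
            truth.methylation_driven[sid] = cpg_id
        elif sid in truth_plan.variable:
            k = min(int(rng.choice(params.variable_subset_sizes)), S - 1)
            subset = rng.choice(S, size=k, replace=False)
            fold = _log_uniform(rng, *params.variable_fold_range)
            means[i, subset] *= fold
        else:
            k = min(int(rng.choice(params.background_subset_sizes)), S - 1)
            subset = rng.choice(S, size=k, replace=False)
            fold = _log_uniform(rng, *params.background_fold_range)
            means[i, subset] *= fold

    libraries = pd.DataFrame(
        [{"library": f"{s}_rep{r + 1}", "strain": s, "replicate": r + 1}
         for s in strains for r in range(reps)])
    r_param = 1.0 / params.alpha
    counts = np.empty((n_sites, len(libraries)), dtype=np.int64)
    for j, lib in enumerate(libraries.itertuples(index=False)):
        s_idx = list(strains).index(lib.strain)
        mu = means[:, s_idx]
        p_nb = r_param / (r_param + mu)
        counts[:, j] = rng.negative_binomial(r_param, p_nb)
    truth.validate()
    return counts, libraries, truth


def simulate_methylation(cpg_positions: pd.DataFrame, strains: Sequence[str],
                         dm_plan: Dict[int, bool], seed: int,
                         loose_cpg_ids: Optional[set] = None,
                         variance_threshold: float = 0.05,
                         range_threshold: float = 0.75,
                         margin: float = 0.2) -> pd.DataFrame:
    """Per-CpG, per-strain methylation fractions.

    Planted DM CpGs are resampled until they satisfy the DM definition
    with a safety margin (variance > threshold * (1 + margin), range >
    threshold + a margin); planted non-DM CpGs are resampled until they
    fail it with the same margin, so the strict-threshold caller recovers
    exactly the planted set. ``loose_cpg_ids`` get a wider (but still
    non-DM) cross-strain spread, emulating the larger methylation
    variability of repeat-derived sequence.
    """
    rng = np.random.default_rng(seed)
    if "cpg_id" not in cpg_positions.columns:
        raise ValueError("cpg_positions needs a cpg_id column")
    known = set(cpg_positions["cpg_id"])
    unknown = set(dm_plan) - known
    if unknown:
        raise ValueError(f"dm_plan references unknown CpGs: {sorted(unknown)[:5]}")
    loose_cpg_ids = loose_cpg_ids or set()
    S = len(strains)
    var_hi = variance_threshold * (1.0 + margin)
    var_lo = variance_threshold * (1.0 - margin)
    rng_hi = min(range_threshold + 0.1, 0.99)
    rng_lo = range_threshold - 0.1

    rows = []
    for row in cpg_positions.itertuples(index=False):
        is_dm = bool(dm_plan.get(row.cpg_id, False))
        for _ in range(500):
            if is_dm:
                n_hi = int(rng.integers(2, max(3, S // 2 + 1)))
                hi_set = rng.choice(S, size=n_hi, replace=False)
                vals = rng.beta(2, 25, size=S) * 0.3          # low methylation
                vals[hi_set] = 1.0 - rng.beta(2, 25, size=n_hi) * 0.15
                ok = (np.var(vals, ddof=1) > var_hi
                      and vals.max() - vals.min() > rng_hi)
            elif row.cpg_id in loose_cpg_ids:
                base = rng.uniform(0.25, 0.75)
                vals = np.clip(base + rng.normal(0, 0.13, size=S), 0.0, 1.0)
                ok = (np.var(vals, ddof=1) < var_lo
                      and vals.max() - vals.min() < rng_lo)
            else:
                base = rng.uniform(0.05, 0.95)
                vals = np.clip(base + rng.normal(0, 0.03, size=S), 0.0, 1.0)
                ok = (np.var(vals, ddof=1) < var_lo
                      and vals.max() - vals.min() < rng_lo)
            if ok:
                break
        else:
            raise RuntimeError(f"could not satisfy methylation plan for CpG {row.cpg_id}")
        rows.append({"cpg_id": row.cpg_id, "chrom": row.chrom, "pos": row.pos,
                     **{s: round(float(v), 4) for s, v in zip(strains, vals)}})
    return pd.DataFrame(rows, columns=["cpg_id", "chrom", "pos", *strains])
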
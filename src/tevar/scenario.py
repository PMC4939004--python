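"""The default desk-scale synthetic scenario.

Seven inbred strains x two replicates over a 2 x 1 Mb genome carrying
~300 TE copies from seven subfamilies spanning 5-80 Myr of age, ~1000
planted accessible sites, strain SNPs, planted variable / common /
SNP-driven / methylation-driven site structure, a GAS-like motif planted
in young-LINE variable sites, planted polymorphic TEs, and an RRBS-like
CpG table. The composition is chosen so the analyses the package
implements have recoverable planted signal at this scale: variable sites
are concentrated at young LINEs, common sites at old SINEs, and
background sites carry moderate strain-to-strain variation so the
no-effect common sites sit at the bottom of the variability ranking.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .motifs import Pwm
from .simulate import (CountParams, TESubfamilySpec, TruthPlan,
                       simulate_fragments, simulate_genome, simulate_methylation,
                       simulate_strains)
from .types import GenomeSequence, SimTruth, SnpTable, TEInstance

STRAINS = ("C57BL6J", "AJ", "BALBcJ", "C3HHeJ", "CBAJ", "DBA2J", "FVBNJ")

GAS_CONSENSUS = "TTCCAGGAA"   # STAT-family gamma-activated-site-like motif
HNF4_CONSENSUS = "AGGTCAAAGGTCA"
CEBP_CONSENSUS = "TTGCGCAA"
CTCF_CONSENSUS = "CCGCGNGGNGGCAG".replace("N", "G")


def default_motif_set() -> List[Pwm]:
    return [
        Pwm.from_consensus("STAT_GAS", GAS_CONSENSUS),
        Pwm.from_consensus("HNF4", HNF4_CONSENSUS),
        Pwm.from_consensus("CEBP", CEBP_CONSENSUS),
        Pwm.from_consensus("CTCF", CTCF_CONSENSUS),
    ]


def default_te_spec() -> List[TESubfamilySpec]:
    return [
        TESubfamilySpec("L1Md_T", "LINE", "L1", 5000, 30, 8.0e6),
        TESubfamilySpec("L1Md_A", "LINE", "L1", 4000, 30, 5.0e6),
        TESubfamilySpec("L1_Mus", "LINE", "L1", 5000, 30, 8.0e7),
        TESubfamilySpec("B1_young", "SINE", "Alu", 150, 60, 1.0e7),
        TESubfamilySpec("B3_old", "SINE", "B2", 150, 60, 6.0e7),
        TESubfamilySpec("RLTR_young", "LTR", "ERVK", 500, 40, 1.5e7),
        TESubfamilySpec("MER_DNA", "DNA", "hAT", 300, 40, 7.0e7),
    ]


@dataclass
class ScenarioConfig:
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_strains: int = 7
    n_replicates: int = 2
    n_sites: int = 1000
    site_width: int = 400
    min_site_gap: int = 600
    snp_rate: float = 2e-3
    polymorphic_te_fraction: float = 0.10
    n_fragments_per_library: int = 80_000
    peak_enrichment_range: Tuple[float, float] = (12.0, 40.0)  # per-site, log-uniform
    variable_fraction: float = 0.05
    snp_driven_fraction: float = 0.30     # of variable sites
    n_meth_driven: int = 10
    motif_planting_fraction: float = 0.5  # of young-LINE variable sites
    n_extra_dm_cpgs: int = 8
    counts: CountParams = field(default_factory=CountParams)
    # site composition (class of TE each planted site overlaps, or unique)
    variable_composition: Dict[str, int] = field(default_factory=lambda: {
        "young_LINE": 30, "old_LINE": 3, "young_LTR": 3, "unique": 14})
    common_composition: Dict[str, int] = field(default_factory=lambda: {
        "old_SINE": 20, "old_LINE": 3, "young_LTR": 1, "unique": 26})


@dataclass
class Scenario:
    config: ScenarioConfig
    seed: int
    genome: GenomeSequence
    tes: List[TEInstance]
    snps: SnpTable
    carrier_table: pd.DataFrame
    planted_sites: pd.DataFrame          # site_id, chrom, start, end, role, te_id
    truth_plan: TruthPlan
    truth: SimTruth
    cpg_table: pd.DataFrame              # includes cpg_id
    dm_plan: Dict[int, bool]
    motif_set: List[Pwm]
    strains: Tuple[str, ...]

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _place_sites(rng, genome: GenomeSequence, tes: List[TEInstance],
                 cfg: ScenarioConfig) -> pd.DataFrame:
    """Choose ~n non-overlapping planted site intervals, each either
    anchored on a TE of a requested category or on unique sequence."""
    age_cut = 4.0e7
    cats: Dict[str, List[TEInstance]] = {
        "young_LINE": [], "old_LINE": [], "old_SINE": [], "young_SINE": [],
        "young_LTR": [], "DNA": []}
    for t in tes:
        if t.te_class == "LINE":
            cats["young_LINE" if t.age < age_cut else "old_LINE"].append(t)
        elif t.te_class == "SINE":
            cats["young_SINE" if t.age < age_cut else "old_SINE"].append(t)
        elif t.te_class == "LTR":
            cats["young_LTR"].append(t)
        elif t.te_class == "DNA":
            cats["DNA"].append(t)
    for v in cats.values():
        rng.shuffle(v)

    need: List[Tuple[str, Optional[TEInstance]]] = []
    for comp in (cfg.variable_composition, cfg.common_composition):
        for cat, n in comp.items():
            for _ in range(n):
                te = cats[cat].pop() if cat != "unique" and cats[cat] else None
                need.append((cat if te is not None or cat == "unique" else "unique", te))
    # remaining background sites: mix of leftover TEs and unique sequence
    n_background = cfg.n_sites - len(need)
    leftover = [t for v in cats.values() for t in v]
    rng.shuffle(leftover)
    n_bg_te = min(len(leftover), n_background // 3)
    for i in range(n_bg_te):
        need.append(("background_te", leftover[i]))
    for _ in range(n_background - n_bg_te):
        need.append(("unique", None))

    w = cfg.site_width
    chroms = list(genome)
    lengths = {c: len(genome[c]) for c in chroms}
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    te_intervals = {c: [(t.start, t.end) for t in tes if t.chrom == c] for c in chroms}

    def _free(chrom, s, e, avoid_te):
        if s < 0 or e > lengths[chrom]:
            return False
        for (os, oe) in occupied[chrom]:
            if s < oe + cfg.min_site_gap and os < e + cfg.min_site_gap:
                return False
        if avoid_te:
            for (os, oe) in te_intervals[chrom]:
                if s < oe and os < e:
                    return False
        return True

    rows = []
    for cat, te in need:
        placed = False
        if te is not None:
            # anchor the site on the element: centre it inside long TEs,
            # cover short ones entirely
            for _ in range(50):
                if te.length >= w:
                    s = int(rng.integers(te.start, te.end - w + 1))
                else:
                    lo = max(0, te.end - w)
                    hi = min(te.start, lengths[te.chrom] - w)
                    if hi < lo:
                        break
                    s = int(rng.integers(lo, hi + 1))
                if _free(te.chrom, s, s + w, avoid_te=False):
                    rows.append((te.chrom, s, s + w, cat, te.te_id))
                    occupied[te.chrom].append((s, s + w))
                    placed = True
                    break
        else:
            for _ in range(500):
                chrom = chroms[int(rng.integers(len(chroms)))]
                s = int(rng.integers(0, lengths[chrom] - w))
                if _free(chrom, s, s + w, avoid_te=True):
                    rows.append((chrom, s, s + w, cat, -1))
                    occupied[chrom].append((s, s + w))
                    placed = True
                    break
        if not placed and te is None:
            raise RuntimeError("could not place a unique site; genome too crowded")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "category", "te_id"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    df.insert(0, "site_id", np.arange(len(df)))
    return df


def _plant_motifs(rng, genome: GenomeSequence, sites: pd.DataFrame,
                  young_line_variable: Sequence[int], fraction: float) -> pd.DataFrame:
    """Overwrite the GAS-like motif into a fraction of the young-LINE
    variable sites (inside the central half of the site)."""
    ids = list(young_line_variable)
    rng.shuffle(ids)
    n_plant = int(round(fraction * len(ids)))
    arrays = {c: np.frombuffer(genome[c].encode(), dtype="S1").copy() for c in genome}
    rows = []
    motif = GAS_CONSENSUS
    for sid in ids[:n_plant]:
        row = sites[sites["site_id"] == sid].iloc[0]
        span = row["end"] - row["start"] - len(motif)
        off = int(rng.integers(span // 4, 3 * span // 4))
        s = int(row["start"] + off)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = motif if strand == "+" else motif.translate(
            str.maketrans("ACGT", "TGCA"))[::-1]
        arrays[row["chrom"]][s:s + len(motif)] = np.frombuffer(seq.encode(), dtype="S1")
        rows.append(("STAT_GAS", row["chrom"], s, s + len(motif), strand))
    for c in arrays:
        genome[c] = arrays[c].tobytes().decode()
    return pd.DataFrame(rows, columns=["motif", "chrom", "start", "end", "strand"])


def build_scenario(seed: int, config: Optional[ScenarioConfig] = None) -> Scenario:
    """Deterministically build the full synthetic study for one seed."""
    cfg = config or ScenarioConfig()
    root = np.random.SeedSequence(seed)
    seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
             for name, s in zip(
                 ["genome", "strains", "sites", "roles", "meth", "counts", "motif"],
                 root.spawn(7))}
    rng_sites = np.random.default_rng(seeds["sites"])
    rng_roles = np.random.default_rng(seeds["roles"])

    genome, tes, truth = simulate_genome(
        cfg.n_chroms, cfg.chrom_length, default_te_spec(), seeds["genome"])

    sites = _place_sites(rng_sites, genome, tes, cfg)
    # per-site accessibility strength (shared by all libraries): real peak
    # sets span a wide dynamic range, which is what makes replicate score
    # ranks concordant for genuine sites
    lo, hi = cfg.peak_enrichment_range
    sites["enrichment"] = np.exp(rng_sites.uniform(np.log(lo), np.log(hi),
                                                   size=len(sites))).round(3)

    # roles: the first len(variable_composition) placed sites are variable etc.
    n_var = sum(cfg.variable_composition.values())
    n_com = sum(cfg.common_composition.values())
    planted_order = sites.sort_values("site_id")
    # category bookkeeping: sites were appended variable-first, common-second,
    # background last, but sorting lost that order; recover via category + a
    # deterministic draw
    roles = {}
    var_ids: List[int] = []
    com_ids: List[int] = []
    by_cat: Dict[str, List[int]] = {}
    for row in planted_order.itertuples(index=False):
        by_cat.setdefault(row.category, []).append(row.site_id)
    for cat, ids in by_cat.items():
        by_cat[cat] = list(rng_roles.permutation(ids))
    for cat, n in cfg.variable_composition.items():
        take = by_cat.get(cat, [])[:n]
        var_ids.extend(take)
        by_cat[cat] = by_cat.get(cat, [])[n:]
    for cat, n in cfg.common_composition.items():
        take = by_cat.get(cat, [])[:n]
        com_ids.extend(take)
        by_cat[cat] = by_cat.get(cat, [])[n:]
    sites["role"] = "background"
    sites.loc[sites["site_id"].isin(var_ids), "role"] = "variable"
    sites.loc[sites["site_id"].isin(com_ids), "role"] = "common"

    # plant the motif into young-LINE variable site sequence before the
    # SNP table is drawn, so SNP ref alleles match the final reference
    young_line_var = [sid for sid in var_ids
                      if sites.loc[sites["site_id"] == sid, "category"].iloc[0]
                      == "young_LINE"]
    rng_motif = np.random.default_rng(seeds["motif"])
    planted_motifs = _plant_motifs(rng_motif, genome, sites, young_line_var,
                                   cfg.motif_planting_fraction)

    strains = list(STRAINS[:cfg.n_strains])
    snps, carrier_table = simulate_strains(
        genome, cfg.n_strains, cfg.snp_rate, cfg.polymorphic_te_fraction,
        seeds["strains"], tes=tes, strain_names=strains)

    # SNP-driven sites carry a causal SNP in the central half of the site
    # (peak calling recovers the accessible core, not the planted edges).
    # A pre-existing eligible SNP (2-4 alt carriers) is reused when one is
    # there; otherwise a causal SNP is planted at the site centre.
    n_snp_driven = int(round(cfg.snp_driven_fraction * len(var_ids)))
    chosen_sites = list(rng_roles.permutation(sorted(var_ids)))[:n_snp_driven]
    sf = snps.frame
    snp_driven = {}
    new_snps = []
    genome_arrays = {c: np.frombuffer(genome[c].encode(), dtype="S1") for c in genome}
    base_set = np.frombuffer(b"ACGT", dtype="S1")
    max_carriers = min(4, cfg.n_strains - 2)
    for sid in chosen_sites:
        row = sites[sites["site_id"] == sid].iloc[0]
        quarter = (row["end"] - row["start"]) // 4
        lo, hi = row["start"] + quarter, row["end"] - quarter
        inside = sf[(sf["chrom"] == row["chrom"]) & (sf["pos"] >= lo) & (sf["pos"] < hi)]
        g = None
        for snp in inside.itertuples(index=False):
            gv = np.array([getattr(snp, s) for s in strains])
            if 2 <= gv.sum() <= max_carriers:
                g = gv
                break
        if g is None:
            pos = int((lo + hi) // 2)
            while ((sf["chrom"] == row["chrom"]) & (sf["pos"] == pos)).any():
                pos += 1
            ref = genome_arrays[row["chrom"]][pos]
            alt = rng_roles.choice(base_set[base_set != ref]).decode()
            k = int(rng_roles.integers(2, max_carriers + 1))
            carriers = rng_roles.choice(cfg.n_strains, size=k, replace=False)
            g = np.zeros(cfg.n_strains, dtype=int)
            g[carriers] = 1
            new_snps.append({"chrom": row["chrom"], "pos": pos, "ref": ref.decode(),
                             "alt": alt, **{s: int(v) for s, v in zip(strains, g)}})
        snp_driven[sid] = g
    if new_snps:
        frame = pd.concat([sf, pd.DataFrame(new_snps)], ignore_index=True)
        frame = frame.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        snps = SnpTable(frame=frame, strains=strains)

    # methylation-driven: young-LINE variable sites not already SNP-driven
    meth_candidates = [sid for sid in young_line_var if sid not in snp_driven]
    meth_sites = list(rng_roles.permutation(meth_candidates))[:cfg.n_meth_driven]

    # CpGs: 2 per variable site, 1 per common site, plus scattered extras
    cpg_rows = []
    rng_meth = np.random.default_rng(seeds["meth"])
    for row in sites.itertuples(index=False):
        n_cpg = 2 if row.role == "variable" else (1 if row.role == "common" else 0)
        for _ in range(n_cpg):
            pos = int(rng_meth.integers(row.start + 10, row.end - 10))
            cpg_rows.append((row.chrom, pos, row.site_id))
    # extra CpGs on background TE sites (for the DM-in-TE contrast)
    bg_te = sites[(sites["role"] == "background") & (sites["te_id"] >= 0)]
    for row in bg_te.head(60).itertuples(index=False):
        pos = int(rng_meth.integers(row.start + 10, row.end - 10))
        cpg_rows.append((row.chrom, pos, row.site_id))
    cpg_positions = pd.DataFrame(cpg_rows, columns=["chrom", "pos", "site_id"])
    cpg_positions = cpg_positions.sort_values(["chrom", "pos"]).reset_index(drop=True)
    cpg_positions.insert(0, "cpg_id", np.arange(len(cpg_positions)))

    te_site_ids = set(sites.loc[sites["te_id"] >= 0, "site_id"])
    site_of_cpg = dict(zip(cpg_positions["cpg_id"], cpg_positions["site_id"]))
    cpg_of_site: Dict[int, List[int]] = {}
    for cid, sid in site_of_cpg.items():
        cpg_of_site.setdefault(sid, []).append(cid)

    dm_plan: Dict[int, bool] = {}
    meth_linked: Dict[int, int] = {}
    for sid in meth_sites:
        cid = cpg_of_site[sid][0]
        dm_plan[cid] = True
        meth_linked[sid] = cid
    # extra DM CpGs at TE sites that are not methylation-driven
    extra_pool = [cid for cid, sid in site_of_cpg.items()
                  if sid in te_site_ids and cid not in dm_plan]
    for cid in list(rng_meth.permutation(extra_pool))[:cfg.n_extra_dm_cpgs]:
        dm_plan[int(cid)] = True
    loose = {cid for cid, sid in site_of_cpg.items()
             if sid in te_site_ids and not dm_plan.get(cid, False)}

    cpg_table = simulate_methylation(cpg_positions, strains, dm_plan,
                                     seeds["meth"], loose_cpg_ids=loose)
    cpg_table = cpg_table.merge(cpg_positions[["cpg_id", "site_id"]], on="cpg_id")

    truth_plan = TruthPlan(
        variable=set(var_ids), common=set(com_ids), snp_driven=snp_driven,
        meth_driven={sid: (cid, cpg_table.loc[cpg_table["cpg_id"] == cid,
                                              strains].to_numpy()[0])
                     for sid, cid in meth_linked.items()})

    truth.variable_site_ids = set(var_ids)
    truth.common_site_ids = set(com_ids)
    truth.planted_peaks = sites.copy()
    truth.polymorphic_te_ids = {t.te_id: t.carrier_strains for t in tes if t.polymorphic}
    truth.planted_motifs = planted_motifs
    truth.dm_cpg_ids = {cid for cid, v in dm_plan.items() if v}

    return Scenario(config=cfg, seed=seed, genome=genome, tes=tes, snps=snps,
                    carrier_table=carrier_table, planted_sites=sites,
                    truth_plan=truth_plan, truth=truth, cpg_table=cpg_table,
                    dm_plan=dm_plan, motif_set=default_motif_set(),
                    strains=tuple(strains))


def scenario_fragments(scn: Scenario, library_seed: int) -> pd.DataFrame:
    """Fragments for one library: every planted site enriched at its
    site-specific strength."""
    plan = scn.planted_sites[["chrom", "start", "end", "enrichment"]].copy()
    return simulate_fragments(scn.genome, plan, scn.config.n_fragments_per_library,
                              seed=library_seed)
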
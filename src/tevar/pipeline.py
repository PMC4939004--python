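"""End-to-end orchestration of the synthetic study.

``run_all`` drives: genome/strain simulation -> pseudo-genomes ->
mappability -> fragment simulation -> per-library peak calling ->
replicate reproducibility -> cross-strain union -> NB counts at the union
-> quantile normalization + variability classification -> TE overlap and
enrichment -> SNP association -> methylation analyses -> motif
enrichment, persisting every stage under a run directory and emitting a
machine-readable report scored against the planted truth.

Stage outputs are pure functions of (config, seed): rerunning with the
same seed reproduces every persisted file byte for byte. Wall-clock
timings are written to run_log.json, which is the one file excluded from
that contract.
"""
from __future__ import annotations

import json
import time
import zlib
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import drivers, io, motifs, peaks, te, variability
from .config import AnalysisConfig
from .genome import build_pseudo_genome, mappability_track
from .scenario import Scenario, ScenarioConfig, build_scenario, scenario_fragments
from .simulate import simulate_counts
from .types import CpGTable, SiteMatrix


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (global seed + stage-name hash)."""
    return int((seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31))


def match_sites_to_planted(union: pd.DataFrame, planted: pd.DataFrame) -> pd.Series:
    """For each recovered union site, the planted site id with the largest
    overlap (or -1)."""
    out = np.full(len(union), -1, dtype=np.int64)
    for chrom in union["chrom"].unique():
        u = union[union["chrom"] == chrom]
        p = planted[planted["chrom"] == chrom].sort_values("start")
        if len(p) == 0:
            continue
        ps = p["start"].to_numpy()
        pe = p["end"].to_numpy()
        pid = p["site_id"].to_numpy()
        for idx, row in u.iterrows():
            ov = np.minimum(pe, row["end"]) - np.maximum(ps, row["start"])
            j = int(np.argmax(ov))
            if ov[j] > 0:
                out[idx] = pid[j]
    return pd.Series(out, index=union.index)


def run_all(config: Optional[AnalysisConfig] = None,
            scenario_config: Optional[ScenarioConfig] = None,
            out_dir: str | Path = "tevar_run", seed: Optional[int] = None,
            compute_mappability: bool = True) -> Dict:
    cfg = config or AnalysisConfig()
    scn_cfg = scenario_config or ScenarioConfig()
    if not (0 < cfg.variable_fraction < 0.5):
        raise ValueError("variable_fraction must be in (0, 0.5)")
    seed = cfg.rng_seed if seed is None else seed
    out = Path(out_dir)
    for sub in ("inputs", "peaks", "matrix", "results"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    timings: Dict[str, float] = {}
    report: Dict = {"seed": seed, "config": cfg.to_dict(), "stages": {}}

    def _stage(name):
        timings[name] = time.perf_counter()

    def _done(name, **counts):
        timings[name] = round(time.perf_counter() - timings[name], 3)
        report["stages"][name] = counts

    # ----- simulate inputs
    _stage("simulate")
    scn = build_scenario(stage_seed(seed, "scenario"), scn_cfg)
    io.write_fasta(scn.genome, out / "inputs" / "reference.fa")
    io.write_snv_vcf(scn.snps, out / "inputs" / "strains.vcf",
                     contig_lengths=scn.chrom_lengths)
    io.write_te_tsv(scn.tes, out / "inputs" / "tes.tsv")
    scn.planted_sites.to_csv(out / "inputs" / "planted_sites.tsv", sep="\t", index=False)
    scn.cpg_table.to_csv(out / "inputs" / "methylation.tsv", sep="\t", index=False)
    motifs.write_pwm_file(scn.motif_set, out / "inputs" / "motifs.pwm")
    _done("simulate", n_tes=len(scn.tes), n_snps=len(scn.snps),
          n_planted_sites=len(scn.planted_sites))

    # ----- pseudo-genomes
    _stage("pseudogenome")
    for strain in scn.strains:
        pg = build_pseudo_genome(scn.genome, scn.snps, strain)
        io.write_fasta(pg, out / "inputs" / f"pseudo_{strain}.fa")
    _done("pseudogenome", n_strains=len(scn.strains))

    # ----- mappability
    if compute_mappability:
        _stage("mappability")
        track = mappability_track(scn.genome, cfg.kmer_length, cfg.max_mismatches,
                                  max_total_bp=cfg.mappability_max_bp)
        io.write_bedgraph({c: np.nan_to_num(v, nan=0.0)
                           for c, v in track.scores.items()},
                          out / "results" / "mappability.bedgraph")
        mean_m = float(np.nanmean(np.concatenate(list(track.scores.values()))))
        _done("mappability", mean_score=round(mean_m, 6))

    # ----- fragments and peak calling
    _stage("peaks")
    per_strain_reproducible = []
    frag_counts = {}
    for strain in scn.strains:
        rep_peaks = []
        for rep in (1, 2):
            frags = scenario_fragments(scn, stage_seed(seed, f"frags_{strain}_{rep}"))
            frag_counts[f"{strain}_rep{rep}"] = frags
            called = peaks.call_peaks_genome(frags, scn.chrom_lengths,
                                             cfg.feature_length, cfg.peak_threshold_sd)
            io.write_bed(called.assign(name=".",
                                       score=called["score"].astype(float).round(6)),
                         out / "peaks" / f"{strain}_rep{rep}.bed")
            rep_peaks.append(called)
        repr_peaks = peaks.reproducible_peaks(rep_peaks[0], rep_peaks[1],
                                              cfg.idr_window, cfg.idr_discordance)
        io.write_bed(repr_peaks.assign(name=".", score=repr_peaks["score"].astype(float).round(6)),
                     out / "peaks" / f"{strain}_reproducible.bed")
        per_strain_reproducible.append(repr_peaks)
    union = peaks.union_sites(per_strain_reproducible)
    union.to_csv(out / "peaks" / "union_sites.bed", sep="\t", index=False, header=False)
    _done("peaks", n_union_sites=len(union),
          mean_reproducible=float(np.mean([len(p) for p in per_strain_reproducible])))

    # ----- fragment counts at the union (structural check output)
    _stage("fragment_counts")
    frag_matrix = peaks.count_matrix(frag_counts, union)
    libs_frag = pd.DataFrame({"library": list(frag_counts)})
    io.write_counts_tsv(union, frag_matrix, libs_frag,
                        out / "matrix" / "fragment_counts.tsv")
    _done("fragment_counts", total=int(frag_matrix.sum()))

    # ----- NB counts with planted truth at the recovered union sites
    _stage("counts")
    matched = match_sites_to_planted(union, scn.planted_sites)
    union_tr = union.copy()
    union_tr["planted_id"] = matched
    # carry the planted roles onto recovered sites via the planted id
    remap = {}
    planted_roles = scn.planted_sites.set_index("site_id")["role"]
    plan = scn.truth_plan
    from .simulate import TruthPlan
    plan_r = TruthPlan()
    for row in union_tr.itertuples(index=False):
        pid = row.planted_id
        if pid < 0:
            continue
        if pid in plan.snp_driven:
            plan_r.snp_driven[row.site_id] = plan.snp_driven[pid]
        if pid in plan.meth_driven:
            plan_r.meth_driven[row.site_id] = plan.meth_driven[pid]
        role = planted_roles.get(pid, "background")
        if role == "variable":
            plan_r.variable.add(row.site_id)
        elif role == "common":
            plan_r.common.add(row.site_id)
    plan_r.variable |= set(plan_r.snp_driven) | set(plan_r.meth_driven)
    counts, libraries, truth_counts = simulate_counts(
        union, scn.strains, scn_cfg.n_replicates, scn_cfg.counts, plan_r,
        stage_seed(seed, "counts"))
    io.write_counts_tsv(union, counts, libraries, out / "matrix" / "counts.tsv")
    _done("counts", n_sites=len(union), n_libraries=len(libraries))

    # ----- variability
    _stage("variability")
    normalized = variability.quantile_normalize(counts)
    io.write_counts_tsv(union, normalized.round(4), libraries,
                        out / "matrix" / "normalized.tsv")
    results = variability.nb_variability_test(normalized,
                                              libraries["strain"].tolist(), union)
    labeled = variability.classify_sites(results, cfg.variable_fraction)
    labeled.round(6).to_csv(out / "results" / "variability.tsv", sep="\t", index=False)
    matrix = SiteMatrix(sites=union, counts=counts, libraries=libraries,
                        normalized=normalized, results=labeled)
    variable_ids = set(labeled.loc[labeled["label"] == "variable", "site_id"])
    common_ids = set(labeled.loc[labeled["label"] == "common", "site_id"])
    _done("variability", n_variable=len(variable_ids), n_common=len(common_ids))

    # ----- TE analyses
    _stage("te")
    te.annotate_ages(scn.tes, cfg.substitution_rate)
    hit_table = te.overlap_tes(union, scn.tes)
    hit_table.to_csv(out / "results" / "te_hits.tsv", sep="\t", index=False)
    class_rows = [te.class_enrichment(hit_table, variable_ids, common_ids, c)
                  for c in te.TE_PROPER_CLASSES]
    class_df = pd.DataFrame(class_rows)
    class_df.to_csv(out / "results" / "class_enrichment.tsv", sep="\t", index=False)
    subfam = te.subfamily_enrichment(hit_table, variable_ids, common_ids)
    subfam.to_csv(out / "results" / "subfamily_enrichment.tsv", sep="\t", index=False)
    ages_var = hit_table.loc[hit_table["site_id"].isin(variable_ids), "age"]
    ages_com = hit_table.loc[hit_table["site_id"].isin(common_ids), "age"]
    age_p = (te.age_distribution_compare(ages_var, ages_com)
             if len(ages_var) and len(ages_com) else float("nan"))
    poly = te.polymorphic_fraction(hit_table, variable_ids, matrix)
    _done("te", n_hits=len(hit_table), age_wilcoxon_p=age_p,
          line_fisher_p=float(class_df.loc[class_df["te_class"] == "LINE", "p"].iloc[0]),
          polymorphic_fraction=poly["fraction"])

    # ----- SNP association
    _stage("assoc")
    frac_snp, assoc = drivers.fraction_snp_explained(matrix, scn.snps, variable_ids)
    assoc.round(6).to_csv(out / "results" / "snp_association.tsv", sep="\t", index=False)
    _done("assoc", fraction_snp_explained=frac_snp, n_tests=len(assoc))

    # ----- methylation
    _stage("methylation")
    cpg = CpGTable(frame=scn.cpg_table.drop(columns=["site_id"]),
                   strains=list(scn.strains))
    cpg = drivers.drop_polymorphic_cpgs(cpg, scn.snps)
    dm_table = drivers.call_dm_cpgs(cpg, cfg.dm_variance_threshold,
                                    cfg.dm_range_threshold)
    dm_table.round(6).to_csv(out / "results" / "dm_cpgs.tsv", sep="\t", index=False)
    groups, meth_p = drivers.methylation_variance_by_group(
        dm_table, union, hit_table, variable_ids)
    in_te = _cpg_in_te(dm_table, scn.tes)
    dm_enrich = drivers.dm_te_enrichment(dm_table, in_te)
    recovered_dm = set(dm_table.loc[dm_table["dm"], "cpg_id"]) \
        if "cpg_id" in dm_table.columns else set()
    planted_dm = scn.truth.dm_cpg_ids & set(cpg.frame.get("cpg_id", []))
    _done("methylation", n_dm=int(dm_table["dm"].sum()),
          dm_te_fisher_p=dm_enrich["p"], te_vs_unique_wilcoxon_p=meth_p,
          dm_exact_recovery=bool(recovered_dm == planted_dm))

    # ----- motifs
    _stage("motifs")
    young_ids = set(hit_table.loc[(hit_table["te_class"] == "LINE")
                                  & (hit_table["age"] < cfg.age_cutoff), "site_id"])
    old_ids = set(hit_table.loc[(hit_table["te_class"] == "LINE")
                                & (hit_table["age"] >= cfg.age_cutoff), "site_id"])
    seqs = _site_sequences(scn.genome, union)
    targets_young = [seqs[s] for s in sorted(variable_ids & young_ids)]
    targets_old = [seqs[s] for s in sorted(variable_ids & old_ids)]
    pool = [seqs[s] for s in sorted(set(seqs) - variable_ids)]
    enrich_young = enrich_old = pd.DataFrame()
    if targets_young:
        bg = motifs.gc_matched_background(targets_young, pool,
                                          stage_seed(seed, "motif_bg_young"),
                                          cfg.gc_background_ratio, cfg.gc_bin_width)
        enrich_young = motifs.motif_enrichment(targets_young, bg, scn.motif_set,
                                               cfg.motif_p_threshold,
                                               cfg.motif_occurrence_fraction)
        enrich_young.to_csv(out / "results" / "motif_enrichment_young_lines.tsv",
                            sep="\t", index=False)
    if targets_old:
        bg = motifs.gc_matched_background(targets_old, pool,
                                          stage_seed(seed, "motif_bg_old"),
                                          cfg.gc_background_ratio, cfg.gc_bin_width)
        enrich_old = motifs.motif_enrichment(targets_old, bg, scn.motif_set,
                                             cfg.motif_p_threshold,
                                             cfg.motif_occurrence_fraction)
        enrich_old.to_csv(out / "results" / "motif_enrichment_old_lines.tsv",
                          sep="\t", index=False)
    gas_selected = bool(len(enrich_young)
                        and enrich_young.set_index("motif").loc["STAT_GAS", "selected"])
    _done("motifs", n_young_targets=len(targets_young),
          n_old_targets=len(targets_old), gas_selected_young=gas_selected)

    # ----- recovery metrics vs truth
    recovered_var_planted = {int(union_tr.loc[union_tr["site_id"] == s,
                                              "planted_id"].iloc[0])
                             for s in variable_ids}
    recovered_com_planted = {int(union_tr.loc[union_tr["site_id"] == s,
                                              "planted_id"].iloc[0])
                             for s in common_ids}
    planted_var = scn.truth.variable_site_ids
    planted_com = scn.truth.common_site_ids
    report["recovery"] = {
        "variable_recall": len(recovered_var_planted & planted_var) / len(planted_var),
        "variable_precision": (len(recovered_var_planted & planted_var)
                               / max(len(variable_ids), 1)),
        "common_recall": len(recovered_com_planted & planted_com) / len(planted_com),
        "fraction_snp_explained": frac_snp,
        "planted_snp_fraction": len(plan_r.snp_driven) / max(len(plan_r.variable), 1),
        "dm_exact_recovery": bool(recovered_dm == planted_dm),
        "line_fisher_p": float(class_df.loc[class_df["te_class"] == "LINE",
                                            "p"].iloc[0]),
        "age_wilcoxon_p": age_p,
        "gas_motif_selected_young": gas_selected,
        "polymorphic_fraction": poly["fraction"],
    }
    report["n_union_sites"] = len(union)

    with open(out / "results" / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "run_log.json", "w") as fh:
        json.dump({"timings_s": timings}, fh, indent=2)
    return report


def _cpg_in_te(dm_table: pd.DataFrame, tes) -> np.ndarray:
    from .types import te_list_to_frame
    te_df = te_list_to_frame(tes)
    out = np.zeros(len(dm_table), dtype=bool)
    for chrom in dm_table["chrom"].unique():
        t = te_df[te_df["chrom"] == chrom].sort_values("start")
        if len(t) == 0:
            continue
        starts = t["start"].to_numpy()
        ends = t["end"].to_numpy()
        sel = (dm_table["chrom"] == chrom).to_numpy()
        pos = dm_table.loc[sel, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        out[sel] = ok
    return out


def _site_sequences(genome, sites: pd.DataFrame) -> Dict[int, str]:
    return {int(r.site_id): genome[r.chrom][int(r.start):int(r.end)]
            for r in sites.itertuples(index=False)}
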
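"""Attribution of chromatin variability to SNP genotype and to
differential DNA methylation.

SNP association: the seven homozygous strain genotypes at a SNP form a
0/1 vector which is regressed (OLS) against the strains'
replicate-averaged normalized accessibility at the overlapping site; the
F test (1, n-2 df) gives the p-value. A variable site is "SNP-explained"
when at least one overlapping SNP's BH-adjusted p falls below alpha.

Differential methylation: a CpG is DM when its cross-strain sample
variance exceeds 0.05 AND its methylation range exceeds 0.75 (both
strict). Polymorphic CpGs (coinciding with a SNP) are removed before any
variance computation.
"""
from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import assign_points
from .stats import bh_adjust, fisher_exact_two_sided, wilcoxon_rank_sum
from .types import CpGTable, SiteMatrix, SnpTable

log = logging.getLogger(__name__)


# ------------------------------------------------------------ SNP association

def snp_association(matrix: SiteMatrix, snps: SnpTable,
                    site_ids: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """OLS of per-strain accessibility on genotype for every SNP inside
    each requested site. Constant genotype vectors are flagged, not
    errors. Returns one row per (site, SNP) pair."""
    strains = matrix.strains
    if len(strains) < 3:
        raise ValueError("need >= 3 strains for regression")
    shared = [s for s in strains if s in snps.strains]
    if len(shared) < 3:
        raise ValueError("fewer than 3 strains shared between matrix and SNP table")
    means = matrix.strain_means(normalized=True)

    sites = matrix.sites
    if site_ids is not None:
        sites = sites[sites["site_id"].isin(set(site_ids))]
    site_lookup = sites.reset_index(drop=True)
    snp_site = assign_points(snps.frame["chrom"].to_numpy(),
                             snps.frame["pos"].to_numpy(), site_lookup)
    rows = []
    for i in np.flatnonzero(snp_site >= 0):
        snp = snps.frame.iloc[i]
        site_id = int(site_lookup.iloc[snp_site[i]]["site_id"])
        g = np.array([snp[s] for s in shared], dtype=float)
        y = means.loc[site_id, shared].to_numpy(dtype=float)
        if np.all(g == g[0]):
            rows.append({"site_id": site_id, "chrom": snp["chrom"], "pos": int(snp["pos"]),
                         "slope": np.nan, "r_squared": np.nan, "p": np.nan,
                         "note": "constant_genotype"})
            continue
        res = sps.linregress(g, y)
        rows.append({"site_id": site_id, "chrom": snp["chrom"], "pos": int(snp["pos"]),
                     "slope": res.slope, "r_squared": res.rvalue ** 2,
                     "p": res.pvalue, "note": ""})
    return pd.DataFrame(rows, columns=["site_id", "chrom", "pos", "slope",
                                       "r_squared", "p", "note"])


def fraction_snp_explained(matrix: SiteMatrix, snps: SnpTable,
                           variable_ids: Set[int], alpha: float = 0.05):
    """Fraction of variable sites with >= 1 overlapping SNP whose
    BH-adjusted association p < alpha. Returns (fraction, association
    table with adjusted p)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    assoc = snp_association(matrix, snps, site_ids=sorted(variable_ids))
    if len(assoc) == 0:
        log.info("fraction_snp_explained: no variable site overlaps a SNP")
        return 0.0, assoc
    testable = assoc["p"].notna()
    assoc["adjusted_p"] = np.nan
    if testable.any():
        assoc.loc[testable, "adjusted_p"] = bh_adjust(assoc.loc[testable, "p"].to_numpy())
    explained = set(assoc.loc[assoc["adjusted_p"] < alpha, "site_id"])
    return len(explained & variable_ids) / len(variable_ids), assoc


# --------------------------------------------------------------- methylation

def drop_polymorphic_cpgs(table: CpGTable, snps: SnpTable) -> CpGTable:
    """Remove CpGs whose position coincides with a SNP."""
    snp_keys = set(zip(snps.frame["chrom"], snps.frame["pos"]))
    keep = [not ((c, p) in snp_keys or (c, p + 1) in snp_keys)
            for c, p in zip(table.frame["chrom"], table.frame["pos"])]
    return CpGTable(frame=table.frame[keep].reset_index(drop=True),
                    strains=table.strains)


def call_dm_cpgs(table: CpGTable, variance_threshold: float = 0.05,
                 range_threshold: float = 0.75) -> pd.DataFrame:
    """Per-CpG variance (sample, n-1), range, and the strict-conjunction
    DM flag. CpGs with < 2 non-missing strains are flagged untestable."""
    vals = table.frame[table.strains].to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(vals), axis=1)
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        variance = np.where(n_obs >= 2, np.nanvar(vals, axis=1, ddof=1), np.nan)
        vrange = np.where(n_obs >= 2,
                          np.nanmax(vals, axis=1) - np.nanmin(vals, axis=1), np.nan)
    dm = (variance > variance_threshold) & (vrange > range_threshold)
    dm = np.where(n_obs >= 2, dm, False).astype(bool)
    out = table.frame[["chrom", "pos"]].copy()
    if "cpg_id" in table.frame.columns:
        out.insert(0, "cpg_id", table.frame["cpg_id"])
    out["n_strains"] = n_obs
    out["variance"] = variance
    out["range"] = vrange
    out["dm"] = dm
    out["testable"] = n_obs >= 2
    return out


def methylation_variance_by_group(dm_table: pd.DataFrame, sites: pd.DataFrame,
                                  hit_table: pd.DataFrame,
                                  variable_ids: Set[int]):
    """CpG methylation variance within variable sites, grouped by the
    site's annotation (TE > other-repeat > unique precedence); returns
    (per-group variance dict, TE-vs-unique Wilcoxon p)."""
    var_sites = sites[sites["site_id"].isin(variable_ids)].reset_index(drop=True)
    cpg_site = assign_points(dm_table["chrom"].to_numpy(),
                             dm_table["pos"].to_numpy(), var_sites)
    te_sites = set(hit_table.loc[hit_table["te_class"] != "Other", "site_id"])
    repeat_sites = set(hit_table.loc[hit_table["te_class"] == "Other", "site_id"])
    groups: Dict[str, list] = {"TE": [], "other_repeat": [], "unique": []}
    for i in np.flatnonzero(cpg_site >= 0):
        site_id = int(var_sites.iloc[cpg_site[i]]["site_id"])
        v = dm_table.iloc[i]["variance"]
        if np.isnan(v):
            continue
        if site_id in te_sites:
            groups["TE"].append(v)
        elif site_id in repeat_sites:
            groups["other_repeat"].append(v)
        else:
            groups["unique"].append(v)
    for name in [k for k, v in groups.items() if not v]:
        log.info("methylation_variance_by_group: empty group %s", name)
    if groups["TE"] and groups["unique"]:
        if (len(set(groups["TE"])) == 1 and set(groups["TE"]) == set(groups["unique"])):
            p = 1.0
        else:
            p = wilcoxon_rank_sum(groups["TE"], groups["unique"])
    else:
        p = np.nan
    return {k: np.asarray(v) for k, v in groups.items() if v}, p


def dm_te_enrichment(dm_table: pd.DataFrame, in_te: np.ndarray) -> Dict[str, float]:
    """Fisher 2x2 of (DM / not DM) x (in TE / not in TE) over testable CpGs."""
    in_te = np.asarray(in_te, dtype=bool)
    testable = dm_table["testable"].to_numpy(dtype=bool)
    dm = dm_table["dm"].to_numpy(dtype=bool) & testable
    a = int(np.sum(dm & in_te & testable))
    b = int(np.sum(dm & ~in_te & testable))
    c = int(np.sum(~dm & in_te & testable))
    d = int(np.sum(~dm & ~in_te & testable))
    p = fisher_exact_two_sided(a, b, c, d) if (a + b + c + d) else 1.0
    frac_in = a / (a + c) if a + c else 0.0
    frac_out = b / (b + d) if b + d else 0.0
    return {"dm_in_te": a, "dm_outside": b, "other_in_te": c, "other_outside": d,
            "dm_fraction_in_te": frac_in, "dm_fraction_outside": frac_out, "p": p}
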
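"""TE overlap, age, enrichment and boundary-profile analyses.

A site hits a TE when the intervals share >= 1 bp. For class-level
proportions a site counts once per class no matter how many instances it
spans; for subfamily tallies every overlapped instance counts. TE age is
divergence / substitution_rate (4.5e-9 substitutions per site per year
for mouse); 40 Myr separates "young" from "old" elements.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_exact_two_sided, wilcoxon_rank_sum
from .types import SiteMatrix, TEInstance, te_list_to_frame

log = logging.getLogger(__name__)

TE_PROPER_CLASSES = ("LINE", "SINE", "LTR", "DNA")


def te_age(divergence, substitution_rate: float = 4.5e-9):
    """Years since insertion: divergence / substitution_rate (exact quotient)."""
    if substitution_rate <= 0:
        raise ValueError("substitution_rate must be > 0")
    d = np.asarray(divergence, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("divergence must be in [0, 1]")
    out = d / substitution_rate
    return float(out) if np.isscalar(divergence) else out


def annotate_ages(tes: Sequence[TEInstance], substitution_rate: float = 4.5e-9) -> None:
    for t in tes:
        t.age = te_age(t.divergence, substitution_rate)


def overlap_tes(sites: pd.DataFrame, tes: Sequence[TEInstance] | pd.DataFrame) -> pd.DataFrame:
    """Per-site TE hit table: one row per (site, TE instance) pair sharing
    >= 1 bp, carrying the TE's class/subfamily/age columns."""
    te_df = tes if isinstance(tes, pd.DataFrame) else te_list_to_frame(tes)
    hits = []
    for chrom in sites["chrom"].unique():
        sv = sites[sites["chrom"] == chrom]
        tv = te_df[te_df["chrom"] == chrom].sort_values("start")
        if len(tv) == 0:
            continue
        t_start = tv["start"].to_numpy()
        t_end = tv["end"].to_numpy()
        for row in sv.itertuples(index=False):
            hi = np.searchsorted(t_start, row.end, side="left")
            cand = np.flatnonzero(t_end[:hi] > row.start)
            for j in cand:
                t = tv.iloc[j]
                hits.append((row.site_id, t["te_id"], t["te_class"], t["family"],
                             t["subfamily"], t["divergence"], t["age"],
                             t["end"] - t["start"], bool(t["polymorphic"]),
                             t.get("carrier_strains", "")))
    return pd.DataFrame(hits, columns=["site_id", "te_id", "te_class", "family",
                                       "subfamily", "divergence", "age",
                                       "te_length", "polymorphic",
                                       "carrier_strains"])


def _class_hit_sites(hit_table: pd.DataFrame, te_class: str) -> set:
    return set(hit_table.loc[hit_table["te_class"] == te_class, "site_id"])


def class_enrichment(hit_table: pd.DataFrame, variable_ids: set, common_ids: set,
                     te_class: str) -> Dict[str, float]:
    """Fisher 2x2 of (variable/common) x (hits the class / does not)."""
    if not variable_ids or not common_ids:
        raise ValueError("both site sets must be nonempty")
    hit_sites = _class_hit_sites(hit_table, te_class)
    a = len(variable_ids & hit_sites)
    b = len(variable_ids) - a
    c = len(common_ids & hit_sites)
    d = len(common_ids) - c
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        p = 1.0
    else:
        p = fisher_exact_two_sided(a, b, c, d)
    return {"te_class": te_class,
            "variable_hit": a, "variable_total": len(variable_ids),
            "common_hit": c, "common_total": len(common_ids),
            "variable_proportion": a / len(variable_ids),
            "common_proportion": c / len(common_ids),
            "p": p}


def subfamily_enrichment(hit_table: pd.DataFrame, variable_ids: set,
                         common_ids: set, min_hits: int = 5) -> pd.DataFrame:
    """Per-subfamily Fisher tests (sites hitting subfamily vs not, variable
    vs common), BH-corrected; subfamilies with < ``min_hits`` variable+common
    hit sites are excluded. Instance-level tallies are also reported."""
    vc = hit_table[hit_table["site_id"].isin(variable_ids | common_ids)]
    rows = []
    for subfam, grp in vc.groupby("subfamily", sort=True):
        sites_hit = set(grp["site_id"])
        n_hit = len(sites_hit & variable_ids) + len(sites_hit & common_ids)
        if n_hit < min_hits:
            continue
        a = len(sites_hit & variable_ids)
        b = len(variable_ids) - a
        c = len(sites_hit & common_ids)
        d = len(common_ids) - c
        p = fisher_exact_two_sided(a, b, c, d)
        rows.append({"subfamily": subfam, "variable_sites": a, "common_sites": c,
                     "variable_instances": int((grp["site_id"].isin(variable_ids)).sum()),
                     "common_instances": int((grp["site_id"].isin(common_ids)).sum()),
                     "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["adjusted_p"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p").reset_index(drop=True)
    return out


def age_distribution_compare(ages_a: Sequence[float], ages_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p comparing two TE age samples."""
    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both age samples must be nonempty")
    return wilcoxon_rank_sum(a, b)


def subfamily_accessibility_matrix(matrix: SiteMatrix, hit_table: pd.DataFrame,
                                   min_sites: int = 1) -> pd.DataFrame:
    """Subfamily x strain matrix of mean replicate-averaged normalized
    signal over sites hitting the subfamily, z-scored within each row."""
    means = matrix.strain_means(normalized=True)
    rows = {}
    for subfam, grp in hit_table.groupby("subfamily", sort=True):
        ids = grp["site_id"].unique()
        ids = [i for i in ids if i in means.index]
        if len(ids) < min_sites:
            continue
        rows[subfam] = means.loc[ids].mean(axis=0)
    if not rows:
        return pd.DataFrame(columns=means.columns)
    df = pd.DataFrame(rows).T
    sd = df.std(axis=1, ddof=0)
    centered = df.sub(df.mean(axis=1), axis=0)
    z = centered.div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return z


def polymorphic_fraction(hit_table: pd.DataFrame, variable_ids: set,
                         matrix: Optional[SiteMatrix] = None) -> Dict:
    """Fraction of TE instances hit by variable sites that are polymorphic,
    plus (when a matrix is given) a per-site concordance flag: the top-half
    strains by normalized signal equal the carrier set."""
    var_hits = hit_table[hit_table["site_id"].isin(variable_ids)]
    te_ids = var_hits["te_id"].unique()
    if len(te_ids) == 0:
        return {"fraction": 0.0, "n_polymorphic": 0, "n_te": 0, "concordance": {}}
    poly = var_hits.drop_duplicates("te_id").set_index("te_id")["polymorphic"]
    n_poly = int(poly.sum())
    concordance = {}
    if matrix is not None and matrix.results is not None:
        means = matrix.strain_means(normalized=True)
        half = len(matrix.strains) // 2
        carriers_by_te = {}
        if "carrier_strains" in hit_table.columns:
            carriers_by_te = dict(zip(hit_table["te_id"], hit_table.get("carrier_strains", "")))
        for row in var_hits.itertuples(index=False):
            if not row.polymorphic or row.site_id not in means.index:
                continue
            ranked = means.loc[row.site_id].sort_values(ascending=False)
            accessible = set(ranked.index[:half])
            carriers = carriers_by_te.get(row.te_id, "")
            carrier_set = set(str(carriers).split(",")) - {""}
            concordance[(row.site_id, row.te_id)] = accessible == carrier_set
    return {"fraction": n_poly / len(te_ids), "n_polymorphic": n_poly,
            "n_te": int(len(te_ids)), "concordance": concordance}


@dataclass
class BoundaryProfiles:
    """Per-TE coverage around element boundaries and per-stratum aggregates.

    ``five_prime`` / ``three_prime``: (n_te, 2*flank/bin) matrices, rows in
    age-ascending order; 3' rows are flipped so genome-outside always lies
    to the right of the boundary column. ``aggregate``: per length stratum,
    mean coverage over flank + unit-rescaled body + flank.
    """

    five_prime: np.ndarray
    three_prime: np.ndarray
    te_order: pd.DataFrame
    aggregate: Dict[str, np.ndarray]
    bin_size: int
    flank: int


DEFAULT_LENGTH_STRATA = ((0, 1000), (1000, 3000), (3000, 6000), (6000, np.inf))


def boundary_profile(coverage: Dict[str, np.ndarray],
                     tes: Sequence[TEInstance] | pd.DataFrame,
                     flank: int = 2500, bin_size: int = 50,
                     length_strata: Tuple = DEFAULT_LENGTH_STRATA,
                     body_bins: int = 40) -> BoundaryProfiles:
    te_df = tes if isinstance(tes, pd.DataFrame) else te_list_to_frame(tes)
    n_bins = 2 * flank // bin_size
    rows5, rows3, kept = [], [], []
    n_skipped = 0
    for row in te_df.itertuples(index=False):
        if row.end - row.start < 2 * bin_size:
            n_skipped += 1
            continue
        cov = coverage.get(row.chrom)
        if cov is None:
            continue
        five = _binned(cov, row.start - flank, row.start + flank, bin_size)
        three = _binned(cov, row.end - flank, row.end + flank, bin_size)[::-1]
        rows5.append(five)
        rows3.append(three)
        kept.append(row)
    if n_skipped:
        log.info("boundary_profile: skipped %d TEs shorter than 2 bins", n_skipped)
    if not kept:
        return BoundaryProfiles(np.zeros((0, n_bins)), np.zeros((0, n_bins)),
                                pd.DataFrame(), {}, bin_size, flank)
    order_df = pd.DataFrame([r._asdict() for r in kept])
    order = np.argsort(order_df["age"].to_numpy(), kind="mergesort")
    order_df = order_df.iloc[order].reset_index(drop=True)
    m5 = np.asarray(rows5)[order]
    m3 = np.asarray(rows3)[order]

    flank_bins = flank // bin_size
    aggregate = {}
    for lo, hi in length_strata:
        sel = order_df[(order_df["end"] - order_df["start"] >= lo)
                       & (order_df["end"] - order_df["start"] < hi)]
        if len(sel) == 0:
            continue
        curves = []
        for row in sel.itertuples(index=False):
            cov = coverage[row.chrom]
            left = _binned(cov, row.start - flank, row.start, bin_size)
            right = _binned(cov, row.end, row.end + flank, bin_size)
            body = _unit_body(cov, row.start, row.end, body_bins)
            curves.append(np.concatenate([left, body, right]))
        label = f"{lo}-{hi if np.isfinite(hi) else 'inf'}"
        aggregate[label] = np.mean(curves, axis=0)
    return BoundaryProfiles(m5, m3, order_df, aggregate, bin_size, flank)


def _binned(cov: np.ndarray, start: int, end: int, bin_size: int) -> np.ndarray:
    n = (end - start) // bin_size
    out = np.zeros(n)
    for i in range(n):
        s = start + i * bin_size
        e = s + bin_size
        s_c, e_c = max(s, 0), min(e, cov.size)
        if e_c > s_c:
            out[i] = cov[s_c:e_c].sum() / bin_size
    return out


def _unit_body(cov: np.ndarray, start: int, end: int, body_bins: int) -> np.ndarray:
    edges = np.linspace(start, end, body_bins + 1).astype(int)
    out = np.zeros(body_bins)
    for i in range(body_bins):
        s, e = edges[i], max(edges[i + 1], edges[i] + 1)
        s_c, e_c = max(s, 0), min(e, cov.size)
        if e_c > s_c:
            out[i] = cov[s_c:e_c].mean()
    return out
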
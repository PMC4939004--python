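"""TE overlap, age, enrichment and boundary profiles."""
from math import comb

import numpy as np
import pandas as pd
import pytest

from tevar.te import (age_distribution_compare, boundary_profile,
                      class_enrichment, overlap_tes, polymorphic_fraction,
                      subfamily_accessibility_matrix, subfamily_enrichment,
                      te_age)
from tevar.types import SiteMatrix, TEInstance


def _te(chrom="chr1", start=0, end=1000, te_class="LINE", subfamily="L1Md_T",
        divergence=0.05, te_id=0, **kw):
    return TEInstance(chrom=chrom, start=start, end=end, strand="+",
                      te_class=te_class, family="L1", subfamily=subfamily,
                      divergence=divergence, age=divergence / 4.5e-9,
                      te_id=te_id, **kw)


def _sites(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df.insert(0, "site_id", np.arange(len(df)))
    return df


# ---------------------------------------------------------------- te_age

def test_age_formula_exact_values():
    assert te_age(0.0) == 0.0
    assert te_age(0.045) == pytest.approx(1.0e7)
    assert te_age(0.18) == pytest.approx(4.0e7)   # the young/old cutoff
    assert te_age(0.09, substitution_rate=4.5e-9) == pytest.approx(2.0e7)


def test_age_is_monotone_in_divergence():
    d = np.linspace(0, 0.5, 50)
    ages = te_age(d)
    assert np.all(np.diff(ages) > 0)


def test_age_validation():
    with pytest.raises(ValueError):
        te_age(0.1, substitution_rate=0)
    with pytest.raises(ValueError):
        te_age(1.5)


# ------------------------------------------------------------ overlap_tes

def test_overlap_boundary_semantics():
    sites = _sites([("chr1", 100, 200)])
    one_bp = overlap_tes(sites, [_te(start=199, end=300)])
    assert len(one_bp) == 1
    bookended = overlap_tes(sites, [_te(start=200, end=300)])
    assert len(bookended) == 0


def test_site_spanning_two_lines_counts_class_once_subfamilies_twice():
    sites = _sites([("chr1", 0, 5000)])
    tes = [_te(start=100, end=1100, subfamily="L1Md_T", te_id=0),
           _te(start=2000, end=3000, subfamily="L1Md_A", te_id=1)]
    hits = overlap_tes(sites, tes)
    assert len(hits) == 2                       # two instance-level rows
    assert hits["site_id"].nunique() == 1       # one site for class flags


# ------------------------------------------------------- class_enrichment

def test_class_enrichment_identical_proportions():
    sites = _sites([("chr1", i * 1000, i * 1000 + 100) for i in range(20)])
    tes = [_te(start=i * 1000, end=i * 1000 + 100, te_id=i)
           for i in list(range(5)) + list(range(10, 15))]
    hits = overlap_tes(sites, tes)
    res = class_enrichment(hits, set(range(10)), set(range(10, 20)), "LINE")
    assert res["p"] == pytest.approx(1.0)
    assert res["variable_proportion"] == res["common_proportion"] == 0.5


def test_class_enrichment_diagonal_matches_closed_form():
    sites = _sites([("chr1", i * 1000, i * 1000 + 100) for i in range(20)])
    tes = [_te(start=i * 1000, end=i * 1000 + 100, te_id=i) for i in range(10)]
    hits = overlap_tes(sites, tes)
    res = class_enrichment(hits, set(range(10)), set(range(10, 20)), "LINE")
    assert res["p"] == pytest.approx(2 / comb(20, 10), rel=1e-9)


def test_class_enrichment_planted_difference_significant(rng):
    # 40% vs 20% hit proportions at n = 500 per group
    n = 500
    sites = _sites([("chr1", i * 1000, i * 1000 + 100) for i in range(2 * n)])
    hit_ids = list(rng.choice(n, size=200, replace=False)) \
        + [n + i for i in rng.choice(n, size=100, replace=False)]
    tes = [_te(start=i * 1000, end=i * 1000 + 100, te_id=j)
           for j, i in enumerate(hit_ids)]
    hits = overlap_tes(sites, tes)
    res = class_enrichment(hits, set(range(n)), set(range(n, 2 * n)), "LINE")
    assert res["p"] < 0.001


def test_class_enrichment_empty_group_rejected():
    hits = pd.DataFrame(columns=["site_id", "te_class"])
    with pytest.raises(ValueError):
        class_enrichment(hits, set(), {1}, "LINE")


# --------------------------------------------------- subfamily_enrichment

def test_subfamily_exclusive_to_variable_ranks_first():
    sites = _sites([("chr1", i * 1000, i * 1000 + 100) for i in range(1000)])
    tes = ([_te(start=i * 1000, end=i * 1000 + 100, subfamily="EXC", te_id=i)
            for i in range(20)]
           + [_te(start=(100 + i) * 1000, end=(100 + i) * 1000 + 100,
                  subfamily="BAL", te_id=100 + i) for i in range(10)]
           + [_te(start=(600 + i) * 1000, end=(600 + i) * 1000 + 100,
                  subfamily="BAL", te_id=600 + i) for i in range(10)])
    hits = overlap_tes(sites, tes)
    var, com = set(range(500)), set(range(500, 1000))
    res = subfamily_enrichment(hits, var, com)
    assert res.iloc[0]["subfamily"] == "EXC"
    bal = res.set_index("subfamily").loc["BAL"]
    assert bal["adjusted_p"] == pytest.approx(1.0)


def test_subfamily_below_min_hits_excluded():
    sites = _sites([("chr1", i * 1000, i * 1000 + 100) for i in range(10)])
    tes = [_te(start=i * 1000, end=i * 1000 + 100, subfamily="RARE", te_id=i)
           for i in range(4)]
    hits = overlap_tes(sites, tes)
    res = subfamily_enrichment(hits, set(range(5)), set(range(5, 10)))
    assert len(res) == 0


# ------------------------------------------------ age_distribution_compare

def test_age_compare_exact_small_sample():
    assert age_distribution_compare([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
    assert age_distribution_compare([1e7, 2e7], [1e7, 2e7]) == pytest.approx(1.0)


def test_age_compare_planted_young_vs_old(rng):
    young = rng.uniform(5e6, 1.5e7, size=60)
    mixed = np.concatenate([young, rng.uniform(6e7, 9e7, size=10)])
    old = rng.uniform(5e7, 9e7, size=40)
    assert age_distribution_compare(mixed, old) < 1e-6


# ------------------------------------- subfamily accessibility + polymorphism

def _matrix(n_sites, values):
    sites = _sites([("chr1", i * 1000, i * 1000 + 100) for i in range(n_sites)])
    libs = pd.DataFrame({"library": [f"{s}_r{r}" for s in "ABC" for r in (1, 2)],
                         "strain": [s for s in "ABC" for _ in (1, 2)],
                         "replicate": [1, 2] * 3})
    return SiteMatrix(sites=sites, counts=values, libraries=libs,
                      normalized=values.astype(float))


def test_subfamily_matrix_zscores_zero_for_identical_strains(rng):
    vals = np.tile(rng.poisson(50, size=(6, 1)), (1, 6)).astype(float)
    m = _matrix(6, vals)
    tes = [_te(start=i * 1000, end=i * 1000 + 100, te_id=i) for i in range(6)]
    hits = overlap_tes(m.sites, tes)
    z = subfamily_accessibility_matrix(m, hits)
    np.testing.assert_allclose(z.to_numpy(), 0.0)


def test_subfamily_matrix_elevated_strain_has_max_z(rng):
    vals = rng.poisson(50, size=(6, 6)).astype(float)
    vals[:, 0:2] *= 2                      # strain A elevated everywhere
    m = _matrix(6, vals)
    tes = [_te(start=i * 1000, end=i * 1000 + 100,
               subfamily="S1" if i < 3 else "S2", te_id=i) for i in range(6)]
    hits = overlap_tes(m.sites, tes)
    z = subfamily_accessibility_matrix(m, hits)
    assert (z.idxmax(axis=1) == "A").all()


def test_polymorphic_fraction_limits():
    sites = _sites([("chr1", 0, 100), ("chr1", 1000, 1100)])
    tes_none = [_te(start=0, end=100, te_id=0),
                _te(start=1000, end=1100, te_id=1)]
    hits = overlap_tes(sites, tes_none)
    assert polymorphic_fraction(hits, {0, 1})["fraction"] == 0.0
    tes_all = [_te(start=0, end=100, te_id=0, polymorphic=True,
                   carrier_strains=("A",)),
               _te(start=1000, end=1100, te_id=1, polymorphic=True,
                   carrier_strains=("B",))]
    hits = overlap_tes(sites, tes_all)
    assert polymorphic_fraction(hits, {0, 1})["fraction"] == 1.0


def test_polymorphic_fraction_matches_planted_rate(rng):
    n = 300
    sites = _sites([("chr1", i * 1000, i * 1000 + 100) for i in range(n)])
    poly = set(rng.choice(n, size=30, replace=False).tolist())
    tes = [_te(start=i * 1000, end=i * 1000 + 100, te_id=i,
               polymorphic=i in poly,
               carrier_strains=("A",) if i in poly else None)
           for i in range(n)]
    hits = overlap_tes(sites, tes)
    frac = polymorphic_fraction(hits, set(range(n)))["fraction"]
    assert abs(frac - 0.10) < 3 * np.sqrt(0.1 * 0.9 / n)


# --------------------------------------------------------- boundary profile

def test_boundary_profile_zero_and_uniform_coverage():
    tes = [_te(start=5000, end=9000, te_id=0)]
    zero = {"chr1": np.zeros(20_000)}
    prof = boundary_profile(zero, tes, flank=2500)
    np.testing.assert_allclose(prof.five_prime, 0.0)
    np.testing.assert_allclose(prof.three_prime, 0.0)
    unif = {"chr1": np.full(20_000, 3.0)}
    prof_u = boundary_profile(unif, tes, flank=2500)
    np.testing.assert_allclose(prof_u.five_prime, 3.0)
    for curve in prof_u.aggregate.values():
        np.testing.assert_allclose(curve, 3.0)


def test_boundary_profile_rows_sorted_by_age_and_short_tes_dropped():
    tes = [_te(start=2600, end=6000, divergence=0.3, te_id=0),
           _te(start=10_000, end=14_000, divergence=0.05, te_id=1),
           _te(start=16_000, end=16_060, divergence=0.1, te_id=2)]  # < 2 bins
    cov = {"chr1": np.ones(20_000)}
    prof = boundary_profile(cov, tes, flank=2500)
    assert len(prof.te_order) == 2
    assert prof.te_order.iloc[0]["te_id"] == 1    # youngest first


def test_boundary_profile_young_body_elevation_recovered(rng):
    # coverage elevated 5x inside young TEs only
    cov = np.ones(100_000)
    tes = []
    for i in range(8):
        start = 6000 + i * 11_000
        young = i < 4
        tes.append(_te(start=start, end=start + 4000,
                       divergence=0.02 if young else 0.4, te_id=i))
        if young:
            cov[start:start + 4000] = 5.0
    cov = cov * rng.uniform(0.97, 1.03, size=cov.size)
    prof = boundary_profile({"chr1": cov}, tes, flank=2500)
    order = prof.te_order
    young_rows = order["divergence"] < 0.1
    strat = prof.aggregate["3000-6000"]
    # body bins sit between the two flank blocks (50 flank bins each side)
    body = slice(50, len(strat) - 50)
    young_mean = np.mean([_body_mean(prof, cov, r) for r in
                          order[young_rows].itertuples(index=False)])
    old_mean = np.mean([_body_mean(prof, cov, r) for r in
                        order[~young_rows].itertuples(index=False)])
    assert abs(young_mean / old_mean - 5.0) < 0.5


def _body_mean(prof, cov, row):
    return cov[row.start:row.end].mean()
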
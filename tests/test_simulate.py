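"""Synthetic-data generators: planted structure and distributional checks."""
import numpy as np
import pandas as pd
import pytest

from tevar.drivers import call_dm_cpgs
from tevar.simulate import (CountParams, TESubfamilySpec, TruthPlan,
                            simulate_counts, simulate_fragments, simulate_genome,
                            simulate_methylation, simulate_strains)
from tevar.types import CpGTable, GenomeSequence


def _spec(name="fam", te_class="LINE", length=6000, copies=1, age=0.0):
    return TESubfamilySpec(name, te_class, "L1", length, copies, age)


# ---------------------------------------------------------------- genome

def test_zero_age_te_is_identical_to_consensus():
    g, tes, _ = simulate_genome(1, 50_000, [_spec(age=0.0)], seed=1)
    (t,) = tes
    assert t.divergence == 0.0 and t.age == 0.0


def test_realized_divergence_within_binomial_bound():
    rate = 4.5e-9
    age = 1e7
    p = age * rate                      # 0.045
    g, tes, _ = simulate_genome(1, 50_000, [_spec(age=age)], seed=2)
    (t,) = tes
    sd = np.sqrt(p * (1 - p) / 6000)
    assert abs(t.divergence - p) < 3 * sd
    assert t.age == pytest.approx(t.divergence / rate)


def test_te_copies_are_placed_without_overlap():
    specs = [_spec("a", length=1000, copies=10, age=1e7),
             _spec("b", "SINE", length=300, copies=10, age=2e7)]
    g, tes, truth = simulate_genome(2, 100_000, specs, seed=3)
    assert len(tes) == 20
    by_chrom = {}
    for t in tes:
        by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    for ivs in by_chrom.values():
        ivs.sort()
        assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))
    assert set(truth.te_target_age.values()) == {1e7, 2e7}


def test_genome_capacity_and_divergence_errors():
    with pytest.raises(ValueError, match="capacity"):
        simulate_genome(1, 10_000, [_spec(length=5000, copies=10, age=0)], seed=1)
    with pytest.raises(ValueError, match="0.75"):
        simulate_genome(1, 100_000, [_spec(age=2e8)], seed=1)


# ---------------------------------------------------------------- strains

def test_zero_snp_rate_gives_empty_table(small_genome):
    snps, carriers = simulate_strains(small_genome, 3, 0.0, 0.0, seed=1)
    assert len(snps) == 0 and len(carriers) == 0


def test_snp_count_within_poisson_bound(rng):
    genome = GenomeSequence(chr1="".join(rng.choice(list("ACGT"), size=1_000_000)))
    snps, _ = simulate_strains(genome, 4, 2e-3, 0.0, seed=4)
    assert abs(len(snps) - 2000) < 3 * np.sqrt(2000)
    # alleles: every SNP carried by a nonempty proper subset
    mat = snps.frame[snps.strains].to_numpy()
    assert mat.sum(axis=1).min() >= 1 and mat.sum(axis=1).max() <= 3
    snps.validate_against(genome)


def test_zero_polymorphic_fraction_gives_empty_carrier_table(small_genome):
    g, tes, _ = simulate_genome(1, 50_000, [_spec(length=500, copies=5, age=1e7)],
                                seed=5)
    snps, carriers = simulate_strains(g, 3, 1e-3, 0.0, seed=5, tes=tes)
    assert len(carriers) == 0 and not any(t.polymorphic for t in tes)


def test_invalid_strain_and_rate_arguments(small_genome):
    with pytest.raises(ValueError):
        simulate_strains(small_genome, 0, 1e-3, 0.0, seed=1)
    with pytest.raises(ValueError):
        simulate_strains(small_genome, 3, 0.5, 0.0, seed=1)


# -------------------------------------------------------------- fragments

def test_zero_fragments_gives_empty_set(small_genome):
    plan = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [500],
                         "enrichment": [10.0]})
    frags = simulate_fragments(small_genome, plan, 0, seed=1)
    assert len(frags) == 0


def test_fragment_peak_mixture_weight(rng):
    genome = GenomeSequence(chr1="".join(rng.choice(list("ACGT"), size=1_000_000)))
    plan = pd.DataFrame({"chrom": ["chr1"], "start": [499_800], "end": [500_200],
                         "enrichment": [10.0]})
    n = 20_000
    frags = simulate_fragments(genome, plan, n, seed=6)
    mid = (frags["start"] + frags["end"]) // 2
    inside = ((mid >= 499_800) & (mid < 500_200)).sum()
    # peak weight: (enr-1)*width / (L + (enr-1)*width), plus background mass
    w_peak = 9 * 400 / (1e6 + 9 * 400)
    expect = n * (w_peak + (1 - w_peak) * 400 / 1e6)
    assert abs(inside - expect) < 3 * np.sqrt(expect)


def test_fragment_length_distribution(small_genome):
    plan = pd.DataFrame(columns=["chrom", "start", "end", "enrichment"])
    frags = simulate_fragments(small_genome, plan, 10_000, seed=7)
    lengths = frags["end"] - frags["start"]
    # boundary clipping can shorten a handful of fragments
    core = lengths[(frags["start"] > 0) & (frags["end"] < 3000)]
    assert abs(core.mean() - 170) < 0.1
    assert core.min() >= 20


def test_fragment_plan_validation(small_genome):
    bad_enrich = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100],
                               "enrichment": [0.5]})
    with pytest.raises(ValueError, match="enrichment"):
        simulate_fragments(small_genome, bad_enrich, 10, seed=1)
    outside = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [99_999],
                            "enrichment": [2.0]})
    with pytest.raises(ValueError, match="outside"):
        simulate_fragments(small_genome, outside, 10, seed=1)


# ----------------------------------------------------------------- counts

def _sites(n):
    return pd.DataFrame({"site_id": np.arange(n), "chrom": "chr1",
                         "start": np.arange(n) * 1000,
                         "end": np.arange(n) * 1000 + 400})


def test_alpha_zero_directs_to_poisson_limit():
    with pytest.raises(ValueError, match="1e-8"):
        CountParams(alpha=0.0)


def test_no_planted_effects_yields_empty_truth_sets():
    counts, libs, truth = simulate_counts(_sites(50), ["a", "b"], 2,
                                          CountParams(), TruthPlan(), seed=8)
    assert truth.variable_site_ids == set() and truth.common_site_ids == set()
    assert counts.shape == (50, 4)


def test_planted_fold_recovered_in_affected_strain_means():
    # 4-fold planted in a fixed strain subset: law of large numbers over
    # 50 sites puts the affected-strain mean within 5% of 400
    n = 1000
    strains = [f"s{i}" for i in range(7)]
    plan = TruthPlan(variable=set(range(50)))
    params = CountParams(mu=100.0, alpha=0.05, variable_fold_range=(4.0, 4.0),
                         variable_subset_sizes=(3,))
    counts, libs, truth = simulate_counts(_sites(n), strains, 2, params, plan,
                                          seed=9)
    affected_means = []
    for i in range(50):
        row = counts[i].reshape(7, 2).mean(axis=1)
        affected_means.extend(sorted(row)[-3:])    # the 3 boosted strains
    assert abs(np.mean(affected_means) - 400) < 0.05 * 400
    assert truth.variable_site_ids == set(range(50))


def test_snp_and_methylation_driven_means():
    strains = [f"s{i}" for i in range(7)]
    g = np.array([1, 1, 0, 0, 0, 0, 0])
    meth = np.array([0.9, 0.9, 0.05, 0.05, 0.05, 0.05, 0.05])
    plan = TruthPlan(variable={0, 1}, snp_driven={0: g},
                     meth_driven={1: (42, meth)})
    params = CountParams(mu=100.0, alpha=0.001, snp_fold=8.0)
    counts, libs, truth = simulate_counts(_sites(2), strains, 50, params, plan,
                                          seed=10)
    m0 = counts[0].reshape(7, 50).mean(axis=1)
    assert m0[0] / m0[2] == pytest.approx(8.0, rel=0.15)
    m1 = counts[1].reshape(7, 50).mean(axis=1)
    expected = 100 * (params.meth_base + params.meth_span * (1 - meth))
    np.testing.assert_allclose(m1, expected, rtol=0.2)
    assert truth.snp_driven == {0: 8.0} and truth.methylation_driven == {1: 42}


# -------------------------------------------------------------- methylation

def _cpg_positions(n):
    return pd.DataFrame({"cpg_id": np.arange(n), "chrom": "chr1",
                         "pos": np.arange(n) * 50 + 10})


def test_methylation_dm_caller_recovers_exactly_planted_set():
    strains = [f"s{i}" for i in range(25)]
    pos = _cpg_positions(200)
    rng = np.random.default_rng(11)
    dm_ids = set(rng.choice(200, size=20, replace=False).tolist())
    plan = {int(i): (i in dm_ids) for i in range(200)}
    table = simulate_methylation(pos, strains, plan, seed=11)
    called = call_dm_cpgs(CpGTable(frame=table, strains=strains))
    assert set(called.loc[called["dm"], "cpg_id"]) == dm_ids


def test_methylation_unknown_cpg_in_plan_raises():
    with pytest.raises(ValueError, match="unknown"):
        simulate_methylation(_cpg_positions(5), ["a", "b", "c"], {99: True}, seed=1)


def test_all_non_dm_plan_yields_no_dm_calls():
    strains = [f"s{i}" for i in range(7)]
    table = simulate_methylation(_cpg_positions(50), strains, {}, seed=12)
    called = call_dm_cpgs(CpGTable(frame=table, strains=strains))
    assert not called["dm"].any()


def test_generators_are_deterministic_given_seed():
    a = simulate_genome(1, 30_000, [_spec(length=500, copies=3, age=1e7)], seed=42)
    b = simulate_genome(1, 30_000, [_spec(length=500, copies=3, age=1e7)], seed=42)
    assert a[0] == b[0]
    assert [(t.start, t.divergence) for t in a[1]] == \
        [(t.start, t.divergence) for t in b[1]]
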
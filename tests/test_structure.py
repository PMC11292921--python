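"""Relatedness, F-statistics, distances, AMOVA and LD behaviour."""

import math

import numpy as np
import pytest

from pawprint import structure as st
from pawprint.geno_core import AlleleFreqTable, allele_frequencies
from pawprint.synthetic_data import (PedigreeSim, SimConfig, simulate_pedigree,
                                     simulate_populations)
from conftest import make_table


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

def test_unrelated_pairs_mean_r_near_zero():
    t, _ = simulate_populations(SimConfig(
        n_pops=1, n_per_pop=[200], n_loci=20, fst=0.0, seed=17))
    rng = np.random.default_rng(1)
    pairs = [tuple(sorted(rng.choice(200, 2, replace=False)))
             for _ in range(4000)]
    res = st.pairwise_relatedness(t, pairs=pairs)
    rs = np.array([x.r for x in res if math.isfinite(x.r)])
    assert abs(rs.mean()) < 0.02


def test_parent_offspring_mean_r_near_half():
    t, _ = simulate_populations(SimConfig(
        n_pops=1, n_per_pop=[200], n_loci=20, fst=0.0, seed=19))
    f = allele_frequencies(t, "pooled")
    ped, truth = simulate_pedigree(PedigreeSim(founder_freqs=f, n_trios=300,
                                               seed=23))
    ids = {s.id: i for i, s in enumerate(ped.samples)}
    pairs = [(ids[sire], ids[off]) for sire, dam, off in truth.trios]
    res = st.pairwise_relatedness(ped, ref_freqs=f, pairs=pairs)
    rs = np.array([x.r for x in res if math.isfinite(x.r)])
    assert abs(rs.mean() - 0.5) < 0.03


def test_pair_counts_are_combinatorial():
    t, _ = simulate_populations(SimConfig(
        n_pops=2, n_per_pop=[6, 4], n_loci=3, seed=2))
    res = st.pairwise_relatedness(t)
    assert len(res) == 10 * 9 // 2
    # the study-scale grouping arithmetic: all-pairs over 184 samples,
    # and the within-breed pair total for the five breed sizes
    assert 184 * 183 // 2 == 16836
    n_within = sum(n * (n - 1) // 2 for n in (59, 29, 41, 37, 18))
    assert n_within == 3756


# ---------------------------------------------------------------------------
# FIS
# ---------------------------------------------------------------------------

def test_all_homozygote_table_gives_fis_near_one():
    genos = [[(100, 100)], [(102, 102)]] * 10
    t = make_table(genos, ["A"] * 20)
    assert st.weir_cockerham_fis(t, "pooled") == pytest.approx(1.0)


def test_hw_proportions_give_fis_near_zero():
    # 25 AA, 50 AB, 25 BB: exact HW proportions at p = 0.5
    genos = ([[(100, 100)]] * 25 + [[(100, 102)]] * 50 + [[(102, 102)]] * 25)
    t = make_table(genos, ["A"] * 100)
    assert abs(st.weir_cockerham_fis(t, "pooled")) < 0.02


def test_fis_bootstrap_deterministic():
    t, _ = simulate_populations(SimConfig(
        n_pops=2, n_per_pop=[40, 40], n_loci=8, seed=29))
    a = st.fis_with_ci(t, "breed", n_boot=100, seed=5)
    b = st.fis_with_ci(t, "breed", n_boot=100, seed=5)
    assert a["ci_low"] == b["ci_low"] and a["ci_high"] == b["ci_high"]
    assert a["ci_low"] <= a["fis"] <= a["ci_high"]


# ---------------------------------------------------------------------------
# FST / RST / Nei D
# ---------------------------------------------------------------------------

def test_fixed_differences_give_theta_near_one():
    genos_a = [[(100, 100)]] * 10
    genos_b = [[(120, 120)]] * 10
    t = make_table(genos_a + genos_b, ["A"] * 10 + ["B"] * 10)
    assert st.weir_cockerham_theta(t, "breed") == pytest.approx(1.0, abs=1e-9)


def test_duplicated_population_theta_near_zero():
    t, _ = simulate_populations(SimConfig(
        n_pops=1, n_per_pop=[60], n_loci=10, seed=31))
    relabel = ["A"] * 30 + ["B"] * 30
    t2 = make_table([[tuple(t.calls[i, j]) for j in range(t.n_loci)]
                     for i in range(60)], relabel, loci=t.loci)
    res = st.pairwise_fst(t2, "breed", n_perm=99, seed=3)
    assert abs(res.values[0, 1]) < 0.02
    assert res.p_values[0, 1] > 0.05


def test_pairwise_fst_permutation_reproducible():
    t, _ = simulate_populations(SimConfig(
        n_pops=2, n_per_pop=[20, 20], n_loci=5, seed=37))
    a = st.pairwise_fst(t, "breed", n_perm=50, seed=7)
    b = st.pairwise_fst(t, "breed", n_perm=50, seed=7)
    assert np.array_equal(a.p_values, b.p_values, equal_nan=True)


def test_theta_monotone_in_simulated_fst():
    means = []
    for fst in (0.01, 0.05, 0.2):
        vals = []
        for seed in range(10):
            t, _ = simulate_populations(SimConfig(
                n_pops=2, n_per_pop=[80, 80], n_loci=10, fst=fst,
                seed=1000 + seed))
            vals.append(st.weir_cockerham_theta(t, "breed"))
        means.append(np.mean(vals))
        assert all(v > -0.05 for v in vals)
    assert means[0] < means[1] < means[2]


def test_rst_distance_sensitivity_and_invariance():
    near = make_table([[(100, 100)]] * 6 + [[(102, 102)]] * 6,
                      ["A"] * 6 + ["B"] * 6)
    far = make_table([[(100, 100)]] * 6 + [[(120, 120)]] * 6,
                     ["A"] * 6 + ["B"] * 6)
    r_near = st.pairwise_rst(near, "breed").values[0, 1]
    r_far = st.pairwise_rst(far, "breed").values[0, 1]
    assert r_far >= r_near  # both fully sorted: equal variance ratio or larger
    # identical groups -> RST ~ 0
    same = make_table([[(100, 102)], [(100, 100)], [(100, 102)], [(100, 100)]],
                      ["A", "A", "B", "B"])
    assert st.pairwise_rst(same, "breed").values[0, 1] == pytest.approx(0.0, abs=1e-9)


def test_rst_invariant_to_repeat_unit_scaling():
    from pawprint.geno_core import LocusMeta
    g1 = [[(100, 104)], [(104, 104)], [(100, 100)], [(108, 108)]]
    t1 = make_table(g1, ["A", "A", "B", "B"], loci=[LocusMeta("L1", 4)])
    g2 = [[(50, 52)], [(52, 52)], [(50, 50)], [(54, 54)]]
    t2 = make_table(g2, ["A", "A", "B", "B"], loci=[LocusMeta("L1", 2)])
    assert (st.pairwise_rst(t1, "breed").values[0, 1]
            == pytest.approx(st.pairwise_rst(t2, "breed").values[0, 1]))


def test_nei_distance_values():
    f = AlleleFreqTable(
        ["L1"], ["A", "B", "C"],
        {("L1", "A"): {1: 1.0}, ("L1", "B"): {1: 0.5, 2: 0.5},
         ("L1", "C"): {3: 1.0}},
        {("L1", "A"): 10, ("L1", "B"): 10, ("L1", "C"): 10})
    assert st.nei_distance(f, "A", "A") == pytest.approx(0.0)
    # I = 0.5 / sqrt(1 * 0.5) = 0.7071 -> D = 0.3466
    assert st.nei_distance(f, "A", "B") == pytest.approx(0.346574, abs=1e-5)
    assert st.nei_distance(f, "A", "C") == math.inf


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def test_amova_identical_population_copies_have_zero_among():
    t, _ = simulate_populations(SimConfig(
        n_pops=1, n_per_pop=[30], n_loci=6, seed=41))
    genos = [[tuple(t.calls[i, j]) for j in range(t.n_loci)]
             for i in range(30)] * 2
    t2 = make_table(genos, ["A"] * 30 + ["B"] * 30, loci=t.loci)
    res = st.amova(t2, "breed")
    assert res.pct_among_pops == pytest.approx(0.0, abs=1e-9)
    assert (res.pct_among_pops + res.pct_among_ind + res.pct_within_ind
            == pytest.approx(100.0))


def test_amova_among_pct_tracks_differentiation():
    def pct(fst, seed):
        t, _ = simulate_populations(SimConfig(
            n_pops=3, n_per_pop=[40, 40, 40], n_loci=10, fst=fst, seed=seed))
        return st.amova(t, "breed").pct_among_pops

    low = np.mean([pct(0.02, 200 + s) for s in range(5)])
    high = np.mean([pct(0.2, 200 + s) for s in range(5)])
    assert high > low


def test_amova_total_equals_component_sum():
    t, _ = simulate_populations(SimConfig(
        n_pops=3, n_per_pop=[25, 25, 25], n_loci=8, f_is=0.3, seed=43))
    res = st.amova(t, "breed")
    assert res.total_variance == pytest.approx(
        res.sigma_among_pops + res.sigma_among_ind + res.sigma_within_ind,
        abs=1e-9)
    with pytest.raises(ValueError):
        st.amova(t, "pooled")   # single group: degenerate design


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def test_duplicated_locus_has_tiny_ld_p():
    t, _ = simulate_populations(SimConfig(
        n_pops=1, n_per_pop=[60], n_loci=1, alleles_per_locus=6, seed=47))
    genos = [[tuple(t.calls[i, 0]), tuple(t.calls[i, 0])] for i in range(60)]
    t2 = make_table(genos, ["A"] * 60)
    p = st.genotypic_ld_test(t2, "L1", "L2", n_perm=1000, seed=3)
    assert p <= 0.01


def test_ld_p_reproducible_and_needs_shared_samples():
    t, _ = simulate_populations(SimConfig(
        n_pops=1, n_per_pop=[40], n_loci=2, seed=53))
    p1 = st.genotypic_ld_test(t, "L01", "L02", n_perm=200, seed=9)
    p2 = st.genotypic_ld_test(t, "L01", "L02", n_perm=200, seed=9)
    assert p1 == p2
    tiny = make_table([[(1, 1), (2, 2)]] * 4, ["A"] * 4)
    with pytest.raises(ValueError):
        st.genotypic_ld_test(tiny, "L1", "L2")


def test_ld_null_rejection_rate_calibrated():
    """Independently simulated locus pairs reject at ~5%."""
    t, _ = simulate_populations(SimConfig(
        n_pops=1, n_per_pop=[50], n_loci=29, alleles_per_locus=4, seed=59))
    from itertools import combinations
    names = t.locus_names
    pairs = list(combinations(names, 2))[:400]
    rej = 0
    for i, (a, b) in enumerate(pairs):
        p = st.genotypic_ld_test(t, a, b, n_perm=199, seed=i)
        rej += p < 0.05
    rate = rej / len(pairs)
    assert abs(rate - 0.05) <= 0.02
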
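"""D-loop diversity, differentiation, neutrality and mismatch statistics."""

import math
from itertools import combinations

import numpy as np
import pytest

from pawprint import dloop as dl
from pawprint.geno_core import DloopAlignment
from pawprint.synthetic_data import simulate_dloop_alignment


def aln(seqs, pops=None):
    pops = pops or ["X"] * len(seqs)
    return DloopAlignment([(f"s{i + 1}", p, s)
                           for i, (p, s) in enumerate(zip(pops, seqs))])


@pytest.fixture
def four_seq_fixture():
    """n=4, L=20: S=3 segregating sites, 2 singletons, k=10/6."""
    ref = "A" * 20
    return aln([ref,
                ref[:1] + "G" + ref[2:],
                ref[:2] + "CC" + ref[4:],
                ref[:2] + "C" + ref[3:]])


# ---------------------------------------------------------------------------
# haplotype collapsing
# ---------------------------------------------------------------------------

def test_identical_sequences_collapse_to_one():
    ht = dl.collapse_haplotypes(aln(["ACGT" * 5] * 4))
    assert len(ht.haplotypes) == 1 and ht.s_sites == 0


def test_two_haplotypes_direct_count():
    a = simulate_dloop_alignment(2, {"X": [0.5, 0.5]}, length=100,
                                 sites_per_haplotype=3, seed=1,
                                 n_per_pop={"X": 4})
    ht = dl.collapse_haplotypes(a)
    assert len(ht.haplotypes) == 2 and ht.s_sites == 3


def test_gap_column_removed_before_comparison():
    ht = dl.collapse_haplotypes(aln(["ACGTA", "AC-TA"]))
    assert len(ht.haplotypes) == 1            # differ only at the gap column
    assert ht.length == 4
    with pytest.raises(Exception):
        dl.collapse_haplotypes(aln(["-----", "ACGTA"]))


def test_pairwise_mode_keeps_all_sites():
    ht = dl.collapse_haplotypes(aln(["ACGTA", "AC-TA"]), "pairwise")
    assert ht.length == 5


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def test_haplotype_diversity_two_plus_two():
    a = simulate_dloop_alignment(2, {"X": [0.5, 0.5]}, length=100,
                                 sites_per_haplotype=3, seed=1,
                                 n_per_pop={"X": 4})
    d = dl.diversity_stats(dl.collapse_haplotypes(a))[0]
    assert d.hap_diversity == pytest.approx(2.0 / 3.0, abs=1e-12)
    # enumerate all 6 pairs: 4 cross pairs x 3 diffs, 2 within pairs x 0
    assert d.k == pytest.approx((4 * 3 + 2 * 0) / 6.0, abs=1e-12)
    assert d.pi == pytest.approx(0.02, abs=1e-12)
    assert d.theta_s == pytest.approx(3.0 / ((1 + 0.5 + 1 / 3) * 100),
                                      abs=1e-5)


def test_k_equals_pi_times_length_and_invariances():
    rng = np.random.default_rng(5)
    seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(6)]
    ht = dl.collapse_haplotypes(aln(seqs))
    d = dl.diversity_stats(ht)[0]
    assert d.k == pytest.approx(d.pi * ht.length, abs=1e-9)
    # column permutation leaves pi unchanged
    perm = rng.permutation(30)
    seqs_p = ["".join(s[j] for j in perm) for s in seqs]
    d2 = dl.diversity_stats(dl.collapse_haplotypes(aln(seqs_p)))[0]
    assert d2.pi == pytest.approx(d.pi, abs=1e-12)
    assert d2.hap_diversity == pytest.approx(d.hap_diversity, abs=1e-12)


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def test_fixed_haplotypes_fully_sorted():
    seqs = ["AAAAAAAAAA"] * 3 + ["AAACCCAAAA"] * 3
    res = dl.differentiation(dl.collapse_haplotypes(
        aln(seqs, ["X"] * 3 + ["Y"] * 3)))[0]
    assert res.g_st == pytest.approx(1.0)
    assert res.phi_st == pytest.approx(1.0)
    # both pops monomorphic: Dxy = 3/10 and Da = Dxy
    assert res.d_xy == pytest.approx(0.3, abs=1e-12)
    assert res.d_a == pytest.approx(res.d_xy, abs=1e-12)


def test_monomorphic_pair_dxy_three_of_hundred():
    a = simulate_dloop_alignment(2, {"X": [1.0, 0.0], "Y": [0.0, 1.0]},
                                 length=100, sites_per_haplotype=3, seed=3,
                                 n_per_pop={"X": 4, "Y": 4})
    res = dl.differentiation(dl.collapse_haplotypes(a))[0]
    assert res.d_xy == pytest.approx(0.03, abs=1e-12)
    assert res.d_a == pytest.approx(0.03, abs=1e-12)


def test_identical_populations_have_zero_da():
    rng = np.random.default_rng(7)
    base = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(4)]
    ht = dl.collapse_haplotypes(aln(base + base, ["X"] * 4 + ["Y"] * 4))
    res = dl.differentiation(ht)[0]
    assert res.d_a == pytest.approx(0.0, abs=1e-12)
    assert res.d_a <= res.d_xy + 1e-12


def test_da_never_exceeds_dxy():
    rng = np.random.default_rng(9)
    for trial in range(5):
        seqs = ["".join(rng.choice(list("ACGT"), 25)) for _ in range(8)]
        ht = dl.collapse_haplotypes(aln(seqs, ["X"] * 4 + ["Y"] * 4))
        res = dl.differentiation(ht)[0]
        assert res.d_a <= res.d_xy + 1e-12


# ---------------------------------------------------------------------------
# neutrality
# ---------------------------------------------------------------------------

def test_no_segregation_gives_undefined_statistics():
    ht = dl.collapse_haplotypes(aln(["ACGT" * 5] * 5))
    nt = dl.neutrality_tests(ht)[0]
    assert math.isnan(nt.tajima_d)
    assert math.isnan(nt.fu_li_dstar)
    assert math.isnan(nt.fu_fs)


def test_four_sequence_fixture_frozen_values(four_seq_fixture):
    """Frozen oracle values hand-derived from the published formulas:
    n=4, S=3, eta_s=2, k=5/3."""
    nt = dl.neutrality_tests(dl.collapse_haplotypes(four_seq_fixture))[0]
    assert (nt.n, nt.s_sites, nt.eta_s) == (4, 3, 2)
    assert nt.tajima_d == pytest.approx(0.167656, abs=1e-5)
    assert nt.fu_li_dstar == pytest.approx(0.167656, abs=1e-5)
    assert nt.fu_li_fstar == pytest.approx(0.081777, abs=1e-5)
    assert nt.fu_fs == pytest.approx(-2.181095, abs=1e-5)


def test_tajimas_d_independent_reimplementation(four_seq_fixture):
    """Step-by-step re-derivation of D for the fixture (independent path)."""
    n, S, k = 4, 3, 10 / 6
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1, e2 = c1 / a1, c2 / (a1 ** 2 + a2)
    d_oracle = (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    assert dl.tajimas_d(n, S, k) == pytest.approx(d_oracle, abs=1e-12)


def test_fus_fs_recursion_matches_naive_ewens_enumeration():
    """P(K = k) from the Stirling recursion equals the sum of Ewens sampling
    formula probabilities over all partitions of n, for n <= 8."""
    def partitions(n, max_part=None):
        if n == 0:
            yield []
            return
        max_part = max_part or n
        for first in range(min(n, max_part), 0, -1):
            for rest in partitions(n - first, first):
                yield [first] + rest

    theta = 1.7
    for n in range(2, 9):
        rising = math.prod(theta + i for i in range(n))
        by_k = np.zeros(n + 1)
        for part in partitions(n):
            a = {}
            for sz in part:
                a[sz] = a.get(sz, 0) + 1
            prob = math.factorial(n) / rising * theta ** len(part)
            for sz, cnt in a.items():
                prob /= sz ** cnt * math.factorial(cnt)
            by_k[len(part)] += prob
        got = dl.ewens_k_distribution(n, theta)
        assert np.allclose(got, by_k, atol=1e-9)


def test_neutral_coalescent_alignment_yields_defined_statistics():
    from pawprint.synthetic_data import simulate_neutral_alignment
    a = simulate_neutral_alignment(25, length=423, theta=5.0, seed=3)
    nt = dl.neutrality_tests(dl.collapse_haplotypes(a))[0]
    assert nt.s_sites > 0
    assert math.isfinite(nt.tajima_d)
    assert math.isfinite(nt.fu_li_dstar) and math.isfinite(nt.fu_fs)


# ---------------------------------------------------------------------------
# mismatch distribution
# ---------------------------------------------------------------------------

def test_raggedness_two_class_convention():
    # observed frequencies (0.5, 0.5) over classes {0, 1}:
    # r = (0.5 - 0.5)^2 + (0 - 0.5)^2 = 0.25
    seqs = ["AAAA", "AAAA", "AAAT", "AAAT"]
    # pairs: within = 0 diffs (x2), cross = 1 diff (x4) -> obs (1/3, 2/3)
    res = dl.mismatch_distribution(dl.collapse_haplotypes(aln(seqs)))
    assert res.observed.sum() == pytest.approx(1.0)
    exp_r = (res.observed[1] - res.observed[0]) ** 2 + res.observed[1] ** 2
    assert res.raggedness == pytest.approx(exp_r, abs=1e-12)


def test_all_identical_raggedness_is_one():
    res = dl.mismatch_distribution(dl.collapse_haplotypes(aln(["ACGT"] * 5)))
    assert res.observed.tolist() == [1.0]
    assert res.raggedness == pytest.approx(1.0)


def test_mismatch_expected_is_geometric_and_needs_n3():
    seqs = ["AAAA", "AAAT", "AATT"]
    res = dl.mismatch_distribution(dl.collapse_haplotypes(aln(seqs)))
    theta = res.theta
    i = np.arange(len(res.expected))
    assert np.allclose(res.expected, theta ** i / (1 + theta) ** (i + 1))
    with pytest.raises(ValueError):
        dl.mismatch_distribution(dl.collapse_haplotypes(aln(["AAAA", "AAAT"])))
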
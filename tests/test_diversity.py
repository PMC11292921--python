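"""Closed-form diversity statistics against hand-derived oracle values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from pawprint import diversity as dv
from pawprint.geno_core import LocusMeta
from conftest import make_table


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def test_symmetric_biallelic_closed_forms():
    p = np.array([0.5, 0.5])
    assert 1.0 / dv.power_sum(p, 2) == pytest.approx(2.0)
    assert dv.shannon_index(p) == pytest.approx(math.log(2), abs=1e-12)
    assert 1.0 - dv.power_sum(p, 2) == pytest.approx(0.5)
    assert dv.pic(p) == pytest.approx(0.375, abs=1e-12)


def test_three_allele_closed_forms():
    p = np.array([0.7, 0.2, 0.1])
    he = 1.0 - dv.power_sum(p, 2)
    assert he == pytest.approx(0.46, abs=1e-12)
    assert 1.0 / dv.power_sum(p, 2) == pytest.approx(1.0 / 0.54, abs=1e-4)
    uhe = (2 * 10 / (2 * 10 - 1)) * he        # n = 10 diploids
    assert uhe == pytest.approx(0.484211, abs=1e-4)


@settings(max_examples=200, deadline=None)
@given(hst.lists(hst.floats(0.01, 1.0), min_size=2, max_size=10))
def test_diversity_inequalities(weights):
    p = np.array(weights) / sum(weights)
    he = 1.0 - dv.power_sum(p, 2)
    assert he + 1e-12 >= dv.pic(p) >= -1e-12
    assert 1.0 <= 1.0 / dv.power_sum(p, 2) <= len(p) + 1e-9
    assert dv.shannon_index(p) <= math.log(len(p)) + 1e-9


# ---------------------------------------------------------------------------
# allelic richness
# ---------------------------------------------------------------------------

def test_rarefied_richness_hand_value():
    # counts (3,1), 2n=4, g=2: [1 - C(1,2)/C(4,2)] + [1 - C(3,2)/C(4,2)] = 1.5
    assert dv._rarefied_richness(np.array([3, 1]), 2) == pytest.approx(1.5)


def test_rarefaction_identities():
    counts = np.array([5, 3, 2])
    assert dv._rarefied_richness(counts, 10) == pytest.approx(3.0)  # g = 2n
    assert dv._rarefied_richness(np.array([8]), 4) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        dv._rarefied_richness(counts, 11)


def test_allelic_richness_table_errors_name_locus():
    t = make_table([[(100, 102)], [(100, 100)], [(102, 102)]], ["A", "A", "B"])
    with pytest.raises(ValueError, match="L1.*B|B.*L1"):
        dv.allelic_richness(t, "breed", g=4)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def test_hwe_two_sample_exact_p():
    """{AA, BB} with allele counts (2, 2): configurations {AA,BB} (1/3)
    and {AB,AB} (2/3); observed is the least probable, p = 1/3."""
    t = make_table([[(100, 100)], [(102, 102)]], ["A", "A"])
    p = dv.hwe_exact_test(t, "breed", "L1", "A", method="enumeration")
    assert p == pytest.approx(1.0 / 3.0, abs=1e-12)


def test_hwe_all_heterozygote_p_via_enumeration():
    t = make_table([[(100, 102)], [(100, 102)]], ["A", "A"])
    p = dv.hwe_exact_test(t, "breed", "L1", "A", method="enumeration")
    # observed {AB,AB} has prob 2/3; both configs qualify -> p = 1
    assert p == pytest.approx(1.0, abs=1e-12)


def test_hwe_monomorphic_is_one():
    t = make_table([[(100, 100)], [(100, 100)]], ["A", "A"])
    assert dv.hwe_exact_test(t, "breed", "L1", "A") == 1.0


def test_hwe_monte_carlo_agrees_with_enumeration():
    genos = ([[(100, 100)]] * 6 + [[(100, 102)]] * 2 + [[(102, 102)]] * 4
             + [[(100, 104)]] * 1 + [[(102, 104)]] * 1 + [[(104, 104)]] * 2)
    t = make_table(genos, ["A"] * len(genos))
    p_enum = dv.hwe_exact_test(t, "breed", "L1", "A", method="enumeration")
    p_mc = dv.hwe_exact_test(t, "breed", "L1", "A", method="monte_carlo",
                             reps=100_000, seed=2)
    assert abs(p_mc - p_enum) < 0.01


def test_hwe_null_rejection_rate_is_nominal():
    """Under HWE simulation the exact test rejects at ~ the nominal level."""
    from pawprint.synthetic_data import SimConfig, simulate_populations
    pvals = []
    for seed in range(20):
        t, _ = simulate_populations(SimConfig(
            n_pops=1, n_per_pop=[100], n_loci=20, alleles_per_locus=5,
            fst=0.0, f_is=0.0, seed=100 + seed))
        for locus in t.locus_names:
            pvals.append(dv.hwe_exact_test(t, "breed", locus, "POP1",
                                           method="monte_carlo", reps=2000,
                                           seed=seed))
    rate = np.mean(np.array(pvals) < 0.05)
    assert abs(rate - 0.05) <= 0.02


# ---------------------------------------------------------------------------
# null alleles, M-ratio, Welch
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ho,he,expected", [
    (0.30, 0.46, 0.16 / 1.46),
    (0.50, 0.40, 0.0),          # Ho >= He truncates to 0
    (0.00, 0.50, 1.0 / 3.0),
])
def test_brookfield_null_estimator(ho, he, expected):
    assert dv.null_allele_estimate(ho, he) == pytest.approx(expected, abs=1e-4)


@pytest.mark.parametrize("sizes,unit,m,flag", [
    ([150, 154, 158], 4, 1.0, False),
    ([150, 158], 4, 2.0 / 3.0, True),
    ([150], 4, 1.0, False),
])
def test_m_ratio(sizes, unit, m, flag):
    got_m, got_flag = dv.m_ratio(np.array(sizes), unit)
    assert got_m == pytest.approx(m)
    assert got_flag is flag


def test_welch_identical_vectors():
    v = np.linspace(0.3, 0.8, 15)
    t, df, p = dv.welch_ho_he(v, v)
    assert t == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_welch_matches_textbook_formula():
    rng = np.random.default_rng(8)
    he = rng.uniform(0.4, 0.9, size=15)
    ho = he - 0.2
    t, df, p = dv.welch_ho_he(ho, he)
    # independent re-derivation of the Welch statistic
    n1 = n2 = 15
    v1, v2 = ho.var(ddof=1), he.var(ddof=1)
    t_oracle = (ho.mean() - he.mean()) / math.sqrt(v1 / n1 + v2 / n2)
    df_oracle = (v1 / n1 + v2 / n2) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    from scipy import stats
    p_oracle = 2 * stats.t.sf(abs(t_oracle), df_oracle)
    assert t < 0
    assert t == pytest.approx(t_oracle, abs=1e-10)
    assert df == pytest.approx(df_oracle, abs=1e-9)
    assert p == pytest.approx(p_oracle, abs=1e-10)


def test_welch_single_locus_errors():
    with pytest.raises(ValueError):
        dv.welch_ho_he(np.array([0.5]), np.array([0.6]))


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def test_locus_summary_fields_and_f_undefined_when_monomorphic():
    genos = [[(100, 102), (300, 300)], [(100, 100), (300, 300)],
             [(102, 102), (300, 300)], [(100, 102), (300, 300)]]
    t = make_table(genos, ["A"] * 4,
                   loci=[LocusMeta("L1", 2), LocusMeta("L2", 2)])
    s = {rec.locus: rec for rec in dv.locus_summary(t, "breed", seed=1)}
    l1 = s["L1"]
    assert l1.na == 2 and l1.n_typed == 4
    assert l1.ho == pytest.approx(0.5)
    assert l1.he == pytest.approx(0.5)
    assert l1.uhe == pytest.approx(0.5 * 8 / 7)
    assert 1.0 <= l1.nea <= l1.na
    assert math.isnan(s["L2"].f)            # He = 0 -> undefined, not 0
    assert s["L2"].m_ratio == 1.0


def test_holm_correction_monotone_and_bounded():
    p = np.array([0.01, 0.04, 0.03, 0.5])
    adj = dv.holm_correction(p)
    assert np.all(adj <= 1.0) and np.all(adj >= p)
    assert adj[np.argsort(p)][0] == pytest.approx(0.04)
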
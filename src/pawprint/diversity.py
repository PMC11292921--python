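"""Per-locus, per-population microsatellite diversity statistics.

Implements the standard single-locus summary battery: allele counts (Na),
effective allele number (Nea = 1/sum p^2), rarefied allelic richness (FSTAT
rarefaction), Shannon's information index I, observed/expected/unbiased
heterozygosity, polymorphic information content (PIC, Botstein), fixation
index F = 1 - Ho/He, an exact Hardy-Weinberg test (full enumeration or
conditional Monte Carlo), the Brookfield-1 null-allele frequency estimate,
the Garza-Williamson M-ratio bottleneck statistic, and a Welch t comparison
of Ho vs He across loci.

He is reported as ``1 - sum p^2`` with the unbiased ``2n/(2n-1)`` variant
alongside.  All statistics use pairwise deletion: missing genotypes are
dropped locus by locus.  F is undefined (NaN) when He = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geno_core import AlleleFreqTable, GenotypeTable, allele_frequencies

__all__ = [
    "LocusSummary",
    "allele_frequencies",
    "locus_summary",
    "locus_summary_frame",
    "allelic_richness",
    "hwe_exact_test",
    "null_allele_estimate",
    "m_ratio",
    "welch_ho_he",
    "power_sum",
    "shannon_index",
    "pic",
    "holm_correction",
]

M_RATIO_BOTTLENECK_THRESHOLD = 0.68


@dataclass
class LocusSummary:
    """Summary record for one locus in one population."""

    locus: str
    population: str
    n_typed: int
    na: int
    nea: float
    ar_g: float
    shannon_i: float
    ho: float
    he: float
    uhe: float
    pic: float
    f: float            # NaN when He == 0
    hwe_p: float
    null_freq: float
    m_ratio: float
    m_ratio_flag: bool


# ---------------------------------------------------------------------------
# frequency helpers
# ---------------------------------------------------------------------------

def power_sum(p: np.ndarray, k: int) -> float:
    """a_k = sum_i p_i^k."""
    p = np.asarray(p, dtype=float)
    return float((p ** k).sum())


def shannon_index(p: np.ndarray) -> float:
    """I = -sum p ln p (0 log 0 := 0)."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def pic(p: np.ndarray) -> float:
    """Botstein polymorphic information content.

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2
        = 1 - a2 - a2^2 + a4   (using power sums).
    """
    a2 = power_sum(p, 2)
    a4 = power_sum(p, 4)
    return 1.0 - a2 - a2 * a2 + a4


# ---------------------------------------------------------------------------
# allelic richness (FSTAT rarefaction)
# ---------------------------------------------------------------------------

def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    """AR_g = sum over alleles of 1 - C(2n - N_a, g)/C(2n, g)."""
    counts = np.asarray(counts, dtype=np.int64)
    two_n = int(counts.sum())
    if g > two_n:
        raise ValueError(f"rarefaction depth g={g} exceeds 2n={two_n}")
    if g < 1:
        raise ValueError("rarefaction depth must be >= 1")
    denom = math.comb(two_n, g)
    total = 0.0
    for c in counts:
        total += 1.0 - math.comb(two_n - int(c), g) / denom
    return total


def allelic_richness(t: GenotypeTable, grouping: str = "breed",
                     g: int | None = None) -> pd.DataFrame:
    """Rarefied allelic richness per locus x group.

    ``g`` is the rarefaction depth in gene copies; the default is, per locus,
    the minimum ``2 * n_typed`` over groups typed at that locus (FSTAT
    behaviour).  Raises if a requested ``g`` exceeds some group's gene-copy
    count, naming the locus and group.
    """
    f = allele_frequencies(t, grouping)
    rows = []
    for locus in f.loci:
        present = [grp for grp in f.groups if (locus, grp) in f.n_typed]
        if not present:
            continue
        g_loc = g if g is not None else min(2 * f.n_typed[(locus, grp)]
                                            for grp in present)
        for grp in present:
            two_n = 2 * f.n_typed[(locus, grp)]
            if g_loc > two_n:
                raise ValueError(
                    f"g={g_loc} exceeds 2n={two_n} at locus {locus}, group {grp}")
            d = f.get(locus, grp)
            counts = np.rint(np.array(list(d.values())) * two_n).astype(np.int64)
            rows.append({"locus": locus, "group": grp, "g": g_loc,
                         "ar": _rarefied_richness(counts, g_loc)})
    return pd.DataFrame(rows, columns=["locus", "group", "g", "ar"])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _genotype_counts(t: GenotypeTable, grouping: str, locus: str,
                     group: str) -> dict[tuple[int, int], int]:
    j = t.locus_index(locus)
    labels = np.array(t.group_labels(grouping))
    miss = t.missing_mask()[:, j]
    ok = (labels == group) & ~miss
    out: dict[tuple[int, int], int] = {}
    for a, b in t.calls[ok, j, :]:
        key = (int(a), int(b))
        out[key] = out.get(key, 0) + 1
    return out


def _log_config_prob(geno_counts: dict[tuple[int, int], int],
                     allele_counts: dict[int, int]) -> float:
    """log P(genotype config | allele counts) under HWE (Levene's conditional)."""
    n = sum(geno_counts.values())
    two_n = 2 * n
    het = sum(c for (a, b), c in geno_counts.items() if a != b)
    lp = math.lgamma(n + 1) + het * math.log(2.0)
    for c in geno_counts.values():
        lp -= math.lgamma(c + 1)
    for c in allele_counts.values():
        lp += math.lgamma(c + 1)
    lp -= math.lgamma(two_n + 1)
    return lp


def _enumerate_configs(alleles: list[int], allele_counts: dict[int, int]):
    """Yield all genotype-count dicts consistent with the allele counts."""
    pairs = [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]

    def rec(idx: int, remaining: dict[int, int], current: dict[tuple[int, int], int]):
        if idx == len(pairs):
            if all(v == 0 for v in remaining.values()):
                yield dict(current)
            return
        a, b = pairs[idx]
        if a == b:
            max_c = remaining[a] // 2
        else:
            max_c = min(remaining[a], remaining[b])
        # feasibility prune: remaining copies must be pairable by later pairs
        for c in range(max_c, -1, -1):
            remaining[a] -= c if a == b else c
            if a == b:
                remaining[a] -= c
            else:
                remaining[b] -= c
            if c:
                current[(a, b)] = c
            yield from rec(idx + 1, remaining, current)
            if c:
                del current[(a, b)]
            if a == b:
                remaining[a] += 2 * c
            else:
                remaining[a] += c
                remaining[b] += c

    yield from rec(0, dict(allele_counts), {})


def _config_space_bound(n: int, k: int) -> int:
    """Upper bound on the genotype-configuration count: compositions of the
    n individuals over the K(K+1)/2 genotype categories."""
    g = k * (k + 1) // 2
    return math.comb(n + g - 1, g - 1)


def _mc_hwe(copies: np.ndarray, lp_obs: float, const: float, reps: int,
            seed: int) -> float:
    """Vectorised conditional Monte Carlo: random pairing of gene copies.

    ``const`` is the part of log P that does not depend on the pairing
    (lgamma(n+1) + sum lgamma(allele counts + 1) - lgamma(2n + 1)); the
    pairing-dependent part is het*log 2 - sum lgamma(c_genotype + 1).
    """
    rng = np.random.default_rng(seed)
    n = len(copies) // 2
    hits = 0
    chunk = max(1, min(reps, 20_000))
    done = 0
    while done < reps:
        r = min(chunk, reps - done)
        keys = rng.random((r, len(copies)))
        perm = np.argsort(keys, axis=1)
        shuffled = copies[perm]
        a = shuffled[:, 0::2]
        b = shuffled[:, 1::2]
        het = (a != b).sum(axis=1)
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        code = np.sort(lo.astype(np.int64) * 100_000 + hi, axis=1)
        # per-row run rank of each element within its genotype class:
        # sum over elements of log(rank) equals sum over classes of lgamma(c+1)
        idx = np.arange(n)
        new = np.ones((r, n), dtype=bool)
        new[:, 1:] = code[:, 1:] != code[:, :-1]
        start = np.where(new, idx[None, :], -1)
        start = np.maximum.accumulate(start, axis=1)
        rank = idx[None, :] - start + 1
        lgam_sum = np.log(rank).sum(axis=1)
        lp = const + het * math.log(2.0) - lgam_sum
        hits += int((lp <= lp_obs + 1e-9).sum())
        done += r
    return (hits + 1) / (reps + 1)


def hwe_exact_test(t: GenotypeTable, grouping: str, locus: str, group: str,
                   method: str = "auto", reps: int = 100_000,
                   seed: int = 1) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    The test conditions on the observed allele counts and sums the Levene
    conditional probabilities of all genotype configurations no more probable
    than the observed one.  ``method`` is ``"enumeration"``,
    ``"monte_carlo"``, or ``"auto"`` (enumeration when the configuration
    space has at most 10^6 tables).  Monte Carlo draws configurations by
    randomly pairing the observed gene copies, which samples exactly the
    conditional distribution.  Monomorphic data give p = 1 by convention.
    """
    geno = _genotype_counts(t, grouping, locus, group)
    n = sum(geno.values())
    if n < 2:
        raise ValueError(f"need >= 2 typed genotypes at {locus}/{group}")
    allele_counts: dict[int, int] = {}
    for (a, b), c in geno.items():
        allele_counts[a] = allele_counts.get(a, 0) + c
        allele_counts[b] = allele_counts.get(b, 0) + c
    if len(allele_counts) < 2:
        return 1.0
    alleles = sorted(allele_counts)

    if method == "auto":
        method = ("enumeration"
                  if _config_space_bound(n, len(alleles)) <= 1_000_000
                  else "monte_carlo")

    lp_obs = _log_config_prob(geno, allele_counts)
    if method == "enumeration":
        p = 0.0
        seen = 0
        for cfg in _enumerate_configs(alleles, allele_counts):
            seen += 1
            if seen > 2_000_000:  # safety valve: fall back to Monte Carlo
                break
            lp = _log_config_prob(cfg, allele_counts)
            if lp <= lp_obs + 1e-9:
                p += math.exp(lp)
        else:
            return min(p, 1.0)
        method = "monte_carlo"
    if method == "monte_carlo":
        copies = np.repeat(np.array(alleles, dtype=np.int64),
                           [allele_counts[a] for a in alleles])
        const = (math.lgamma(n + 1) - math.lgamma(2 * n + 1)
                 + sum(math.lgamma(c + 1) for c in allele_counts.values()))
        return _mc_hwe(copies, lp_obs, const, reps, seed)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# null alleles, M-ratio, Welch
# ---------------------------------------------------------------------------

def null_allele_estimate(ho: float, he: float, estimator: str = "brookfield1") -> float:
    """Null-allele frequency from the heterozygote deficit.

    Brookfield-1: r = (He - Ho) / (1 + He); Chakraborty:
    r = (He - Ho) / (He + Ho).  Truncated at 0.
    """
    if estimator == "brookfield1":
        r = (he - ho) / (1.0 + he)
    elif estimator == "chakraborty":
        r = (he - ho) / (he + ho) if (he + ho) > 0 else 0.0
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return max(r, 0.0)


def m_ratio(allele_sizes: np.ndarray, repeat_unit_bp: int) -> tuple[float, bool]:
    """Garza-Williamson M = k / (r + 1) with r the size range in repeat units.

    Returns ``(M, bottleneck_flag)``; the flag is set when M < 0.68.
    Monomorphic loci give M = 1.
    """
    sizes = np.unique(np.asarray(allele_sizes, dtype=np.int64))
    k = len(sizes)
    if k == 0:
        raise ValueError("no alleles")
    span = int(sizes.max() - sizes.min())
    r = round(span / repeat_unit_bp)
    m = k / (r + 1.0)
    return m, bool(m < M_RATIO_BOTTLENECK_THRESHOLD)


def welch_ho_he(ho: np.ndarray, he: np.ndarray) -> tuple[float, float, float]:
    """Welch unequal-variance t-test of per-locus Ho vs He vectors.

    Treats the two vectors as independent samples (Welch-Satterthwaite df).
    Returns (t, df, two-sided p).  Requires >= 2 loci; raises when both
    vectors are constant.
    """
    ho = np.asarray(ho, dtype=float)
    he = np.asarray(he, dtype=float)
    if len(ho) < 2 or len(he) < 2:
        raise ValueError("need >= 2 loci for the Welch comparison")
    v1, v2 = ho.var(ddof=1), he.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if np.allclose(ho.mean(), he.mean()):
            return 0.0, float(len(ho) + len(he) - 2), 1.0
        raise ValueError("zero variance in both vectors; Welch t undefined")
    res = stats.ttest_ind(ho, he, equal_var=False)
    n1, n2 = len(ho), len(he)
    df = (v1 / n1 + v2 / n2) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def holm_correction(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


# ---------------------------------------------------------------------------
# per-locus summary table
# ---------------------------------------------------------------------------

def locus_summary(t: GenotypeTable, grouping: str = "breed",
                  rarefy_g: int | None = None, hwe_method: str = "auto",
                  hwe_reps: int = 100_000, seed: int = 1,
                  null_estimator: str = "brookfield1") -> list[LocusSummary]:
    """Full per-locus x per-group diversity summary.

    See the module docstring for the statistic definitions.  ``rarefy_g``
    overrides the per-locus default rarefaction depth.
    """
    f = allele_frequencies(t, grouping)
    ar = allelic_richness(t, grouping, rarefy_g)
    ar_map = {(r.locus, r.group): r.ar for r in ar.itertuples()}
    labels = np.array(t.group_labels(grouping))
    miss = t.missing_mask()
    unit = {m.name: m.repeat_unit_bp for m in t.loci}

    out: list[LocusSummary] = []
    for locus in f.loci:
        j = t.locus_index(locus)
        for grp in f.groups:
            if (locus, grp) not in f.n_typed:
                continue
            n = f.n_typed[(locus, grp)]
            d = f.get(locus, grp)
            p = np.array(list(d.values()))
            a2 = power_sum(p, 2)
            he = 1.0 - a2
            uhe = (2 * n / (2 * n - 1.0)) * he if n > 1 else float("nan")
            ok = (labels == grp) & ~miss[:, j]
            calls = t.calls[ok, j, :]
            ho = float((calls[:, 0] != calls[:, 1]).mean()) if len(calls) else float("nan")
            fix = 1.0 - ho / he if he > 0 else float("nan")
            hwe_p = hwe_exact_test(t, grouping, locus, grp, method=hwe_method,
                                   reps=hwe_reps, seed=seed) if n >= 2 else float("nan")
            m, flag = m_ratio(np.array(sorted(d)), unit[locus])
            out.append(LocusSummary(
                locus=locus, population=grp, n_typed=n,
                na=len(d), nea=1.0 / a2 if a2 > 0 else float("nan"),
                ar_g=float(ar_map.get((locus, grp), float("nan"))),
                shannon_i=shannon_index(p), ho=ho, he=he, uhe=uhe,
                pic=pic(p), f=fix, hwe_p=hwe_p,
                null_freq=null_allele_estimate(ho, he, null_estimator),
                m_ratio=m, m_ratio_flag=flag))
    return out


def locus_summary_frame(summaries: list[LocusSummary]) -> pd.DataFrame:
    """LocusSummary records as a DataFrame (stable column order)."""
    cols = ["locus", "population", "n_typed", "na", "nea", "ar_g", "shannon_i",
            "ho", "he", "uhe", "pic", "f", "hwe_p", "null_freq", "m_ratio",
            "m_ratio_flag"]
    df = pd.DataFrame([vars(s) for s in summaries])
    if df.empty:
        return pd.DataFrame(columns=cols)
    df["hwe_p_holm"] = holm_correction(df["hwe_p"].to_numpy())
    return df[cols + ["hwe_p_holm"]]
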
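"""Relatedness, inbreeding, differentiation, genetic distance, AMOVA and LD.

All estimators work directly on a :class:`~pawprint.geno_core.GenotypeTable`
with pairwise deletion of missing genotypes.

* Pairwise relatedness: Queller-Goodnight estimator, multilocus-weighted and
  symmetrically averaged, with reference allele frequencies from the pooled
  sample (or a supplied frequency table).
* FIS / FST: Weir-Cockerham variance-component estimators (per-allele a, b, c
  components summed over alleles and loci).  FIS confidence intervals by
  percentile bootstrap over loci; pairwise FST p-values by permuting
  individuals between the two groups.
* RST: Slatkin's allele-size analogue, computed from size variance components
  with sizes expressed in repeat units.
* Nei (1972) standard genetic distance D = -ln(I).
* Three-level codominant AMOVA (among populations / among individuals within
  populations / within individuals) with the allele-mismatch distance
  (0/1/2 non-shared alleles per locus).
* Genotypic linkage disequilibrium: G statistic on the two-locus genotype
  contingency table with a permutation p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .geno_core import AlleleFreqTable, GenotypeTable, allele_frequencies
from .diversity import holm_correction

__all__ = [
    "RelatednessResult",
    "AmovaResult",
    "pairwise_relatedness",
    "fis_with_ci",
    "individual_fis",
    "weir_cockerham_theta",
    "pairwise_fst",
    "pairwise_rst",
    "nei_distance",
    "amova",
    "genotypic_ld_test",
]


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

@dataclass
class RelatednessResult:
    sample_a: str
    sample_b: str
    r: float           # NaN when no shared typed loci
    n_loci: int
    estimator: str = "queller_goodnight"


def _qg_directional(ab: tuple[int, int], cd: tuple[int, int],
                    freqs: dict[int, float]) -> tuple[float, float]:
    """Queller-Goodnight numerator/denominator with (a,b) as the focal pair."""
    a, b = ab
    c, d = cd
    pa, pb = freqs[a], freqs[b]
    sim = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d))
    num = sim - pa - pb
    den = 1.0 + (a == b) - pa - pb
    return num, den


def pairwise_relatedness(t: GenotypeTable,
                         ref_freqs: AlleleFreqTable | None = None,
                         pairs: list[tuple[int, int]] | None = None,
                         estimator: str = "queller_goodnight") -> list[RelatednessResult]:
    """Queller-Goodnight pairwise relatedness for all (or given) sample pairs.

    The estimator is multilocus-weighted (numerators and denominators summed
    over loci before dividing) and averaged over the two directional forms.
    Reference frequencies default to the pooled sample.  Pairs with no shared
    typed loci get ``r = NaN``.
    """
    if t.n_samples < 2:
        raise ValueError("need at least two samples")
    if estimator not in ("queller_goodnight", "lynch_ritland"):
        raise ValueError(f"unknown estimator {estimator!r}")
    f = ref_freqs if ref_freqs is not None else allele_frequencies(t, "pooled")
    group = f.groups[0]
    freq_by_locus = [f.get(ln, group) for ln in t.locus_names]
    miss = t.missing_mask()
    if pairs is None:
        pairs = list(combinations(range(t.n_samples), 2))

    out: list[RelatednessResult] = []
    for i, k in pairs:
        num_xy = den_xy = num_yx = den_yx = 0.0
        n_loci = 0
        for j in range(t.n_loci):
            if miss[i, j] or miss[k, j]:
                continue
            fr = freq_by_locus[j]
            if not fr:
                continue
            gx = (int(t.calls[i, j, 0]), int(t.calls[i, j, 1]))
            gy = (int(t.calls[k, j, 0]), int(t.calls[k, j, 1]))
            if estimator == "queller_goodnight":
                n1, d1 = _qg_directional(gx, gy, fr)
                n2, d2 = _qg_directional(gy, gx, fr)
            else:
                n1, d1 = _lr_directional(gx, gy, fr)
                n2, d2 = _lr_directional(gy, gx, fr)
            num_xy += n1
            den_xy += d1
            num_yx += n2
            den_yx += d2
            n_loci += 1
        if n_loci == 0 or den_xy == 0 or den_yx == 0:
            r = float("nan")
        else:
            r = 0.5 * (num_xy / den_xy + num_yx / den_yx)
        out.append(RelatednessResult(t.samples[i].id, t.samples[k].id, r,
                                     n_loci, estimator))
    return out


def _lr_directional(ab, cd, freqs):
    """Lynch-Ritland (1999) directional estimator with (a,b) as reference."""
    a, b = ab
    c, d = cd
    pa, pb = freqs[a], freqs[b]
    sac, sad = float(a == c), float(a == d)
    sbc, sbd = float(b == c), float(b == d)
    if a == b:
        # degenerate reference homozygote: fall back to QG form
        return _qg_directional(ab, cd, freqs)
    num = (pa * (sbc + sbd) + pb * (sac + sad) - 4.0 * pa * pb)
    den = (1.0 + float(a == b)) * (pa + pb) - 4.0 * pa * pb
    return num, den


def relatedness_group_means(results: list[RelatednessResult],
                            t: GenotypeTable,
                            grouping: str = "breed") -> pd.DataFrame:
    """Mean +/- SE of within-group pairwise r for each group."""
    pop = {s.id: g for s, g in zip(t.samples, t.group_labels(grouping))}
    rows = []
    groups: dict[str, list[float]] = {}
    for res in results:
        ga, gb = pop[res.sample_a], pop[res.sample_b]
        if ga == gb and math.isfinite(res.r):
            groups.setdefault(ga, []).append(res.r)
    for g, vals in groups.items():
        arr = np.array(vals)
        rows.append({"group": g, "n_pairs": len(arr), "mean_r": arr.mean(),
                     "se_r": arr.std(ddof=1) / math.sqrt(len(arr)) if len(arr) > 1
                     else float("nan")})
    return pd.DataFrame(rows, columns=["group", "n_pairs", "mean_r", "se_r"])


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

def _wc_components(t: GenotypeTable, grouping: str,
                   groups: list[str] | None = None,
                   loci_idx: list[int] | None = None) -> tuple[float, float, float]:
    """Summed Weir-Cockerham (1984) a, b, c components over alleles and loci."""
    labels = np.array(t.group_labels(grouping))
    if groups is None:
        groups = t.groups(grouping)
    if loci_idx is None:
        loci_idx = list(range(t.n_loci))
    miss = t.missing_mask()
    A = B = C = 0.0
    for j in loci_idx:
        pops = []
        for g in groups:
            ok = (labels == g) & ~miss[:, j]
            if ok.sum() >= 1:
                pops.append(t.calls[ok, j, :])
        r = len(pops)
        if r < 1:
            continue
        ns = np.array([len(p) for p in pops], dtype=float)
        nbar = ns.mean()
        if nbar <= 1:
            continue
        nc = ((r * nbar - (ns ** 2).sum() / (r * nbar)) / (r - 1)
              if r > 1 else float("nan"))
        alleles = np.unique(np.concatenate([p.ravel() for p in pops]))
        for al in alleles:
            p_i = np.array([(pop == al).sum() / (2.0 * n)
                            for pop, n in zip(pops, ns)])
            h_i = np.array([((pop[:, 0] == al) ^ (pop[:, 1] == al)).sum() / n
                            for pop, n in zip(pops, ns)])
            pbar = (ns * p_i).sum() / (r * nbar)
            hbar = (ns * h_i).sum() / (r * nbar)
            if r > 1:
                s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
                a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                         - hbar / 4.0) / (nbar - 1))
            else:
                # single population: only the b and c components are defined
                s2 = 0.0
                a = 0.0
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2.0
            A += a
            B += b
            C += c
    return A, B, C


def weir_cockerham_theta(t: GenotypeTable, grouping: str = "breed",
                         groups: list[str] | None = None) -> float:
    """Multi-allelic multi-locus Weir-Cockerham theta (FST)."""
    a, b, c = _wc_components(t, grouping, groups)
    denom = a + b + c
    return a / denom if denom != 0 else float("nan")


def weir_cockerham_fis(t: GenotypeTable, grouping: str = "breed",
                       loci_idx: list[int] | None = None) -> float:
    """Weir-Cockerham small-f (FIS): 1 - c/(b + c)."""
    _, b, c = _wc_components(t, grouping, loci_idx=loci_idx)
    return 1.0 - c / (b + c) if (b + c) != 0 else float("nan")


def individual_fis(t: GenotypeTable, grouping: str = "pooled") -> pd.DataFrame:
    """Per-individual homozygosity-excess index.

    ``FIS_i = 1 - (observed het count) / (sum of per-locus He over the
    individual's typed loci)``, with He from the individual's group.  A
    proxy for an individual inbreeding coefficient.
    """
    f = allele_frequencies(t, grouping)
    labels = t.group_labels(grouping)
    miss = t.missing_mask()
    rows = []
    for i, s in enumerate(t.samples):
        g = labels[i]
        het = 0.0
        exp = 0.0
        for j, ln in enumerate(t.locus_names):
            if miss[i, j]:
                continue
            d = f.get(ln, g)
            if not d:
                continue
            p = np.array(list(d.values()))
            exp += 1.0 - float((p ** 2).sum())
            het += float(t.calls[i, j, 0] != t.calls[i, j, 1])
        fis = 1.0 - het / exp if exp > 0 else float("nan")
        rows.append({"sample": s.id, "group": g, "fis": fis})
    return pd.DataFrame(rows, columns=["sample", "group", "fis"])


def fis_with_ci(t: GenotypeTable, grouping: str = "breed", n_boot: int = 1000,
                seed: int = 1) -> dict:
    """Overall Weir-Cockerham FIS with a 95% bootstrap-over-loci CI.

    Also returns the per-individual FIS proxy table.  With a single locus no
    CI is produced.
    """
    if t.n_loci < 2:
        raise ValueError("need >= 2 loci for FIS with CI")
    fis = weir_cockerham_fis(t, grouping)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, t.n_loci, size=t.n_loci).tolist()
        boots.append(weir_cockerham_fis(t, grouping, loci_idx=idx))
    boots_arr = np.array([b for b in boots if math.isfinite(b)])
    lo, hi = (np.percentile(boots_arr, [2.5, 97.5]) if len(boots_arr)
              else (float("nan"), float("nan")))
    return {"fis": fis, "ci_low": float(lo), "ci_high": float(hi),
            "n_boot": n_boot, "per_individual": individual_fis(t, grouping)}


# ---------------------------------------------------------------------------
# pairwise FST / RST matrices
# ---------------------------------------------------------------------------

@dataclass
class PairwiseStatMatrix:
    labels: list[str]
    values: np.ndarray       # symmetric; diagonal 0
    p_values: np.ndarray | None = None
    p_holm: np.ndarray | None = None
    n_perm: int = 0
    statistic: str = ""

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def pairwise_fst(t: GenotypeTable, grouping: str = "breed", n_perm: int = 110,
                 seed: int = 1) -> PairwiseStatMatrix:
    """Pairwise Weir-Cockerham theta with permutation p-values.

    The p-value for a pair permutes individuals between the two groups
    (``n_perm`` draws, one-sided on theta); Holm adjustment across pairs.
    Groups with fewer than two samples are skipped (NaN entries).
    """
    groups = t.groups(grouping)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels = np.array(t.group_labels(grouping))
    k = len(groups)
    theta = np.zeros((k, k))
    pmat = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for ia, ib in combinations(range(k), 2):
        ga, gb = groups[ia], groups[ib]
        idx = np.where((labels == ga) | (labels == gb))[0]
        if (labels == ga).sum() < 2 or (labels == gb).sum() < 2:
            theta[ia, ib] = theta[ib, ia] = np.nan
            continue
        sub = t.subset_samples(idx)
        obs = weir_cockerham_theta(sub, grouping)
        theta[ia, ib] = theta[ib, ia] = obs
        n_a = int((np.array(sub.group_labels(grouping)) == ga).sum())
        hits = 0
        base_labels = np.array(sub.group_labels(grouping))
        for _ in range(n_perm):
            perm = rng.permutation(len(base_labels))
            relabeled = GenotypeTable(
                [type(s)(id=s.id, population=p, locality=s.locality, sex=s.sex)
                 for s, p in zip(sub.samples, base_labels[perm])],
                sub.loci, sub.calls)
            if weir_cockerham_theta(relabeled, "breed") >= obs - 1e-12:
                hits += 1
        pmat[ia, ib] = pmat[ib, ia] = (hits + 1) / (n_perm + 1)
    iu = np.triu_indices(k, 1)
    raw = pmat[iu]
    finite = np.isfinite(raw)
    adj = np.full_like(raw, np.nan)
    if finite.any():
        adj[finite] = holm_correction(raw[finite])
    padj = np.full((k, k), np.nan)
    padj[iu] = adj
    padj.T[iu] = adj
    return PairwiseStatMatrix(groups, theta, pmat, padj, n_perm, "fst_theta")


def pairwise_rst(t: GenotypeTable, grouping: str = "breed") -> PairwiseStatMatrix:
    """Pairwise Slatkin RST from allele-size variance components.

    Sizes are converted to repeat units per locus.  RST = (S_bar - S_w)/S_bar
    with S_bar the total size variance and S_w the weighted within-group
    variance, summed over loci via variance components (AMOVA-style on
    squared size differences).
    """
    for m in t.loci:
        if m.repeat_unit_bp is None:
            raise ValueError(f"locus {m.name} lacks repeat-unit metadata")
    groups = t.groups(grouping)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels = np.array(t.group_labels(grouping))
    miss = t.missing_mask()
    k = len(groups)
    mat = np.zeros((k, k))
    for ia, ib in combinations(range(k), 2):
        num = den = 0.0
        for j, m in enumerate(t.loci):
            unit = m.repeat_unit_bp
            xs = []
            for g in (groups[ia], groups[ib]):
                ok = (labels == g) & ~miss[:, j]
                xs.append(t.calls[ok, j, :].ravel() / unit)
            allx = np.concatenate(xs)
            if len(allx) < 2 or np.ptp(allx) == 0:
                continue
            # among/within sums of squares on gene copies
            sst = ((allx - allx.mean()) ** 2).sum()
            ssw = sum(((x - x.mean()) ** 2).sum() for x in xs if len(x) > 0)
            ns = np.array([len(x) for x in xs], dtype=float)
            n_tot = ns.sum()
            dfw = n_tot - 2
            dfa = 1.0
            if dfw <= 0:
                continue
            msw = ssw / dfw
            msa = (sst - ssw) / dfa
            nc = (n_tot - (ns ** 2).sum() / n_tot) / dfa
            s2a = max((msa - msw) / nc, 0.0) if nc > 0 else 0.0
            num += s2a
            den += s2a + msw
        mat[ia, ib] = mat[ib, ia] = num / den if den > 0 else float("nan")
    return PairwiseStatMatrix(groups, mat, statistic="rst")


def nei_distance(f: AlleleFreqTable, group_a: str, group_b: str) -> float:
    """Nei (1972) standard genetic distance D = -ln I between two groups.

    I = sum_loci sum_i p1 p2 / sqrt(sum_loci sum p1^2 * sum_loci sum p2^2)
    over loci typed in both groups.  Returns +inf when I = 0.
    """
    jxy = jx = jy = 0.0
    shared = 0
    for locus in f.loci:
        d1, d2 = f.get(locus, group_a), f.get(locus, group_b)
        if not d1 or not d2:
            continue
        shared += 1
        for al in set(d1) | set(d2):
            p1, p2 = d1.get(al, 0.0), d2.get(al, 0.0)
            jxy += p1 * p2
            jx += p1 * p1
            jy += p2 * p2
    if shared == 0:
        raise ValueError("no shared typed loci")
    if jxy == 0.0:
        return float("inf")
    i_val = jxy / math.sqrt(jx * jy)
    return -math.log(i_val)


def nei_distance_matrix(t: GenotypeTable, grouping: str = "breed") -> PairwiseStatMatrix:
    f = allele_frequencies(t, grouping)
    groups = t.groups(grouping)
    k = len(groups)
    mat = np.zeros((k, k))
    for ia, ib in combinations(range(k), 2):
        mat[ia, ib] = mat[ib, ia] = nei_distance(f, groups[ia], groups[ib])
    return PairwiseStatMatrix(groups, mat, statistic="nei_d")


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Three-level codominant AMOVA (Excoffier): variance components and
    percentages for among populations / among individuals within populations
    / within individuals, plus Phi statistics.  Raw (possibly negative)
    components are retained; percentages truncate negatives to 0."""

    sigma_among_pops: float
    sigma_among_ind: float
    sigma_within_ind: float
    pct_among_pops: float
    pct_among_ind: float
    pct_within_ind: float
    phi_st: float
    phi_is: float
    phi_it: float
    df: tuple[float, float, float]
    ss: tuple[float, float, float]

    @property
    def total_variance(self) -> float:
        return self.sigma_among_pops + self.sigma_among_ind + self.sigma_within_ind


def amova(t: GenotypeTable, grouping: str = "breed") -> AmovaResult:
    """Locus-by-locus three-level AMOVA with the allele-mismatch distance.

    Gene copies are the base observations; the squared distance between two
    copies is 0 for identical alleles and 1 otherwise, which makes the
    distance between two individuals the count of non-shared alleles (0/1/2).
    Sums of squares and degrees of freedom are accumulated over loci with
    pairwise deletion, then converted to variance components.
    """
    groups = t.groups(grouping)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels = np.array(t.group_labels(grouping))
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 individuals")
    miss = t.missing_mask()

    ss_ap = ss_ai = ss_wi = 0.0
    df_ap = df_ai = df_wi = 0.0
    nc_num = 0.0
    nc_wt = 0.0
    for j in range(t.n_loci):
        pops = []
        for g in groups:
            ok = (labels == g) & ~miss[:, j]
            if ok.sum() >= 1:
                pops.append(t.calls[ok, j, :])
        r = len(pops)
        if r < 2:
            continue
        ns = np.array([len(p) for p in pops], dtype=float)  # individuals
        n_tot = ns.sum()
        copies = [p.ravel() for p in pops]
        allc = np.concatenate(copies)

        def ss_copies(x: np.ndarray) -> float:
            # sum of squared 0/1 distances to centroid over gene copies:
            # (1/m) * sum_{i<j} d_ij with d in {0,1}
            m = len(x)
            if m < 2:
                return 0.0
            _, counts = np.unique(x, return_counts=True)
            same = (counts * (counts - 1) / 2).sum()
            total_pairs = m * (m - 1) / 2
            return (total_pairs - same) / m

        sst = ss_copies(allc)
        ssp = sum(ss_copies(c) for c in copies)           # within populations
        ssi = 0.0                                          # within individuals
        for p in pops:
            het = (p[:, 0] != p[:, 1]).sum()
            ssi += het * 0.5
        ss_ap += sst - ssp
        ss_ai += ssp - ssi
        ss_wi += ssi
        df_ap += r - 1
        df_ai += n_tot - r
        df_wi += n_tot
        nc = (n_tot - (ns ** 2).sum() / n_tot) / (r - 1)  # in individuals
        nc_num += nc * (r - 1)
        nc_wt += r - 1

    if df_ap <= 0 or df_ai <= 0 or df_wi <= 0:
        raise ValueError("degenerate AMOVA design")
    ms_ap = ss_ap / df_ap
    ms_ai = ss_ai / df_ai
    ms_wi = ss_wi / df_wi
    n_c = nc_num / nc_wt
    sigma_wi = ms_wi
    sigma_ai = (ms_ai - ms_wi) / 2.0
    sigma_ap = (ms_ap - ms_wi - 2.0 * sigma_ai) / (2.0 * n_c)
    trunc = np.clip([sigma_ap, sigma_ai, sigma_wi], 0.0, None)
    total_t = trunc.sum()
    pct = 100.0 * trunc / total_t if total_t > 0 else np.full(3, np.nan)
    total = sigma_ap + sigma_ai + sigma_wi
    phi_st = sigma_ap / total if total != 0 else float("nan")
    phi_is = (sigma_ai / (sigma_ai + sigma_wi)
              if (sigma_ai + sigma_wi) != 0 else float("nan"))
    phi_it = ((sigma_ap + sigma_ai) / total if total != 0 else float("nan"))
    return AmovaResult(sigma_ap, sigma_ai, sigma_wi, *pct, phi_st, phi_is,
                       phi_it, (df_ap, df_ai, df_wi), (ss_ap, ss_ai, ss_wi))


# ---------------------------------------------------------------------------
# genotypic linkage disequilibrium
# ---------------------------------------------------------------------------

def _g_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """G statistic of the contingency table of two categorical vectors."""
    xi, xc = np.unique(x, return_inverse=True)
    yi, yc = np.unique(y, return_inverse=True)
    obs = np.zeros((len(xi), len(yi)))
    np.add.at(obs, (xc, yc), 1.0)
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / n
    mask = obs > 0
    return float(2.0 * (obs[mask] * np.log(obs[mask] / exp[mask])).sum())


def genotypic_ld_test(t: GenotypeTable, locus_a: str, locus_b: str,
                      grouping: str = "pooled", group: str | None = None,
                      n_perm: int = 1000, seed: int = 1) -> float:
    """Permutation G-test of genotypic association between two loci.

    Builds the two-locus genotype contingency table over individuals typed at
    both loci (within ``group`` if given) and permutes one locus's genotypes
    among individuals.  Returns the permutation p-value
    ``(1 + #{G_perm >= G_obs}) / (n_perm + 1)``.
    """
    ja, jb = t.locus_index(locus_a), t.locus_index(locus_b)
    labels = np.array(t.group_labels(grouping))
    miss = t.missing_mask()
    ok = ~miss[:, ja] & ~miss[:, jb]
    if group is not None:
        ok &= labels == group
    if ok.sum() < 5:
        raise ValueError("fewer than 5 complete two-locus genotypes")
    ga = t.calls[ok, ja, 0] * 100_000 + t.calls[ok, ja, 1]
    gb = t.calls[ok, jb, 0] * 100_000 + t.calls[ok, jb, 1]
    obs = _g_statistic(ga, gb)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _g_statistic(ga, rng.permutation(gb)) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
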
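"""mtDNA D-loop diversity, differentiation, neutrality and mismatch statistics.

Works on an equal-length haplotype alignment with population labels.  Sites
containing a gap or N in any sequence are removed before all statistics
(complete deletion, the default; a pairwise mode that keeps all sites is
available), identical remaining sequences are collapsed into haplotypes, and
segregating sites are counted on the retained sites.

Per population: number of haplotypes H, haplotype diversity
``h = n/(n-1) (1 - sum f_i^2)`` with Nei's sampling variance, mean pairwise
difference count k, nucleotide diversity ``pi = k / L`` with the
Tajima/Nei total variance, and Watterson's per-site
``theta_S = S / (a_n L)`` (``a_n = sum_{i=1}^{n-1} 1/i``).

Between populations: Nei's GST on haplotype frequencies, an unbiased
``FST = 1 - Hs/Ht`` variant (Nei-Chesser corrected heterozygosities, may be
slightly negative), Phi-ST from a two-level AMOVA on pairwise nucleotide
differences, Dxy, Da = Dxy - (pi_X + pi_Y)/2, and ``Nm = (1 - FST)/(2 FST)``
for maternally inherited haploid markers.

Neutrality: Tajima's D, Fu & Li's D* and F* (no outgroup, total singleton
count eta_s), and Fu's Fs through the Ewens sampling formula (exact unsigned
Stirling-number recursion).  Mismatch distributions are compared against the
constant-size geometric expectation ``F_i = theta^i / (1 + theta)^(i+1)``
with ``theta = k``, and summarised by Harpending's raggedness index
``r = sum_{i=1}^{d+1} (x_i - x_{i-1})^2`` with a trailing zero class
``x_{d+1} = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd

from .geno_core import AlignmentError, DloopAlignment

__all__ = [
    "HaplotypeTable",
    "DloopDiversity",
    "DloopDifferentiation",
    "NeutralityResult",
    "MismatchResult",
    "collapse_haplotypes",
    "diversity_stats",
    "differentiation",
    "neutrality_tests",
    "mismatch_distribution",
    "tajimas_d",
    "fu_li_dstar_fstar",
    "fus_fs",
    "ewens_k_distribution",
]

_VALID = set("ACGT")


# ---------------------------------------------------------------------------
# haplotype collapsing
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeTable:
    """Collapsed haplotypes on the retained (analysed) alignment sites."""

    haplotypes: dict[str, str]                 # hap id -> retained-site sequence
    counts: dict[str, dict[str, int]]          # population -> hap id -> count
    assignment: dict[str, str]                 # sequence id -> hap id
    s_sites: int                               # segregating sites (retained)
    length: int                                # retained alignment length
    populations: list[str] = field(default_factory=list)
    filtered: DloopAlignment | None = None     # alignment on retained sites

    def n(self, population: str | None = None) -> int:
        if population is None:
            return sum(self.n(p) for p in self.counts)
        return sum(self.counts[population].values())

    def freq_vector(self, population: str) -> np.ndarray:
        c = self.counts[population]
        tot = sum(c.values())
        return np.array([v / tot for v in c.values()], dtype=float)


def collapse_haplotypes(a: DloopAlignment,
                        site_filter: str = "complete_deletion") -> HaplotypeTable:
    """Collapse identical sequences into haplotypes after site filtering.

    ``complete_deletion`` removes every column carrying a gap or N in any
    sequence before comparison; ``pairwise`` keeps all columns (downstream
    pair comparisons then skip sites invalid in either member).  Raises when
    filtering removes every site.
    """
    mat = a.matrix()
    if site_filter == "complete_deletion":
        valid_col = np.ones(a.length, dtype=bool)
        for ch in ("N", "-"):
            valid_col &= ~(mat == ch).any(axis=0)
        mat = mat[:, valid_col]
        if mat.shape[1] == 0:
            raise AlignmentError("complete deletion removed every site")
    elif site_filter != "pairwise":
        raise ValueError(f"unknown site_filter {site_filter!r}")

    seqs = ["".join(row) for row in mat]
    hap_of_seq: dict[str, str] = {}
    haplotypes: dict[str, str] = {}
    assignment: dict[str, str] = {}
    counts: dict[str, dict[str, int]] = {}
    for (rid, pop, _), s in zip(a.records, seqs):
        if s not in hap_of_seq:
            hap_of_seq[s] = f"H{len(hap_of_seq) + 1}"
            haplotypes[hap_of_seq[s]] = s
        hid = hap_of_seq[s]
        assignment[rid] = hid
        counts.setdefault(pop, {})[hid] = counts.setdefault(pop, {}).get(hid, 0) + 1

    s_sites = 0
    for j in range(mat.shape[1]):
        col = mat[:, j]
        bases = {c for c in col if c in _VALID}
        if len(bases) >= 2:
            s_sites += 1
    filtered = DloopAlignment([(rid, pop, s)
                               for (rid, pop, _), s in zip(a.records, seqs)])
    return HaplotypeTable(haplotypes, counts, assignment, s_sites,
                          mat.shape[1], list(counts), filtered)


# ---------------------------------------------------------------------------
# pairwise difference machinery
# ---------------------------------------------------------------------------

def _encode(seqs: list[str]) -> np.ndarray:
    lut = np.zeros(128, dtype=np.int8)
    for i, ch in enumerate("ACGT"):
        lut[ord(ch)] = i + 1
    arr = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
    return lut[arr]  # 0 = invalid (gap/N)


def _pairwise_diffs(x: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
    """Difference counts between rows of x (upper triangle) or across x, y.

    Sites invalid (gap/N) in either sequence of a pair are skipped.
    """
    if y is None:
        n = len(x)
        out = np.zeros((n, n), dtype=np.int64)
        for i, j in combinations(range(n), 2):
            ok = (x[i] > 0) & (x[j] > 0)
            out[i, j] = out[j, i] = int((x[i][ok] != x[j][ok]).sum())
        return out
    out = np.zeros((len(x), len(y)), dtype=np.int64)
    for i in range(len(x)):
        ok_i = x[i] > 0
        for j in range(len(y)):
            ok = ok_i & (y[j] > 0)
            out[i, j] = int((x[i][ok] != y[j][ok]).sum())
    return out


def _pop_matrix(ht: HaplotypeTable, population: str) -> np.ndarray:
    assert ht.filtered is not None
    seqs = [s for _, pop, s in ht.filtered.records if pop == population]
    return _encode(seqs)


def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i ** power for i in range(1, n))


# ---------------------------------------------------------------------------
# per-population diversity
# ---------------------------------------------------------------------------

@dataclass
class DloopDiversity:
    population: str
    n: int
    h_haplotypes: int
    hap_diversity: float
    hap_diversity_sd: float
    pi: float
    pi_sd: float
    theta_s: float
    k: float
    s_sites: int


def diversity_stats(ht: HaplotypeTable) -> list[DloopDiversity]:
    """Haplotype and nucleotide diversity per population (needs n >= 2)."""
    out = []
    for pop in ht.populations:
        n = ht.n(pop)
        if n < 2:
            raise ValueError(f"population {pop!r} has n < 2")
        f = ht.freq_vector(pop)
        sum2 = float((f ** 2).sum())
        h = n / (n - 1.0) * (1.0 - sum2)
        sum3 = float((f ** 3).sum())
        var_h = (2.0 / (n * (n - 1.0))) * (
            2.0 * (n - 2.0) * (sum3 - sum2 ** 2) + sum2 - sum2 ** 2)
        x = _pop_matrix(ht, pop)
        d = _pairwise_diffs(x)
        iu = np.triu_indices(n, 1)
        k = float(d[iu].mean())
        L = ht.length
        pi = k / L
        s_pop, _ = _pop_segregating(x)
        var_pi = ((n + 1.0) / (3.0 * (n - 1.0) * L) * pi
                  + 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0)) * pi ** 2)
        a1 = _harmonic(n)
        theta_s = s_pop / (a1 * L) if a1 > 0 else float("nan")
        out.append(DloopDiversity(
            population=pop, n=n, h_haplotypes=len(ht.counts[pop]),
            hap_diversity=h, hap_diversity_sd=math.sqrt(max(var_h, 0.0)),
            pi=pi, pi_sd=math.sqrt(max(var_pi, 0.0)), theta_s=theta_s,
            k=k, s_sites=s_pop))
    return out


def _pop_segregating(x: np.ndarray) -> tuple[int, int]:
    """(segregating sites, singletons) for one population's encoded matrix."""
    s = 0
    singletons = 0
    for j in range(x.shape[1]):
        col = x[:, j]
        col = col[col > 0]
        if len(col) < 2:
            continue
        vals, counts = np.unique(col, return_counts=True)
        if len(vals) >= 2:
            s += 1
            singletons += int((counts == 1).sum())
    return s, singletons


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

@dataclass
class DloopDifferentiation:
    pop_a: str
    pop_b: str
    g_st: float
    f_st: float
    phi_st: float
    d_xy: float
    d_a: float
    n_m: float


def differentiation(ht: HaplotypeTable) -> list[DloopDifferentiation]:
    """Pairwise population differentiation on haplotypes and sequences."""
    pops = ht.populations
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    mats = {p: _pop_matrix(ht, p) for p in pops}
    L = ht.length
    out = []
    for pa, pb in combinations(pops, 2):
        na, nb = ht.n(pa), ht.n(pb)
        all_haps = sorted(set(ht.counts[pa]) | set(ht.counts[pb]))
        fa = np.array([ht.counts[pa].get(h, 0) / na for h in all_haps])
        fb = np.array([ht.counts[pb].get(h, 0) / nb for h in all_haps])
        hs = 0.5 * ((1 - (fa ** 2).sum()) + (1 - (fb ** 2).sum()))
        fbar = 0.5 * (fa + fb)
        ht_div = 1.0 - float((fbar ** 2).sum())
        g_st = (ht_div - hs) / ht_div if ht_div > 0 else float("nan")
        # Nei-Chesser unbiased variant
        n_harm = 2.0 / (1.0 / na + 1.0 / nb)
        hs_hat = (n_harm / (n_harm - 1.0)) * hs
        ht_hat = ht_div + hs_hat / (2.0 * n_harm)
        f_st = 1.0 - hs_hat / ht_hat if ht_hat > 0 else float("nan")

        da_mat = _pairwise_diffs(mats[pa])
        db_mat = _pairwise_diffs(mats[pb])
        dxy_mat = _pairwise_diffs(mats[pa], mats[pb])
        # Nei's frequency-weighted forms: within-population pi uses the n^2
        # denominator so that Da vanishes for identical populations
        pi_a = float(da_mat.sum()) / (na * na) / L
        pi_b = float(db_mat.sum()) / (nb * nb) / L
        d_xy = float(dxy_mat.mean()) / L
        d_a = d_xy - 0.5 * (pi_a + pi_b)

        phi_st = _phi_st(da_mat, db_mat, dxy_mat, na, nb)
        n_m = (1.0 - f_st) / (2.0 * f_st) if f_st > 0 else float("inf")
        out.append(DloopDifferentiation(pa, pb, g_st, f_st, phi_st, d_xy,
                                        d_a, n_m))
    return out


def _phi_st(da: np.ndarray, db: np.ndarray, dxy: np.ndarray,
            na: int, nb: int) -> float:
    """Two-level AMOVA Phi-ST from pairwise difference matrices."""
    n = na + nb
    iu_a, iu_b = np.triu_indices(na, 1), np.triu_indices(nb, 1)
    ss_wa = float(da[iu_a].sum()) / na if na > 1 else 0.0
    ss_wb = float(db[iu_b].sum()) / nb if nb > 1 else 0.0
    ss_total = (float(da[iu_a].sum()) + float(db[iu_b].sum())
                + float(dxy.sum())) / n
    ss_within = ss_wa + ss_wb
    ss_among = ss_total - ss_within
    df_among, df_within = 1.0, float(n - 2)
    if df_within <= 0:
        return float("nan")
    ms_within = ss_within / df_within
    ms_among = ss_among / df_among
    nc = (n - (na ** 2 + nb ** 2) / n) / df_among
    sigma_a = (ms_among - ms_within) / nc
    total = sigma_a + ms_within
    return sigma_a / total if total != 0 else float("nan")


# ---------------------------------------------------------------------------
# neutrality tests
# ---------------------------------------------------------------------------

def tajimas_d(n: int, s: int, k: float) -> float:
    """Tajima's D with the standard constants; NaN when S = 0 or n < 4."""
    if s == 0 or n < 4:
        return float("nan")
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * s + e2 * s * (s - 1.0)
    return (k - s / a1) / math.sqrt(var)


def fu_li_dstar_fstar(n: int, s: int, eta_s: int, k: float) -> tuple[float, float]:
    """Fu & Li's D* and F* without an outgroup (total singleton count eta_s).

    Uses the corrected constants (the convention of the standard DNA
    polymorphism packages).  Returns (D*, F*); NaN when S = 0 or n < 4.
    """
    if s == 0 or n < 4:
        return float("nan"), float("nan")
    nn = float(n)
    an = _harmonic(n)
    bn = _harmonic(n, 2)
    an1 = an + 1.0 / nn
    cn = 2.0 * (nn * an - 2.0 * (nn - 1.0)) / ((nn - 1.0) * (nn - 2.0))
    dn = (cn + (nn - 2.0) / (nn - 1.0) ** 2
          + (2.0 / (nn - 1.0)) * (1.5 - (2.0 * an1 - 3.0) / (nn - 2.0) - 1.0 / nn))
    v_d = (((nn / (nn - 1.0)) ** 2 * bn + an ** 2 * dn
            - 2.0 * (nn * an * (an + 1.0)) / (nn - 1.0) ** 2)
           / (an ** 2 + bn))
    u_d = (nn / (nn - 1.0)) * (an - nn / (nn - 1.0)) - v_d
    dstar = ((nn / (nn - 1.0)) * s - an * eta_s) / math.sqrt(
        u_d * s + v_d * s * s)

    v_f = ((dn + 2.0 * (nn ** 2 + nn + 3.0) / (9.0 * nn * (nn - 1.0))
            - (2.0 / (nn - 1.0)) * (4.0 * bn - 6.0 + 8.0 / nn))
           / (an ** 2 + bn))
    u_f = ((nn / (nn - 1.0) + (nn + 1.0) / (3.0 * (nn - 1.0))
            - 4.0 / (nn * (nn - 1.0))
            + 2.0 * (nn + 1.0) / (nn - 1.0) ** 2 * (an1 - 2.0 * nn / (nn + 1.0)))
           / an - v_f)
    fstar = (k - ((nn - 1.0) / nn) * eta_s) / math.sqrt(u_f * s + v_f * s * s)
    return dstar, fstar


@lru_cache(maxsize=None)
def _stirling_row(n: int) -> tuple[int, ...]:
    """Unsigned Stirling numbers of the first kind |s(n, k)| for k = 0..n."""
    if n == 0:
        return (1,)
    prev = _stirling_row(n - 1)
    row = [0] * (n + 1)
    for k in range(n + 1):
        row[k] = (prev[k - 1] if k >= 1 else 0) + (n - 1) * (prev[k] if k < n else 0)
    return tuple(row)


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k) for k = 0..n under the Ewens sampling formula.

    P(K = k) = |s(n, k)| theta^k / (theta)_n with (theta)_n the rising
    factorial.  Exact Stirling recursion; valid for n up to a few hundred.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    row = _stirling_row(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    out = np.zeros(n + 1)
    for k in range(1, n + 1):
        out[k] = math.exp(math.log(row[k]) + k * math.log(theta) - log_rising)
    return out


def fus_fs(n: int, k_obs: int, theta: float) -> float:
    """Fu's Fs = ln(S' / (1 - S')) with S' = P(K >= k_obs | theta).

    ``theta`` is customarily the observed mean pairwise difference count k;
    ``k_obs`` the observed number of haplotypes.  NaN when theta <= 0 or the
    tail probability degenerates.
    """
    if theta <= 0 or k_obs <= 0:
        return float("nan")
    p = ewens_k_distribution(n, theta)
    s_prime = float(p[k_obs:].sum())
    if not (0.0 < s_prime < 1.0):
        return float("nan")
    return math.log(s_prime / (1.0 - s_prime))


@dataclass
class NeutralityResult:
    population: str
    n: int
    s_sites: int
    eta_s: int
    tajima_d: float
    fu_li_dstar: float
    fu_li_fstar: float
    fu_fs: float


def neutrality_tests(ht: HaplotypeTable) -> list[NeutralityResult]:
    """Tajima's D, Fu & Li's D*/F* and Fu's Fs per population.

    Statistics are undefined (NaN) when S = 0 or n < 4.
    """
    out = []
    for pop in ht.populations:
        x = _pop_matrix(ht, pop)
        n = len(x)
        s, eta_s = _pop_segregating(x)
        if n >= 2:
            d = _pairwise_diffs(x)
            iu = np.triu_indices(n, 1)
            k = float(d[iu].mean())
        else:
            k = float("nan")
        if s == 0 or n < 4:
            out.append(NeutralityResult(pop, n, s, eta_s, float("nan"),
                                        float("nan"), float("nan"),
                                        float("nan")))
            continue
        dstar, fstar = fu_li_dstar_fstar(n, s, eta_s, k)
        n_hap = len({tuple(row) for row in x})
        fs = fus_fs(n, n_hap, k)
        out.append(NeutralityResult(pop, n, s, eta_s, tajimas_d(n, s, k),
                                    dstar, fstar, fs))
    return out


# ---------------------------------------------------------------------------
# mismatch distribution
# ---------------------------------------------------------------------------

@dataclass
class MismatchResult:
    population: str
    observed: np.ndarray      # x_0..x_d, fractions of pairs
    expected: np.ndarray      # constant-size geometric with theta = k
    raggedness: float
    theta: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"differences": np.arange(len(self.observed)),
                             "observed": self.observed,
                             "expected": self.expected})


def mismatch_distribution(ht: HaplotypeTable,
                          population: str | None = None) -> MismatchResult:
    """Observed vs constant-size expected pairwise-difference distribution.

    Needs n >= 3.  The raggedness index follows the stated trailing-zero
    convention: ``r = sum_{i=1}^{d+1} (x_i - x_{i-1})^2`` with x_{d+1} = 0.
    """
    if population is None:
        assert ht.filtered is not None
        x = _encode([s for _, _, s in ht.filtered.records])
        population = "all"
    else:
        x = _pop_matrix(ht, population)
    n = len(x)
    if n < 3:
        raise ValueError("mismatch distribution needs n >= 3")
    d = _pairwise_diffs(x)
    iu = np.triu_indices(n, 1)
    diffs = d[iu]
    dmax = int(diffs.max())
    obs = np.bincount(diffs, minlength=dmax + 1).astype(float)
    obs /= obs.sum()
    theta = float(diffs.mean())
    i = np.arange(dmax + 1)
    if theta > 0:
        expected = theta ** i / (1.0 + theta) ** (i + 1)
    else:
        expected = np.zeros(dmax + 1)
        expected[0] = 1.0
    padded = np.append(obs, 0.0)
    ragged = float(((padded[1:] - padded[:-1]) ** 2).sum())
    return MismatchResult(population, obs, expected, ragged, theta)
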
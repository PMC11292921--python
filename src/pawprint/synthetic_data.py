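"""Synthetic genotype tables, pedigrees and D-loop alignments.

The generator emulates the statistical structure of a small panel of weakly
differentiated domestic-cat breed populations: ~5 populations of 18-59
diploids, 15 dinucleotide microsatellite loci with 5-12 alleles each, mean
expected heterozygosity around 0.69, weak differentiation, and optional
inbreeding, null alleles and missing data.

Model
-----
* Ancestral allele frequencies per locus are drawn from a symmetric Dirichlet
  (concentration ``dirichlet_conc``, default 0.45, which puts the expected
  within-population He near 0.69 for 5-12 alleles).
* Population frequencies follow a Balding-Nichols-style law: a Dirichlet draw
  with concentration vector ``p_anc * (1 - fst) / fst``, which has mean
  ``p_anc`` and the FST-like variance inflation ``fst``.
* Genotypes: with probability ``f_is`` the two alleles are identical by
  descent (one draw duplicated), otherwise two independent draws.
* Null alleles: each locus carries a hidden null allele at frequency
  ``null_rate``; null/visible genotypes appear homozygous for the visible
  allele, null/null genotypes are missing.
* All randomness flows from one seed through ``numpy.random.Generator.spawn``
  so sub-simulations are independently reproducible.

``simulate_neutral_alignment`` draws constant-size neutral coalescent samples
(via msprime) for calibrating the neutrality tests; the lightweight
``simulate_dloop_alignment`` builds a fixed set of haplotypes on a star
topology and samples individuals from given haplotype frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geno_core import (MISSING, AlleleFreqTable, DloopAlignment, GenotypeTable,
                        LocusMeta, Sample)

__all__ = [
    "SimConfig",
    "SimTruth",
    "PedigreeSim",
    "PedigreeTruth",
    "simulate_populations",
    "simulate_pedigree",
    "simulate_dloop_alignment",
    "simulate_neutral_alignment",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Configuration for :func:`simulate_populations`.

    Defaults are the study conditions this package targets: five breed
    populations with sample sizes 59/29/41/37/18, fifteen dinucleotide loci
    with 5-12 alleles, expected He ~ 0.69 and weak differentiation.
    """

    n_pops: int = 5
    n_per_pop: Sequence[int] = (59, 29, 41, 37, 18)
    n_loci: int = 15
    alleles_per_locus: int | tuple[int, int] = (5, 12)
    dirichlet_conc: float = 0.45
    fst: float = 0.02
    f_is: float = 0.0
    null_rate: float = 0.0
    missing_rate: float = 0.0
    repeat_unit_bp: int = 2
    n_localities_per_pop: int = 2
    seed: int = 1

    def __post_init__(self) -> None:
        if len(self.n_per_pop) != self.n_pops:
            raise ValueError("n_per_pop length must equal n_pops")
        kmin, kmax = self._allele_range()
        if kmin < 1:
            raise ValueError("alleles_per_locus must be >= 1")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        if not (0.0 <= self.f_is <= 1.0):
            raise ValueError("f_is must be in [0, 1]")
        for name in ("null_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")

    def _allele_range(self) -> tuple[int, int]:
        if isinstance(self.alleles_per_locus, int):
            return self.alleles_per_locus, self.alleles_per_locus
        lo, hi = self.alleles_per_locus
        return int(lo), int(hi)


@dataclass
class SimTruth:
    """True generating parameters recorded next to a simulated table."""

    ancestral_freqs: list[dict[int, float]]
    pop_freqs: list[list[dict[int, float]]]  # per pop, per locus
    expected_he: float                        # mean over loci of (1-fst)(1-sum p_anc^2)
    fst: float
    f_is: float
    null_rate: float
    per_locus_expected_he: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "expected_he": self.expected_he,
            "per_locus_expected_he": self.per_locus_expected_he,
            "fst": self.fst,
            "f_is": self.f_is,
            "null_rate": self.null_rate,
            "ancestral_freqs": [{str(a): p for a, p in f.items()}
                                for f in self.ancestral_freqs],
        }


def _locus_allele_sizes(rng: np.random.Generator, k: int, unit: int) -> np.ndarray:
    """Allele sizes on the repeat-unit grid; kept under 1000 bp (GenePop 3-digit)."""
    base = int(rng.integers(100, 260))
    base -= base % unit
    return base + unit * np.arange(k, dtype=np.int64)


def simulate_populations(cfg: SimConfig) -> tuple[GenotypeTable, SimTruth]:
    """Simulate a multi-population diploid microsatellite table.

    Returns the table and a :class:`SimTruth` record holding the realised
    ancestral/population frequencies and the model-expected mean He
    ``mean over loci of (1 - fst)(1 - sum p_anc^2)`` (inbreeding lowers Ho,
    not He).  Deterministic under ``cfg.seed``.
    """
    root = np.random.default_rng(cfg.seed)
    rng_freq, rng_geno, rng_noise = root.spawn(3)
    kmin, kmax = cfg._allele_range()

    loci = [LocusMeta(name=f"L{j + 1:02d}", repeat_unit_bp=cfg.repeat_unit_bp)
            for j in range(cfg.n_loci)]
    anc: list[dict[int, float]] = []
    sizes: list[np.ndarray] = []
    anc_vec: list[np.ndarray] = []
    for j in range(cfg.n_loci):
        k = int(rng_freq.integers(kmin, kmax + 1))
        s = _locus_allele_sizes(rng_freq, k, cfg.repeat_unit_bp)
        p = rng_freq.dirichlet(np.full(k, cfg.dirichlet_conc))
        p = np.clip(p, 1e-9, None)
        p /= p.sum()
        sizes.append(s)
        anc_vec.append(p)
        anc.append({int(a): float(q) for a, q in zip(s, p)})

    pop_freqs: list[list[dict[int, float]]] = []
    pop_vecs: list[list[np.ndarray]] = []
    for _ in range(cfg.n_pops):
        per_locus = []
        per_vec = []
        for j in range(cfg.n_loci):
            if cfg.fst <= 0:
                q = anc_vec[j].copy()
            else:
                conc = anc_vec[j] * (1.0 - cfg.fst) / cfg.fst
                q = rng_freq.dirichlet(conc)
                q = np.clip(q, 1e-12, None)
                q /= q.sum()
            per_vec.append(q)
            per_locus.append({int(a): float(v) for a, v in zip(sizes[j], q)})
        pop_freqs.append(per_locus)
        pop_vecs.append(per_vec)

    samples: list[Sample] = []
    n_total = int(sum(cfg.n_per_pop))
    calls = np.zeros((n_total, cfg.n_loci, 2), dtype=np.int64)
    row = 0
    for pi, n in enumerate(cfg.n_per_pop):
        pop_name = f"POP{pi + 1}"
        for ii in range(n):
            loc = f"{pop_name}_LOC{ii % cfg.n_localities_per_pop + 1}"
            sex = "M" if rng_noise.random() < 0.5 else "F"
            samples.append(Sample(id=f"{pop_name}_{ii + 1:03d}",
                                  population=pop_name, locality=loc, sex=sex))
        for j in range(cfg.n_loci):
            # augment with hidden null allele (index k)
            q = pop_vecs[pi][j]
            if cfg.null_rate > 0:
                qa = np.concatenate([q * (1.0 - cfg.null_rate), [cfg.null_rate]])
            else:
                qa = q
            k = len(q)
            a1 = rng_geno.choice(len(qa), size=n, p=qa)
            a2 = rng_geno.choice(len(qa), size=n, p=qa)
            ibd = rng_geno.random(n) < cfg.f_is
            a2 = np.where(ibd, a1, a2)
            g = np.stack([a1, a2], axis=1)
            out = np.zeros((n, 2), dtype=np.int64)
            for t in range(n):
                x, y = g[t]
                if x == k and y == k:          # null/null -> missing
                    out[t] = (MISSING, MISSING)
                elif x == k:                   # null/visible -> apparent homozygote
                    out[t] = (sizes[j][y], sizes[j][y])
                elif y == k:
                    out[t] = (sizes[j][x], sizes[j][x])
                else:
                    out[t] = (sizes[j][x], sizes[j][y])
            calls[row:row + n, j, :] = out
        row += n

    if cfg.missing_rate > 0:
        drop = rng_noise.random((n_total, cfg.n_loci)) < cfg.missing_rate
        calls[drop] = MISSING

    per_locus_ehe = [float((1.0 - cfg.fst) * (1.0 - (p ** 2).sum())) for p in anc_vec]
    truth = SimTruth(
        ancestral_freqs=anc, pop_freqs=pop_freqs,
        expected_he=float(np.mean(per_locus_ehe)),
        fst=cfg.fst, f_is=cfg.f_is, null_rate=cfg.null_rate,
        per_locus_expected_he=per_locus_ehe,
    )
    return GenotypeTable(samples, loci, calls), truth


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

@dataclass
class PedigreeSim:
    """Configuration for :func:`simulate_pedigree`.

    Founder genotypes are drawn in Hardy-Weinberg proportions from
    ``founder_freqs`` (the pooled group by default); offspring receive one
    uniformly chosen allele per parent.  ``error_rate`` replaces inherited
    alleles with a random population allele.
    """

    founder_freqs: AlleleFreqTable
    n_trios: int = 0
    n_sib_pairs: int = 0
    error_rate: float = 0.0
    group: str | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if not self.founder_freqs.freqs:
            raise ValueError("founder frequency table is empty")


@dataclass
class PedigreeTruth:
    trios: list[tuple[str, str, str]]          # (sire, dam, offspring) ids
    sib_pairs: list[tuple[str, str]]


def _freq_arrays(f: AlleleFreqTable, group: str) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for locus in f.loci:
        d = f.get(locus, group)
        if not d:
            raise ValueError(f"no founder frequencies for locus {locus!r}")
        alleles = np.array(sorted(d), dtype=np.int64)
        probs = np.array([d[a] for a in alleles], dtype=float)
        out.append((alleles, probs / probs.sum()))
    return out


def simulate_pedigree(p: PedigreeSim) -> tuple[GenotypeTable, PedigreeTruth]:
    """Simulate parent-offspring trios and full-sib pairs.

    The returned table labels each individual's role in its ``locality``
    field (``sire``/``dam``/``offspring``/``sib``) and its family in the
    ``population`` field.  Mendelian-consistent when ``error_rate == 0``.
    """
    rng = np.random.default_rng(p.seed)
    group = p.group if p.group is not None else p.founder_freqs.groups[0]
    fa = _freq_arrays(p.founder_freqs, group)
    n_loci = len(fa)
    loci = [LocusMeta(name) for name in p.founder_freqs.loci]
    n_fam = p.n_trios + p.n_sib_pairs
    if n_fam == 0:
        raise ValueError("pedigree simulation produced no individuals")

    # vectorised over families, locus by locus
    def founders(count: int, j: int) -> np.ndarray:
        alleles, probs = fa[j]
        return rng.choice(alleles, size=(count, 2), p=probs)

    def children(sire: np.ndarray, dam: np.ndarray, j: int) -> np.ndarray:
        count = len(sire)
        pick_s = rng.integers(0, 2, size=count)
        pick_d = rng.integers(0, 2, size=count)
        g = np.stack([sire[np.arange(count), pick_s],
                      dam[np.arange(count), pick_d]], axis=1)
        if p.error_rate > 0:
            alleles, probs = fa[j]
            err = rng.random((count, 2)) < p.error_rate
            if err.any():
                g[err] = rng.choice(alleles, size=int(err.sum()), p=probs)
        return g

    trio_calls = np.zeros((p.n_trios, 3, n_loci, 2), dtype=np.int64)
    sib_calls = np.zeros((p.n_sib_pairs, 2, n_loci, 2), dtype=np.int64)
    for j in range(n_loci):
        if p.n_trios:
            sire, dam = founders(p.n_trios, j), founders(p.n_trios, j)
            trio_calls[:, 0, j] = sire
            trio_calls[:, 1, j] = dam
            trio_calls[:, 2, j] = children(sire, dam, j)
        if p.n_sib_pairs:
            sire, dam = founders(p.n_sib_pairs, j), founders(p.n_sib_pairs, j)
            sib_calls[:, 0, j] = children(sire, dam, j)
            sib_calls[:, 1, j] = children(sire, dam, j)

    samples: list[Sample] = []
    trios: list[tuple[str, str, str]] = []
    sib_pairs: list[tuple[str, str]] = []
    for f in range(p.n_trios):
        name = f"FAM{f + 1:05d}"
        ids = (f"{name}_sire", f"{name}_dam", f"{name}_off")
        for sid, role in zip(ids, ("sire", "dam", "offspring")):
            samples.append(Sample(id=sid, population=name, locality=role))
        trios.append(ids)
    for f in range(p.n_sib_pairs):
        name = f"FAM{p.n_trios + f + 1:05d}"
        ids = (f"{name}_sib1", f"{name}_sib2")
        for sid in ids:
            samples.append(Sample(id=sid, population=name, locality="sib"))
        sib_pairs.append(ids)

    parts = []
    if p.n_trios:
        parts.append(trio_calls.reshape(p.n_trios * 3, n_loci, 2))
    if p.n_sib_pairs:
        parts.append(sib_calls.reshape(p.n_sib_pairs * 2, n_loci, 2))
    calls = np.concatenate(parts, axis=0)
    return GenotypeTable(samples, loci, calls), PedigreeTruth(trios, sib_pairs)


# ---------------------------------------------------------------------------
# D-loop alignments
# ---------------------------------------------------------------------------

def simulate_dloop_alignment(n_haplotypes: int,
                             freqs: dict[str, Sequence[float]],
                             length: int = 423,
                             sites_per_haplotype: int = 3,
                             seed: int = 1,
                             n_per_pop: dict[str, int] | None = None) -> DloopAlignment:
    """Sample individuals from a fixed set of star-topology haplotypes.

    ``n_haplotypes`` distinct haplotypes are built from one random reference
    sequence by mutating ``sites_per_haplotype`` private sites each (haplotype
    1 is the reference itself).  ``freqs`` maps each population label to its
    haplotype frequency vector (length ``n_haplotypes``, summing to 1); the
    realised counts are the rounded expectation (largest remainder) at the
    population size from ``n_per_pop`` (default: the smallest n at which the
    frequencies are integer counts).

    Deterministic under ``seed``.
    """
    if n_haplotypes < 1:
        raise ValueError("need at least one haplotype")
    needed = (n_haplotypes - 1) * sites_per_haplotype
    if needed > length:
        raise ValueError(
            f"length {length} too small for {needed} private mutation sites")
    rng = np.random.default_rng(seed)
    ref = rng.choice(4, size=length)
    site_pool = rng.permutation(length)[:needed] if needed else np.array([], dtype=int)
    haps = [ref.copy()]
    for h in range(1, n_haplotypes):
        s = ref.copy()
        mine = site_pool[(h - 1) * sites_per_haplotype: h * sites_per_haplotype]
        for site in mine:
            s[site] = (s[site] + int(rng.integers(1, 4))) % 4
        haps.append(s)
    hap_seqs = ["".join(_BASES[h]) for h in haps]

    records: list[tuple[str, str, str]] = []
    for pop, fvec in freqs.items():
        fvec = np.asarray(fvec, dtype=float)
        if len(fvec) != n_haplotypes:
            raise ValueError(f"frequency vector for {pop!r} has wrong length")
        if abs(fvec.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies for {pop!r} do not sum to 1")
        n = (n_per_pop[pop] if n_per_pop is not None and pop in n_per_pop
             else _infer_n(fvec))
        counts = _largest_remainder(fvec * n)
        i = 0
        for h, c in enumerate(counts):
            for _ in range(int(c)):
                i += 1
                records.append((f"{pop}_{i:03d}", pop, hap_seqs[h]))
    return DloopAlignment(records)


def _infer_n(fvec: np.ndarray, max_n: int = 1000) -> int:
    for n in range(1, max_n + 1):
        if np.allclose(fvec * n, np.round(fvec * n), atol=1e-6):
            return n
    return max_n


def _largest_remainder(x: np.ndarray) -> np.ndarray:
    base = np.floor(x).astype(int)
    rem = int(round(x.sum())) - base.sum()
    order = np.argsort(-(x - base))
    for i in range(rem):
        base[order[i]] += 1
    return base


def simulate_neutral_alignment(n: int, length: int = 423, theta: float = 5.0,
                               seed: int = 1, population: str = "all") -> DloopAlignment:
    """Constant-size neutral coalescent haploid sample (msprime backend).

    ``theta`` is scaled so the expected mean pairwise difference count k
    equals ``theta`` (up to finite-sites saturation).  Finite-sites
    Jukes-Cantor mutations on ``length`` sites.
    """
    import msprime  # deferred: only needed for calibration draws

    seed = int(seed) % (2 ** 31 - 2) + 1
    ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1.0,
                              sequence_length=length, random_seed=seed)
    mts = msprime.sim_mutations(ts, rate=theta / (2.0 * length), model="jc69",
                                random_seed=seed + 1)
    base = np.array(list("ACGT"))
    seqs = {i: list("A" * length) for i in range(n)}
    for var in mts.variants():
        pos = int(var.site.position)
        for i, g in enumerate(var.genotypes):
            seqs[i][pos] = var.alleles[g]
    records = [(f"{population}_{i + 1:03d}", population, "".join(seqs[i]))
               for i in range(n)]
    return DloopAlignment(records)
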
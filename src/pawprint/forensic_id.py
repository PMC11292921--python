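"""Forensic individual-identification and parentage statistics.

Per-locus statistics from allele frequencies (power sums a_k = sum p_i^k):

* ``PID_theoretical = 2 (a2)^2 - a4`` — probability two random individuals
  share a genotype under random mating.
* ``PID_unbiased`` — the small-sample-corrected estimator
  ``[n^3 (2 a2^2 - a4) - 2 n^2 (a3 + 2 a2) + n (9 a2 + 2) - 6] /
  [(n-1)(n-2)(n-3)]`` (needs n >= 4).
* ``PID_sibs = 0.25 + 0.5 a2 + 0.5 a2^2 - 0.25 a4`` — for full siblings.
* ``PE = 1 + 4 a4 - 4 a5 - 3 a6 - 8 a2^2 + 8 a2 a3 + 2 a3^2`` — probability a
  locus excludes an unrelated putative parent pair.
* ``MP`` — per-locus random match probability, by default the sum of squared
  Hardy-Weinberg genotype frequencies (identical to PID_theoretical); the
  literal product over genotype terms ``prod p_i^2 x prod 2 p_i p_j`` is
  available as ``mp_formula="literal"`` for auditability.

Across loci: the PID variants and MP multiply; PE combines as
``1 - prod (1 - PE_l)``.  Also genotype-accumulation curves (how the percent
of distinguishable individuals grows with panel size), the He-ordered
cumulative PID_sibs curve, and exact multilocus match reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .diversity import power_sum
from .geno_core import AlleleFreqTable, GenotypeTable, allele_frequencies

__all__ = [
    "IdStats",
    "AccumulationCurve",
    "per_locus_id_stats",
    "combine_panel",
    "id_stats_frame",
    "genotype_accumulation",
    "percent_distinguished",
    "pid_sibs_locus_curve",
    "match_report",
]


@dataclass
class IdStats:
    locus: str               # locus name or "combined"
    mp: float
    pid_theoretical: float
    pid_unbiased: float      # NaN when n < 4
    pid_sibs: float
    pe: float
    n: int                   # sample size used for the unbiased correction


def _pid_theoretical(p: np.ndarray) -> float:
    a2, a4 = power_sum(p, 2), power_sum(p, 4)
    return 2.0 * a2 * a2 - a4


def _pid_unbiased(p: np.ndarray, n: int) -> float:
    if n < 4:
        return float("nan")
    a2, a3, a4 = (power_sum(p, k) for k in (2, 3, 4))
    num = (n ** 3 * (2 * a2 * a2 - a4) - 2 * n ** 2 * (a3 + 2 * a2)
           + n * (9 * a2 + 2) - 6)
    return num / ((n - 1) * (n - 2) * (n - 3))


def _pid_sibs(p: np.ndarray) -> float:
    a2, a4 = power_sum(p, 2), power_sum(p, 4)
    return 0.25 + 0.5 * a2 + 0.5 * a2 * a2 - 0.25 * a4


def _pe(p: np.ndarray) -> float:
    a2, a3, a4, a5, a6 = (power_sum(p, k) for k in (2, 3, 4, 5, 6))
    return (1.0 + 4 * a4 - 4 * a5 - 3 * a6 - 8 * a2 * a2 + 8 * a2 * a3
            + 2 * a3 * a3)


def _mp_literal(p: np.ndarray) -> float:
    """Literal printed product over genotype terms; collapses toward 0 for
    polymorphic loci, preserved only for auditability."""
    v = 1.0
    for i, pi in enumerate(p):
        v *= pi * pi
        for pj in p[i + 1:]:
            v *= 2.0 * pi * pj
    return v


def per_locus_id_stats(f: AlleleFreqTable, group: str = "all",
                       n: int | None = None,
                       mp_formula: str = "standard") -> list[IdStats]:
    """Identification statistics per locus from an allele frequency table.

    ``n`` is the sample size for the unbiased PID correction; the default is
    each locus's own ``n_typed``.  Monomorphic loci give PID = MP = 1 and
    PE = 0.
    """
    if mp_formula not in ("standard", "literal"):
        raise ValueError(f"unknown mp_formula {mp_formula!r}")
    out = []
    for locus in f.loci:
        d = f.get(locus, group)
        if not d:
            continue
        p = np.array(list(d.values()), dtype=float)
        n_loc = n if n is not None else f.n_typed[(locus, group)]
        mp = _pid_theoretical(p) if mp_formula == "standard" else _mp_literal(p)
        out.append(IdStats(
            locus=locus, mp=mp,
            pid_theoretical=_pid_theoretical(p),
            pid_unbiased=_pid_unbiased(p, n_loc),
            pid_sibs=_pid_sibs(p), pe=_pe(p), n=n_loc))
    return out


def combine_panel(stats: list[IdStats], loci: list[str] | None = None) -> IdStats:
    """Combined multilocus statistics: products for MP/PID, 1 - prod(1 - PE)."""
    by_name = {s.locus: s for s in stats}
    if loci is None:
        loci = [s.locus for s in stats]
    if not loci:
        raise ValueError("empty locus subset")
    missing = [l for l in loci if l not in by_name]
    if missing:
        raise KeyError(f"no statistics for loci {missing}")
    sel = [by_name[l] for l in loci]
    return IdStats(
        locus="combined",
        mp=math.prod(s.mp for s in sel),
        pid_theoretical=math.prod(s.pid_theoretical for s in sel),
        pid_unbiased=math.prod(s.pid_unbiased for s in sel),
        pid_sibs=math.prod(s.pid_sibs for s in sel),
        pe=1.0 - math.prod(1.0 - s.pe for s in sel),
        n=min(s.n for s in sel))


def id_stats_frame(stats: list[IdStats]) -> pd.DataFrame:
    cols = ["locus", "mp", "pid_theoretical", "pid_unbiased", "pid_sibs",
            "pe", "n"]
    return pd.DataFrame([vars(s) for s in stats], columns=cols)


# ---------------------------------------------------------------------------
# genotype accumulation
# ---------------------------------------------------------------------------

def percent_distinguished(t: GenotypeTable, loci: list[str],
                          missing_action: str = "drop") -> float:
    """Percent of individuals carrying distinct multilocus genotypes.

    ``100 * (#distinct genotypes among complete individuals) / (#complete
    individuals)``.  With ``missing_action="drop"`` individuals missing any
    panel locus are excluded; ``"wildcard"`` treats a missing genotype as
    matching anything is NOT implemented here - missing genotypes become
    their own sentinel class (documented alternative).
    """
    idx = [t.locus_index(l) for l in loci]
    miss = t.missing_mask()[:, idx]
    if missing_action == "drop":
        keep = ~miss.any(axis=1)
    elif missing_action == "sentinel":
        keep = np.ones(t.n_samples, dtype=bool)
    else:
        raise ValueError(f"unknown missing_action {missing_action!r}")
    sub = t.calls[np.ix_(np.where(keep)[0], idx)]
    n = sub.shape[0]
    if n == 0:
        return float("nan")
    genos = {tuple(row.ravel()) for row in sub}
    return 100.0 * len(genos) / n


@dataclass
class AccumulationCurve:
    sizes: list[int]
    mean_pct: list[float]
    sd_pct: list[float]
    reps: int
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_loci": self.sizes, "mean_pct": self.mean_pct,
                             "sd_pct": self.sd_pct})


def genotype_accumulation(t: GenotypeTable, reps: int = 1000,
                          seed: int = 1) -> AccumulationCurve:
    """Genotype accumulation curve over random locus subsets.

    For each subset size s = 1..L-1, draws ``reps`` random subsets without
    replacement and reports mean +/- SD of the percent of individuals
    distinguished.  The full-panel point (s = L) is exact.
    """
    if t.n_loci < 2:
        raise ValueError("need >= 2 loci")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    names = t.locus_names
    sizes, means, sds = [], [], []
    for s in range(1, t.n_loci):
        vals = np.empty(reps)
        for r in range(reps):
            pick = rng.choice(t.n_loci, size=s, replace=False)
            vals[r] = percent_distinguished(t, [names[i] for i in pick])
        sizes.append(s)
        means.append(float(np.nanmean(vals)))
        sds.append(float(np.nanstd(vals)))
    sizes.append(t.n_loci)
    means.append(percent_distinguished(t, names))
    sds.append(0.0)
    return AccumulationCurve(sizes, means, sds, reps, seed)


# ---------------------------------------------------------------------------
# He-ordered PID_sibs curve
# ---------------------------------------------------------------------------

def pid_sibs_locus_curve(stats: list[IdStats], he_by_locus: dict[str, float],
                         order: str = "descending",
                         thresholds: tuple[float, ...] = (0.01, 0.001, 0.0001)
                         ) -> dict:
    """Loci needed to push cumulative PID_sibs under each threshold.

    Loci are ranked by He (``descending`` starts with the most informative
    marker, ``ascending`` with the least; ties broken by locus name) and the
    cumulative product of per-locus PID_sibs is scanned for the smallest k
    with product <= threshold.  Unreachable thresholds are flagged None.
    """
    if order not in ("descending", "ascending"):
        raise ValueError("order must be 'descending' or 'ascending'")
    per_locus = [s for s in stats if s.locus != "combined"]
    sign = -1.0 if order == "descending" else 1.0
    ranked = sorted(per_locus, key=lambda s: (sign * he_by_locus[s.locus], s.locus))
    cum = np.cumprod([s.pid_sibs for s in ranked])
    loci_needed: dict[float, int | None] = {}
    for thr in thresholds:
        hit = np.nonzero(cum <= thr)[0]
        loci_needed[thr] = int(hit[0]) + 1 if len(hit) else None
    return {"order": order, "loci": [s.locus for s in ranked],
            "cumulative_pid_sibs": cum.tolist(), "loci_needed": loci_needed}


# ---------------------------------------------------------------------------
# match report
# ---------------------------------------------------------------------------

def match_report(t: GenotypeTable, panel: list[str] | None = None) -> pd.DataFrame:
    """Sample pairs with identical genotypes at every mutually typed panel locus.

    Pairs sharing no typed panel locus are excluded (compared-locus count 0).
    Returns columns ``sample_a, sample_b, n_compared``.
    """
    panel = panel if panel is not None else t.locus_names
    idx = [t.locus_index(l) for l in panel]
    miss = t.missing_mask()[:, idx]
    calls = t.calls[:, idx, :]
    rows = []
    for i, k in combinations(range(t.n_samples), 2):
        both = ~miss[i] & ~miss[k]
        n_comp = int(both.sum())
        if n_comp == 0:
            continue
        if np.array_equal(calls[i][both], calls[k][both]):
            rows.append({"sample_a": t.samples[i].id,
                         "sample_b": t.samples[k].id,
                         "n_compared": n_comp})
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "n_compared"])
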
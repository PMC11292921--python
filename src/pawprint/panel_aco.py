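"""Minimal marker-panel selection by ant colony optimisation (ACO).

Objective (lexicographic): find the smallest locus subset whose percent of
distinguished individuals meets ``100 - error_threshold``; among panels of
that size, maximise mean PIC (ties broken by locus names).  An exhaustive
enumerator over all 2^L - 1 panels serves as the optimality oracle for
L <= 15.

Ants build panels by adding loci with probability proportional to
``tau_l^alpha * eta_l^beta`` (heuristic eta_l = per-locus PIC) until the
distinguishability constraint is met, then greedily drop redundant loci.
Pheromone update: evaporation ``tau <- (1 - rho) tau`` followed by a deposit
on the iteration-best feasible panel proportional to ``1/size`` plus a mean
PIC bonus.  Deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .diversity import pic
from .forensic_id import IdStats, combine_panel, per_locus_id_stats, percent_distinguished
from .geno_core import GenotypeTable, allele_frequencies

__all__ = ["PanelSolution", "aco_select_panel", "exhaustive_best_panel",
           "evaluate_panel"]


@dataclass
class PanelSolution:
    loci: list[str]                  # ordered by selection
    size: int
    mean_pic: float
    percent_distinguished: float
    feasible: bool
    combined: IdStats | None = None
    iterations_used: int = 0
    seed: int = 0
    method: str = ""

    def objective(self) -> tuple[int, float]:
        """Lexicographic objective: (size, -mean PIC); smaller is better."""
        return (self.size, -round(self.mean_pic, 12))


class _PanelEvaluator:
    """Caches percent-distinguished per locus subset (exact, not resampled)."""

    def __init__(self, t: GenotypeTable):
        self.t = t
        self.names = t.locus_names
        f = allele_frequencies(t, "pooled")
        self.pic = np.array([
            pic(np.array(list(f.get(l, "all").values()))) if f.get(l, "all") else 0.0
            for l in self.names])
        self._cache: dict[frozenset[int], float] = {}

    def pct(self, idx: frozenset[int]) -> float:
        if idx not in self._cache:
            loci = [self.names[i] for i in sorted(idx)]
            self._cache[idx] = percent_distinguished(self.t, loci)
        return self._cache[idx]

    def mean_pic(self, idx) -> float:
        idx = list(idx)
        return float(self.pic[idx].mean()) if idx else 0.0


def _solution(ev: _PanelEvaluator, ordered: list[int], threshold: float,
              feasible: bool, method: str, seed: int = 0,
              iters: int = 0) -> PanelSolution:
    idx = frozenset(ordered)
    return PanelSolution(
        loci=[ev.names[i] for i in ordered], size=len(ordered),
        mean_pic=ev.mean_pic(idx), percent_distinguished=ev.pct(idx),
        feasible=feasible, iterations_used=iters, seed=seed, method=method)


def exhaustive_best_panel(t: GenotypeTable, error_threshold: float = 5.0,
                          max_loci: int = 15) -> PanelSolution:
    """Globally optimal panel by enumerating all subsets (L <= max_loci <= 15).

    Scans sizes in ascending order; the first size with a feasible panel is
    optimal; among those the highest mean PIC wins, ties broken by
    lexicographic locus names.  If no panel is feasible the full panel is
    returned flagged infeasible.
    """
    L = t.n_loci
    if L > max_loci or max_loci > 15:
        raise ValueError(f"too many loci to enumerate ({L} > {max_loci})")
    ev = _PanelEvaluator(t)
    target = 100.0 - error_threshold
    for size in range(1, L + 1):
        best: tuple | None = None
        for comb in combinations(range(L), size):
            idx = frozenset(comb)
            if ev.pct(idx) >= target - 1e-9:
                key = (-ev.mean_pic(idx), tuple(ev.names[i] for i in sorted(comb)))
                if best is None or key < best[0]:
                    best = (key, list(comb))
        if best is not None:
            return _solution(ev, best[1], target, True, "exhaustive")
    return _solution(ev, list(range(L)), target, False, "exhaustive")


def aco_select_panel(t: GenotypeTable, error_threshold: float = 5.0,
                     ants: int = 50, iterations: int = 200, alpha: float = 1.0,
                     beta: float = 2.0, rho: float = 0.2, tau0: float = 1.0,
                     seed: int = 1) -> PanelSolution:
    """Ant-colony search for the smallest panel meeting the error threshold.

    See the module docstring for the construction and pheromone rules.  If
    even the full panel is infeasible, it is returned flagged infeasible.
    """
    if not (0.0 < error_threshold <= 100.0):
        raise ValueError("error_threshold must be in (0, 100]")
    L = t.n_loci
    ev = _PanelEvaluator(t)
    target = 100.0 - error_threshold
    full = frozenset(range(L))
    if ev.pct(full) < target - 1e-9:
        return _solution(ev, list(range(L)), target, False, "aco", seed,
                         iters=0)

    rng = np.random.default_rng(seed)
    tau = np.full(L, float(tau0))
    eta = np.maximum(ev.pic, 1e-6)
    best: PanelSolution | None = None

    for it in range(1, iterations + 1):
        iter_best: PanelSolution | None = None
        for _ in range(ants):
            chosen: list[int] = []
            avail = np.ones(L, dtype=bool)
            while True:
                w = np.where(avail, tau ** alpha * eta ** beta, 0.0)
                tot = w.sum()
                if tot <= 0:
                    break
                pick = int(rng.choice(L, p=w / tot))
                chosen.append(pick)
                avail[pick] = False
                if ev.pct(frozenset(chosen)) >= target - 1e-9:
                    break
            if ev.pct(frozenset(chosen)) < target - 1e-9:
                continue
            # greedy prune: drop loci that keep the panel feasible
            for i in sorted(chosen, key=lambda i: ev.pic[i]):
                trial = [x for x in chosen if x != i]
                if trial and ev.pct(frozenset(trial)) >= target - 1e-9:
                    chosen = trial
            sol = _solution(ev, chosen, target, True, "aco", seed, it)
            if iter_best is None or sol.objective() < iter_best.objective():
                iter_best = sol
        tau *= (1.0 - rho)
        if iter_best is not None:
            deposit = 1.0 / iter_best.size + 0.1 * iter_best.mean_pic
            for name in iter_best.loci:
                tau[ev.names.index(name)] += deposit
            if best is None or iter_best.objective() < best.objective():
                best = iter_best
                best.iterations_used = it
        tau = np.clip(tau, 1e-6, 1e6)
    assert best is not None  # full panel is feasible, so some ant succeeds
    return best


def evaluate_panel(t: GenotypeTable, loci: list[str],
                   group: str = "all") -> PanelSolution:
    """Diagnostics for a fixed panel (no search): mean PIC, percent
    distinguished and combined identification statistics."""
    if not loci:
        raise ValueError("empty panel")
    idx = [t.locus_index(l) for l in loci]  # raises KeyError on unknown locus
    ev = _PanelEvaluator(t)
    sol = _solution(ev, idx, 0.0, True, "evaluate")
    f = allele_frequencies(t, "pooled")
    stats = per_locus_id_stats(f, "all")
    sol.combined = combine_panel(stats, loci)
    sol.feasible = True
    return sol
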
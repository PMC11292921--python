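"""One-command orchestration of the full breed-panel analysis.

``run_full_pipeline`` chains diversity -> structure -> identification ->
panel selection (-> D-loop when an alignment is supplied), writes one TSV per
statistic family plus a JSON summary, and renders a small markdown report.
``make_fixture`` writes a study-shaped synthetic dataset (five populations of
59/29/41/37/18 diploids, 15 dinucleotide loci, and a 423-bp alignment with 14
haplotypes) for demos and smoke tests.  Everything is deterministic under the
configured seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import dloop as dl
from . import forensic_id as fid
from . import panel_aco as pa
from . import structure as st
from .geno_core import (GenotypeTable, DloopAlignment, allele_frequencies,
                        read_fasta_alignment, read_genepop, read_genotype_csv,
                        read_locus_meta_yaml, write_fasta_alignment,
                        write_genepop, write_genotype_csv,
                        write_locus_meta_yaml, write_tables)
from .synthetic_data import SimConfig, simulate_dloop_alignment, simulate_populations

log = logging.getLogger("pawprint")

__all__ = ["PipelineConfig", "run_full_pipeline", "make_fixture", "load_config"]


@dataclass
class PipelineConfig:
    genotypes: str | Path | None = None
    locus_meta: str | Path | None = None
    fasta: str | Path | None = None
    grouping: str = "breed"
    seed: int = 1
    out_dir: str | Path = "pawprint_out"
    hwe_reps: int = 10_000
    n_perm: int = 110
    n_boot: int = 200
    accumulation_reps: int = 200
    aco_error_threshold: float = 5.0
    aco_ants: int = 30
    aco_iterations: int = 60
    run_structure: bool = True
    run_ident: bool = True
    run_panel: bool = True

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return PipelineConfig(**data)


load_config = PipelineConfig.from_yaml


def _read_genotypes(cfg: PipelineConfig) -> GenotypeTable:
    meta = read_locus_meta_yaml(cfg.locus_meta) if cfg.locus_meta else None
    path = Path(cfg.genotypes)
    if path.suffix.lower() in (".gen", ".genepop", ".txt"):
        return read_genepop(path, meta)
    return read_genotype_csv(path, meta)


def run_full_pipeline(cfg: PipelineConfig,
                      table: GenotypeTable | None = None,
                      alignment: DloopAlignment | None = None) -> dict:
    """Run every configured stage and write the report bundle.

    ``table``/``alignment`` may be passed directly (bypassing file input).
    Returns a dict with the in-memory results and the list of written files.
    Any stage failure aborts with the stage name in the log record.
    """
    t0 = time.time()
    out_dir = Path(cfg.out_dir)
    rng_seed = int(cfg.seed)
    if table is None:
        if cfg.genotypes is None:
            raise ValueError("no genotype input configured")
        table = _read_genotypes(cfg)
    if alignment is None and cfg.fasta:
        alignment = read_fasta_alignment(cfg.fasta)

    results: dict = {}
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"seed": rng_seed, "grouping": cfg.grouping,
                     "n_samples": table.n_samples, "n_loci": table.n_loci,
                     "parameters": {
                         "hwe_reps": cfg.hwe_reps, "n_perm": cfg.n_perm,
                         "n_boot": cfg.n_boot,
                         "accumulation_reps": cfg.accumulation_reps,
                         "aco_error_threshold": cfg.aco_error_threshold,
                         "aco_ants": cfg.aco_ants,
                         "aco_iterations": cfg.aco_iterations}}

    def stage(name: str, fn):
        t = time.time()
        try:
            value = fn()
        except Exception:
            log.exception("stage %s failed", name)
            raise
        log.info("stage %s done in %.2fs", name, time.time() - t)
        return value

    # diversity ------------------------------------------------------------
    def _diversity():
        summaries = dv.locus_summary(table, cfg.grouping, hwe_reps=cfg.hwe_reps,
                                     seed=rng_seed)
        frame = dv.locus_summary_frame(summaries)
        ho = frame.groupby("locus")["ho"].mean().to_numpy()
        he = frame.groupby("locus")["he"].mean().to_numpy()
        tstat, df, pval = dv.welch_ho_he(ho, he)
        return frame, {"welch_t": tstat, "welch_df": df, "welch_p": pval}

    frame, welch = stage("diversity", _diversity)
    tables["locus_summary"] = frame
    summary["diversity"] = {
        "mean_he": float(frame["he"].mean()),
        "mean_ho": float(frame["ho"].mean()),
        "mean_na": float(frame["na"].mean()),
        "mean_ar": float(frame["ar_g"].mean()),
        "mean_pic": float(frame["pic"].mean()), **welch}
    results["locus_summary"] = frame

    # structure ------------------------------------------------------------
    if cfg.run_structure and len(table.groups(cfg.grouping)) >= 2:
        def _structure():
            fst = st.pairwise_fst(table, cfg.grouping, n_perm=cfg.n_perm,
                                  seed=rng_seed)
            rst = st.pairwise_rst(table, cfg.grouping)
            nei = st.nei_distance_matrix(table, cfg.grouping)
            am = st.amova(table, cfg.grouping)
            fis = st.fis_with_ci(table, cfg.grouping, n_boot=cfg.n_boot,
                                 seed=rng_seed)
            rel = st.pairwise_relatedness(table)
            rel_means = st.relatedness_group_means(rel, table, cfg.grouping)
            return fst, rst, nei, am, fis, rel_means

        fst, rst, nei, am, fis, rel_means = stage("structure", _structure)
        tables["pairwise_fst"] = fst.frame().reset_index(names="group")
        tables["pairwise_rst"] = rst.frame().reset_index(names="group")
        tables["nei_distance"] = nei.frame().reset_index(names="group")
        tables["relatedness_groups"] = rel_means
        tables["individual_fis"] = fis["per_individual"]
        summary["structure"] = {
            "fst_overall": st.weir_cockerham_theta(table, cfg.grouping),
            "fis": fis["fis"], "fis_ci": [fis["ci_low"], fis["ci_high"]],
            "amova_pct_among_pops": am.pct_among_pops,
            "amova_pct_among_ind": am.pct_among_ind,
            "amova_pct_within_ind": am.pct_within_ind,
            "amova_phi_st": am.phi_st}
        results.update(fst=fst, rst=rst, nei=nei, amova=am, fis=fis)

    # identification -------------------------------------------------------
    if cfg.run_ident:
        def _ident():
            f = allele_frequencies(table, "pooled")
            stats = fid.per_locus_id_stats(f, "all")
            combined = fid.combine_panel(stats)
            curve = fid.genotype_accumulation(table, reps=cfg.accumulation_reps,
                                              seed=rng_seed)
            he = {l: 1.0 - float((f.vector(l, "all") ** 2).sum())
                  for l in table.locus_names}
            sibs_desc = fid.pid_sibs_locus_curve(stats, he, "descending")
            sibs_asc = fid.pid_sibs_locus_curve(stats, he, "ascending")
            matches = fid.match_report(table)
            return stats, combined, curve, sibs_desc, sibs_asc, matches

        stats, combined, curve, sibs_desc, sibs_asc, matches = stage(
            "forensic_id", _ident)
        tables["id_stats"] = pd.concat(
            [fid.id_stats_frame(stats), fid.id_stats_frame([combined])],
            ignore_index=True)
        tables["genotype_accumulation"] = curve.frame()
        tables["matches"] = matches
        summary["forensic_id"] = {
            "combined_pid_theoretical": combined.pid_theoretical,
            "combined_pid_unbiased": combined.pid_unbiased,
            "combined_pid_sibs": combined.pid_sibs,
            "combined_pe": combined.pe,
            "n_matching_pairs": int(len(matches)),
            "loci_for_sibs_0.01_high_he": sibs_desc["loci_needed"][0.01],
            "loci_for_sibs_0.01_low_he": sibs_asc["loci_needed"][0.01]}
        results.update(id_stats=stats, id_combined=combined,
                       accumulation=curve)

    # panel selection ------------------------------------------------------
    if cfg.run_panel:
        def _panel():
            return pa.aco_select_panel(
                table, error_threshold=cfg.aco_error_threshold,
                ants=cfg.aco_ants, iterations=cfg.aco_iterations,
                seed=rng_seed)

        panel = stage("panel_aco", _panel)
        summary["panel"] = {"loci": panel.loci, "size": panel.size,
                            "mean_pic": panel.mean_pic,
                            "percent_distinguished": panel.percent_distinguished,
                            "feasible": panel.feasible}
        results["panel"] = panel

    # D-loop ---------------------------------------------------------------
    if alignment is not None:
        def _dloop():
            ht = dl.collapse_haplotypes(alignment)
            div = dl.diversity_stats(ht)
            diff = (dl.differentiation(ht)
                    if len(ht.populations) >= 2 else [])
            neut = dl.neutrality_tests(ht)
            mism = dl.mismatch_distribution(ht)
            return ht, div, diff, neut, mism

        ht, div, diff, neut, mism = stage("dloop", _dloop)
        tables["dloop_diversity"] = pd.DataFrame([vars(d) for d in div])
        if diff:
            tables["dloop_differentiation"] = pd.DataFrame(
                [vars(d) for d in diff])
        tables["dloop_neutrality"] = pd.DataFrame([vars(n) for n in neut])
        tables["dloop_mismatch"] = mism.frame()
        summary["dloop"] = {
            "n_haplotypes_total": len(ht.haplotypes),
            "aligned_length": ht.length, "segregating_sites": ht.s_sites,
            "raggedness": mism.raggedness}
        results.update(haplotypes=ht, dloop_diversity=div,
                       dloop_differentiation=diff, dloop_neutrality=neut,
                       mismatch=mism)

    files = write_tables(tables, out_dir, summary)
    report = _render_report(summary)
    (out_dir / "report.md").write_text(report)
    files.append(out_dir / "report.md")
    summary["wall_time_s"] = round(time.time() - t0, 2)
    results["summary"] = summary
    results["files"] = files
    return results


def _render_report(summary: dict) -> str:
    lines = ["# pawprint analysis report", "",
             f"Seed: {summary['seed']}; grouping: {summary['grouping']}; "
             f"{summary['n_samples']} samples x {summary['n_loci']} loci.", ""]
    d = summary.get("diversity", {})
    if d:
        lines += ["## Diversity (Na / AR / He / Ho / PIC)", "",
                  f"- mean Na = {d['mean_na']:.3f}, mean AR = {d['mean_ar']:.3f}",
                  f"- mean He = {d['mean_he']:.3f}, mean Ho = {d['mean_ho']:.3f}, "
                  f"mean PIC = {d['mean_pic']:.3f}",
                  f"- Welch t (Ho vs He) = {d['welch_t']:.3f}, "
                  f"p = {d['welch_p']:.3g}", ""]
    s = summary.get("structure", {})
    if s:
        lines += ["## Structure (FST / FIS / AMOVA)", "",
                  f"- overall Weir-Cockerham FST = {s['fst_overall']:.4f}",
                  f"- FIS = {s['fis']:.4f} "
                  f"(95% CI {s['fis_ci'][0]:.4f}..{s['fis_ci'][1]:.4f})",
                  f"- AMOVA: {s['amova_pct_among_pops']:.1f}% among populations, "
                  f"{s['amova_pct_among_ind']:.1f}% among individuals, "
                  f"{s['amova_pct_within_ind']:.1f}% within individuals", ""]
    f = summary.get("forensic_id", {})
    if f:
        lines += ["## Identification (MP / P(ID) / PE)", "",
                  f"- combined P(ID)theoretical = {f['combined_pid_theoretical']:.3g}",
                  f"- combined P(ID)unbiased = {f['combined_pid_unbiased']:.3g}",
                  f"- combined P(ID)sibs = {f['combined_pid_sibs']:.3g}",
                  f"- combined PE = {f['combined_pe']:.6f}", ""]
    p = summary.get("panel", {})
    if p:
        lines += ["## Marker panel (ACO)", "",
                  f"- selected {p['size']} loci: {', '.join(sorted(p['loci']))}",
                  f"- mean PIC = {p['mean_pic']:.3f}, "
                  f"distinguishes {p['percent_distinguished']:.2f}% of individuals", ""]
    dd = summary.get("dloop", {})
    if dd:
        lines += ["## mtDNA D-loop", "",
                  f"- {dd['n_haplotypes_total']} haplotypes over "
                  f"{dd['aligned_length']} retained sites "
                  f"({dd['segregating_sites']} segregating)",
                  f"- raggedness index = {dd['raggedness']:.4f}", ""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def make_fixture(out_dir: str | Path, seed: int = 1) -> dict[str, Path]:
    """Write a study-shaped synthetic dataset bundle.

    Five populations of 59/29/41/37/18 diploids, 15 dinucleotide loci, plus a
    423-bp alignment sampling 14 haplotypes across the populations.  Writes
    GenePop, wide CSV, locus metadata YAML, FASTA, a truth JSON, and a
    ready-to-run pipeline config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed)
    table, truth = simulate_populations(cfg)

    rng = np.random.default_rng(seed + 1)
    n_h = 14
    freqs = {}
    for pop, n in zip(table.groups("breed"), cfg.n_per_pop):
        w = rng.dirichlet(np.full(n_h, 0.35))
        counts = np.zeros(n_h, dtype=int)
        picks = rng.choice(n_h, size=n, p=w)
        for p_ in picks:
            counts[p_] += 1
        freqs[pop] = counts / n
    aln = simulate_dloop_alignment(
        n_h, freqs, length=423, sites_per_haplotype=3, seed=seed + 2,
        n_per_pop=dict(zip(table.groups("breed"), cfg.n_per_pop)))

    paths = {
        "genepop": out_dir / "genotypes.gen",
        "csv": out_dir / "genotypes.csv",
        "loci": out_dir / "loci.yaml",
        "fasta": out_dir / "dloop.fasta",
        "truth": out_dir / "truth.json",
        "config": out_dir / "config.yaml",
    }
    write_genepop(table, paths["genepop"])
    write_genotype_csv(table, paths["csv"])
    write_locus_meta_yaml(table.loci, paths["loci"])
    write_fasta_alignment(aln, paths["fasta"])
    paths["truth"].write_text(json.dumps(truth.as_dict(), indent=2) + "\n")
    paths["config"].write_text(yaml.safe_dump({
        "genotypes": str(paths["csv"]), "locus_meta": str(paths["loci"]),
        "fasta": str(paths["fasta"]), "grouping": "breed", "seed": seed,
        "out_dir": str(out_dir / "results")}, sort_keys=False))
    return paths
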
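"""Core domain types and file I/O for microsatellite genotypes and D-loop alignments.

The central container is :class:`GenotypeTable`: diploid multilocus genotypes
(allele fragment sizes in base pairs) for samples carrying a breed/population
label, a locality label and a sex flag.  Alleles are stored as positive
integers; a genotype is MISSING when either allele is 0.  Allele pairs are kept
in canonical ascending order so heterozygote identity is order-free.

Supported formats:

* GenePop 4.x dialect (title line, locus names, ``POP`` blocks, 2/3-digit
  allele codes, ``000``/``0000`` = missing).  GenePop carries no population
  names or per-sample metadata, so populations are named ``P1..Pk`` in file
  order and locality/sex default to ``""``/``"U"``.
* CSV, wide (``sample,pop,locality,sex,<locus>.a1,<locus>.a2``) or long
  (``sample,pop,locus,a1,a2`` with optional ``locality``/``sex`` columns).
  The wide dialect round-trips the full table.
* FASTA for pre-aligned D-loop haplotype sequences.  The population label is
  taken from a ``pop=<label>`` token in the header if present, otherwise from
  the second whitespace-separated header token.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = 0

__all__ = [
    "MISSING",
    "LocusMeta",
    "Sample",
    "GenotypeTable",
    "AlleleFreqTable",
    "DloopAlignment",
    "GenoParseError",
    "AlignmentError",
    "read_genepop",
    "write_genepop",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_locus_meta_yaml",
    "write_locus_meta_yaml",
    "write_tables",
]


class GenoParseError(ValueError):
    """Raised on malformed genotype input; message names the offending line/row."""


class AlignmentError(ValueError):
    """Raised on inconsistent sequence alignments."""


@dataclass(frozen=True)
class LocusMeta:
    """Metadata for one microsatellite locus.

    Parameters
    ----------
    name:
        Locus name, unique within a panel (e.g. ``FCA726``).
    repeat_unit_bp:
        Length of the tandem-repeat unit in bp (1-6; dinucleotide = 2).
        Needed by allele-size based statistics (RST, M-ratio).
    size_range:
        Optional (min, max) expected fragment size in bp.
    """

    name: str
    repeat_unit_bp: int = 2
    size_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("locus name must be non-empty")
        if not (1 <= int(self.repeat_unit_bp) <= 6):
            raise ValueError(f"repeat_unit_bp must be in 1..6, got {self.repeat_unit_bp}")


@dataclass(frozen=True)
class Sample:
    """One sampled individual: id, breed/population, locality, sex flag."""

    id: str
    population: str
    locality: str = ""
    sex: str = "U"


class GenotypeTable:
    """Rectangular diploid genotype table (samples x loci x 2 alleles).

    ``calls`` has shape ``(n_samples, n_loci, 2)`` with integer allele sizes in
    bp; 0 marks a missing allele.  A genotype is treated as missing when either
    allele is 0, and is then stored as (0, 0).  Pairs are canonicalised to
    ascending order.
    """

    def __init__(self, samples: Sequence[Sample], loci: Sequence[LocusMeta],
                 calls: np.ndarray) -> None:
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(samples), len(loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(samples)}, {len(loci)}, 2)")
        if (calls < 0).any():
            raise ValueError("allele sizes must be non-negative integers")
        names = [l.name for l in loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        # canonicalise: missing -> (0,0); pairs ascending
        calls = np.sort(calls, axis=2)
        half_missing = (calls == MISSING).any(axis=2)
        calls[half_missing] = MISSING
        self.samples = list(samples)
        self.loci = list(loci)
        self.calls = calls

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def locus_index(self, name: str) -> int:
        try:
            return self.locus_names.index(name)
        except ValueError:
            raise KeyError(f"unknown locus {name!r}") from None

    def group_labels(self, grouping: str = "breed") -> list[str]:
        """Per-sample group label under the chosen grouping.

        ``"breed"`` uses the population field, ``"locality"`` the locality
        field, ``"pooled"`` assigns every sample to a single group ``"all"``.
        """
        if grouping in ("breed", "pop", "population"):
            return [s.population for s in self.samples]
        if grouping == "locality":
            return [s.locality for s in self.samples]
        if grouping == "pooled":
            return ["all"] * self.n_samples
        raise ValueError(f"unknown grouping {grouping!r}")

    def groups(self, grouping: str = "breed") -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.group_labels(grouping):
            seen.setdefault(g)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci) mask of missing genotypes."""
        return (self.calls == MISSING).all(axis=2)

    def subset_loci(self, names: Sequence[str]) -> "GenotypeTable":
        idx = [self.locus_index(n) for n in names]
        return GenotypeTable(self.samples, [self.loci[i] for i in idx],
                             self.calls[:, idx, :])

    def subset_samples(self, keep: Sequence[int]) -> "GenotypeTable":
        keep = list(keep)
        return GenotypeTable([self.samples[i] for i in keep], self.loci,
                             self.calls[keep])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (self.samples == other.samples and self.loci == other.loci
                and np.array_equal(self.calls, other.calls))

    def __repr__(self) -> str:
        return (f"<GenotypeTable {self.n_samples} samples x {self.n_loci} loci, "
                f"{len(self.groups())} populations>")


class AlleleFreqTable:
    """Relative allele frequencies per locus x group.

    ``freqs[(locus, group)]`` maps allele size -> relative frequency computed
    over the ``2 * n_typed`` gene copies at that locus in that group;
    ``n_typed[(locus, group)]`` counts non-missing diploid genotypes.  Entries
    for groups with no typed genotypes at a locus are absent.
    """

    def __init__(self, loci: Sequence[str], groups: Sequence[str],
                 freqs: Mapping[tuple[str, str], Mapping[int, float]],
                 n_typed: Mapping[tuple[str, str], int]) -> None:
        self.loci = list(loci)
        self.groups = list(groups)
        self.freqs = {k: dict(v) for k, v in freqs.items()}
        self.n_typed = dict(n_typed)
        for key, f in self.freqs.items():
            if not f:
                continue
            tot = sum(f.values())
            if abs(tot - 1.0) > 1e-12:
                raise ValueError(f"frequencies at {key} sum to {tot}, not 1")
            if any(not (0.0 < p <= 1.0) for p in f.values()):
                raise ValueError(f"frequencies at {key} outside (0, 1]")

    def get(self, locus: str, group: str) -> dict[int, float]:
        return self.freqs.get((locus, group), {})

    def vector(self, locus: str, group: str) -> np.ndarray:
        """Frequency vector (arbitrary but stable allele order)."""
        f = self.get(locus, group)
        return np.array([f[a] for a in sorted(f)], dtype=float)


@dataclass
class DloopAlignment:
    """Equal-length haplotype alignment with per-sequence population labels.

    ``records`` is a list of ``(sequence id, population label, sequence)``
    with sequences over ``{A, C, G, T, N, -}`` (uppercase).
    """

    records: list[tuple[str, str, str]]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(seq) for _, _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        ids = [rid for rid, _, _ in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sequence ids")
        self.records = [(rid, pop, seq.upper()) for rid, pop, seq in self.records]
        bad = set("".join(s for _, _, s in self.records)) - set("ACGTN-")
        if bad:
            raise AlignmentError(f"illegal alignment characters: {sorted(bad)}")
        self.length = lengths.pop()

    @property
    def n(self) -> int:
        return len(self.records)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, pop, _ in self.records:
            seen.setdefault(pop)
        return list(seen)

    def matrix(self) -> np.ndarray:
        """Alignment as a (n, length) array of single characters."""
        return np.array([list(seq) for _, _, seq in self.records], dtype="U1")


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def _split_genepop_code(code: str, line_no: int) -> tuple[int, int]:
    code = code.strip()
    if len(code) == 4:
        w = 2
    elif len(code) == 6:
        w = 3
    elif len(code) == 8:
        w = 4
    else:
        raise GenoParseError(
            f"line {line_no}: allele code {code!r} is not 2x2, 2x3 or 2x4 digits")
    if not code.isdigit():
        raise GenoParseError(f"line {line_no}: non-numeric allele code {code!r}")
    return int(code[:w]), int(code[w:])


def read_genepop(path: str | Path,
                 locus_meta: Sequence[LocusMeta] | None = None) -> GenotypeTable:
    """Read a GenePop (4.x dialect) file into a :class:`GenotypeTable`.

    Allele codes are interpreted as fragment sizes in bp exactly as written
    (no offset).  ``000``/``0000`` alleles mark missing data.  Populations are
    named ``P1..Pk`` in file order.  If ``locus_meta`` is given it must match
    the file's locus names in order and supplies repeat-unit metadata.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GenoParseError("file too short to be GenePop")
    # locus names: either one per line until first POP, or comma-separated
    pop_re = re.compile(r"^\s*pop\s*$", re.IGNORECASE)
    i = 1
    locus_names: list[str] = []
    while i < len(lines) and not pop_re.match(lines[i]):
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        locus_names.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenoParseError("no POP block found")
    if locus_meta is not None:
        if [m.name for m in locus_meta] != locus_names:
            raise GenoParseError("locus_meta names do not match file locus names")
        loci = list(locus_meta)
    else:
        loci = [LocusMeta(n) for n in locus_names]

    samples: list[Sample] = []
    rows: list[list[tuple[int, int]]] = []
    pop_idx = 0
    for line_no in range(i, len(lines)):
        line = lines[line_no]
        if not line.strip():
            continue
        if pop_re.match(line):
            pop_idx += 1
            continue
        if "," not in line:
            raise GenoParseError(f"line {line_no + 1}: expected 'id , genotypes'")
        sid, geno = line.split(",", 1)
        codes = geno.split()
        if len(codes) != len(loci):
            raise GenoParseError(
                f"line {line_no + 1}: {len(codes)} genotype fields for "
                f"{len(loci)} loci")
        pair_row = [_split_genepop_code(c, line_no + 1) for c in codes]
        samples.append(Sample(id=sid.strip(), population=f"P{pop_idx}"))
        rows.append(pair_row)
    if not samples:
        raise GenoParseError("no samples found")
    calls = np.array(rows, dtype=np.int64)
    return GenotypeTable(samples, loci, calls)


def write_genepop(t: GenotypeTable, path: str | Path, title: str = "pawprint export") -> None:
    """Write a GenotypeTable as GenePop; allele width picked from max size."""
    path = Path(path)
    width = 2 if int(t.calls.max(initial=0)) < 100 else (
        3 if int(t.calls.max(initial=0)) < 1000 else 4)
    out = [title]
    out.extend(t.locus_names)
    labels = t.group_labels("breed")
    prev = None
    for s, lab, row in zip(t.samples, labels, t.calls):
        if lab != prev:
            out.append("POP")
            prev = lab
        codes = " ".join(f"{a:0{width}d}{b:0{width}d}" for a, b in row)
        out.append(f"{s.id} , {codes}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def _int_allele(v, where: str) -> int:
    if pd.isna(v) or v == "":
        return MISSING
    try:
        iv = int(v)
    except (TypeError, ValueError):
        raise GenoParseError(f"{where}: allele value {v!r} is not an integer")
    if iv < 0:
        raise GenoParseError(f"{where}: negative allele size {iv}")
    return iv


def read_genotype_csv(path: str | Path,
                      locus_meta: Sequence[LocusMeta] | None = None) -> GenotypeTable:
    """Read a wide or long genotype CSV (dialect auto-detected from columns)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    cols = set(df.columns)
    if {"sample", "pop", "locus", "a1", "a2"} <= cols:
        return _from_long_df(df, locus_meta)
    if {"sample", "pop"} <= cols and any(c.endswith(".a1") for c in df.columns):
        return _from_wide_df(df, locus_meta)
    raise GenoParseError(
        "unrecognised CSV layout: need long columns sample,pop,locus,a1,a2 "
        "or wide columns sample,pop[,locality,sex],<locus>.a1,<locus>.a2")


def _meta_map(locus_meta: Sequence[LocusMeta] | None) -> dict[str, LocusMeta]:
    return {m.name: m for m in locus_meta} if locus_meta else {}


def _from_wide_df(df: pd.DataFrame,
                  locus_meta: Sequence[LocusMeta] | None) -> GenotypeTable:
    meta = _meta_map(locus_meta)
    locus_names = [c[:-3] for c in df.columns if c.endswith(".a1")]
    for ln in locus_names:
        if f"{ln}.a2" not in df.columns:
            raise GenoParseError(f"wide CSV: column {ln}.a2 missing")
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise GenoParseError(f"duplicate sample id {dup!r}")
    samples = [
        Sample(id=str(r["sample"]), population=str(r["pop"]),
               locality=str(r["locality"]) if "locality" in df.columns and not pd.isna(r.get("locality")) else "",
               sex=str(r["sex"]) if "sex" in df.columns and not pd.isna(r.get("sex")) else "U")
        for _, r in df.iterrows()
    ]
    calls = np.zeros((len(df), len(locus_names), 2), dtype=np.int64)
    for j, ln in enumerate(locus_names):
        for i, (_, r) in enumerate(df.iterrows()):
            where = f"row {i + 2} locus {ln}"
            calls[i, j] = (_int_allele(r[f"{ln}.a1"], where),
                           _int_allele(r[f"{ln}.a2"], where))
    loci = [meta.get(n, LocusMeta(n)) for n in locus_names]
    return GenotypeTable(samples, loci, calls)


def _from_long_df(df: pd.DataFrame,
                  locus_meta: Sequence[LocusMeta] | None) -> GenotypeTable:
    meta = _meta_map(locus_meta)
    if df.duplicated(subset=["sample", "locus"]).any():
        row = df[df.duplicated(subset=["sample", "locus"])].iloc[0]
        raise GenoParseError(
            f"duplicate sample x locus rows for {row['sample']!r} / {row['locus']!r}")
    sample_order: dict[str, int] = {}
    locus_order: dict[str, int] = {}
    for s in df["sample"]:
        sample_order.setdefault(str(s), len(sample_order))
    for l in df["locus"]:
        locus_order.setdefault(str(l), len(locus_order))
    info: dict[str, Sample] = {}
    calls = np.zeros((len(sample_order), len(locus_order), 2), dtype=np.int64)
    for i, (_, r) in enumerate(df.iterrows()):
        sid = str(r["sample"])
        info.setdefault(sid, Sample(
            id=sid, population=str(r["pop"]),
            locality=str(r["locality"]) if "locality" in df.columns and not pd.isna(r.get("locality")) else "",
            sex=str(r["sex"]) if "sex" in df.columns and not pd.isna(r.get("sex")) else "U"))
        si, li = sample_order[sid], locus_order[str(r["locus"])]
        where = f"row {i + 2}"
        calls[si, li] = (_int_allele(r["a1"], where), _int_allele(r["a2"], where))
    samples = [info[s] for s in sample_order]
    loci = [meta.get(n, LocusMeta(n)) for n in locus_order]
    return GenotypeTable(samples, loci, calls)


def write_genotype_csv(t: GenotypeTable, path: str | Path, dialect: str = "wide") -> None:
    """Write a GenotypeTable as CSV (``wide`` round-trips all metadata)."""
    path = Path(path)
    if dialect == "wide":
        data: dict[str, list] = {
            "sample": [s.id for s in t.samples],
            "pop": [s.population for s in t.samples],
            "locality": [s.locality for s in t.samples],
            "sex": [s.sex for s in t.samples],
        }
        for j, ln in enumerate(t.locus_names):
            data[f"{ln}.a1"] = t.calls[:, j, 0].tolist()
            data[f"{ln}.a2"] = t.calls[:, j, 1].tolist()
        pd.DataFrame(data).to_csv(path, index=False)
    elif dialect == "long":
        rows = []
        for s, row in zip(t.samples, t.calls):
            for ln, (a1, a2) in zip(t.locus_names, row):
                rows.append((s.id, s.population, s.locality, s.sex, ln, a1, a2))
        pd.DataFrame(rows, columns=["sample", "pop", "locality", "sex",
                                    "locus", "a1", "a2"]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# FASTA alignment
# ---------------------------------------------------------------------------

def read_fasta_alignment(path: str | Path) -> DloopAlignment:
    """Read a pre-aligned FASTA into a :class:`DloopAlignment`.

    Population label convention: a ``pop=<label>`` token anywhere in the
    header wins; otherwise the second whitespace token of the description;
    otherwise ``""``.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        pop = ""
        tokens = rec.description.split()
        for tok in tokens:
            if tok.startswith("pop="):
                pop = tok[4:]
                break
        else:
            if len(tokens) >= 2:
                pop = tokens[1]
        records.append((rec.id, pop, str(rec.seq).upper()))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return DloopAlignment(records)


def write_fasta_alignment(a: DloopAlignment, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description=f"pop={pop}")
            for rid, pop, seq in a.records]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Locus metadata YAML
# ---------------------------------------------------------------------------

def read_locus_meta_yaml(path: str | Path) -> list[LocusMeta]:
    """YAML list of ``{name, repeat_unit_bp[, size_range]}`` mappings."""
    items = yaml.safe_load(Path(path).read_text())
    out = []
    for it in items:
        rng = tuple(it["size_range"]) if it.get("size_range") else None
        out.append(LocusMeta(name=str(it["name"]),
                             repeat_unit_bp=int(it.get("repeat_unit_bp", 2)),
                             size_range=rng))
    return out


def write_locus_meta_yaml(loci: Sequence[LocusMeta], path: str | Path) -> None:
    items = []
    for m in loci:
        d: dict = {"name": m.name, "repeat_unit_bp": m.repeat_unit_bp}
        if m.size_range:
            d["size_range"] = list(m.size_range)
        items.append(d)
    Path(path).write_text(yaml.safe_dump(items, sort_keys=False))


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------

def write_tables(results: Mapping[str, pd.DataFrame], out_dir: str | Path,
                 summary: Mapping | None = None) -> list[Path]:
    """Write one TSV per statistic family plus a JSON summary.

    ``results`` maps a family name (e.g. ``locus_summary``) to a DataFrame;
    each becomes ``<name>.tsv`` with stable column order.  ``summary`` (scalar
    metadata, parameters, seeds) is written to ``summary.json``.  Deterministic
    given inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)
    p = out_dir / "summary.json"
    p.write_text(json.dumps(_jsonable(summary or {}), indent=2, sort_keys=True) + "\n")
    written.append(p)
    return written


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


# ---------------------------------------------------------------------------
# Allele frequencies (shared by every statistics module)
# ---------------------------------------------------------------------------

def allele_frequencies(t: GenotypeTable, grouping: str = "breed") -> AlleleFreqTable:
    """Relative allele frequencies per locus x group with pairwise deletion.

    Missing genotypes are excluded locus-wise; ``p_i = count_i / (2 n_typed)``.
    Groups with no typed genotype at a locus get no entry (flagged absent).
    """
    if t.n_samples == 0:
        raise ValueError("empty genotype table")
    labels = np.array(t.group_labels(grouping))
    groups = t.groups(grouping)
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    n_typed: dict[tuple[str, str], int] = {}
    miss = t.missing_mask()
    for g in groups:
        in_g = labels == g
        for j, ln in enumerate(t.locus_names):
            ok = in_g & ~miss[:, j]
            n = int(ok.sum())
            if n == 0:
                continue
            alleles = t.calls[ok, j, :].ravel()
            vals, counts = np.unique(alleles, return_counts=True)
            total = counts.sum()
            freqs[(ln, g)] = {int(v): c / total for v, c in zip(vals, counts)}
            n_typed[(ln, g)] = n
    return AlleleFreqTable(t.locus_names, groups, freqs, n_typed)
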
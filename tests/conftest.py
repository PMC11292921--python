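import numpy as np
import pytest

from pawprint.geno_core import (AlleleFreqTable, GenotypeTable, LocusMeta,
                                Sample)


def make_table(genos, pops, loci=None, localities=None):
    """Build a GenotypeTable from a nested list of (a1, a2) pairs.

    ``genos[i][j]`` is the genotype of sample i at locus j.
    """
    n = len(genos)
    l = len(genos[0])
    if loci is None:
        loci = [LocusMeta(f"L{j + 1}", repeat_unit_bp=2) for j in range(l)]
    samples = [Sample(id=f"S{i + 1}", population=pops[i],
                      locality=localities[i] if localities else "")
               for i in range(n)]
    calls = np.array(genos, dtype=np.int64)
    return GenotypeTable(samples, loci, calls)


@pytest.fixture
def two_pop_table():
    """Two populations x two loci, one missing genotype."""
    genos = [
        [(100, 102), (200, 200)],
        [(100, 100), (200, 202)],
        [(102, 102), (0, 0)],
        [(100, 102), (202, 202)],
    ]
    return make_table(genos, ["A", "A", "B", "B"])


@pytest.fixture
def biallelic_freqs():
    """Single-locus p = (0.5, 0.5) frequency table (pooled group)."""
    return AlleleFreqTable(["L1"], ["all"],
                           {("L1", "all"): {100: 0.5, 102: 0.5}},
                           {("L1", "all"): 50})
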
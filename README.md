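# pawprint

Population-genetics toolkit for small managed animal populations genotyped at
microsatellite (SSR) panels and sequenced for the mtDNA control region
(D-loop). It was built around the analysis workflow used for domestic cat
breed studies — a few weakly differentiated breed populations, ~15
fragment-length loci, and a short maternally inherited haplotype alignment —
and is aimed at breeders, conservation geneticists and forensic labs who need
per-locus diversity summaries, parentage/identification power, and a minimal
marker panel.

## What it computes

**Per-locus diversity** (`pawprint.diversity`): allele frequencies, number of
alleles N<sub>a</sub>, effective alleles N<sub>ea</sub> = 1/Σp², rarefied
allelic richness AR (FSTAT rarefaction), Shannon's I = −Σp ln p, observed and
expected heterozygosity (H<sub>e</sub> = 1 − Σp², with the unbiased
2n/(2n−1) variant), polymorphic information content
PIC = 1 − Σp² − Σ<sub>i&lt;j</sub>2p<sub>i</sub>²p<sub>j</sub>², fixation index
F = 1 − H<sub>o</sub>/H<sub>e</sub>, an exact Hardy–Weinberg test (full
enumeration or conditional Monte Carlo), the Brookfield-1 null-allele
estimate r = (H<sub>e</sub> − H<sub>o</sub>)/(1 + H<sub>e</sub>), the
Garza–Williamson M-ratio (bottleneck flag at M &lt; 0.68), and a Welch t
comparison of H<sub>o</sub> vs H<sub>e</sub> across loci.

**Structure** (`pawprint.structure`): Queller–Goodnight pairwise relatedness,
Weir–Cockerham F<sub>IS</sub> (bootstrap CI over loci) and pairwise
F<sub>ST</sub> (θ) with permutation p-values, Slatkin R<sub>ST</sub>, Nei
(1972) standard distance D = −ln I, three-level codominant AMOVA (among
populations / among individuals / within individuals), and a permutation
G-test of genotypic linkage disequilibrium.

**Forensic identification** (`pawprint.forensic_id`): per-locus and combined
matching probability MP, probability of identity
P(ID) = 2(Σp²)² − Σp⁴ with its small-sample-unbiased and full-sib variants
(P(ID)sibs = 0.25 + 0.5Σp² + 0.5(Σp²)² − 0.25Σp⁴), the parent-pair exclusion
probability PE = 1 + 4a₄ − 4a₅ − 3a₆ − 8a₂² + 8a₂a₃ + 2a₃² (a<sub>k</sub> =
Σp<sup>k</sup>), genotype-accumulation curves, and He-ordered cumulative
P(ID)sibs curves.

**Panel selection** (`pawprint.panel_aco`): ant-colony optimisation of the
smallest locus panel that distinguishes ≥ 100 − e% of individuals (secondary
objective: mean PIC), with an exhaustive oracle for panels of up to 15 loci.

**mtDNA D-loop** (`pawprint.dloop`): haplotype collapsing, haplotype and
nucleotide diversity (h, π, θ<sub>S</sub>, k) with Nei's variances,
G<sub>ST</sub>/F<sub>ST</sub>/Φ<sub>ST</sub>/D<sub>xy</sub>/D<sub>a</sub>/N<sub>m</sub>
differentiation, Tajima's D, Fu & Li's D* and F*, Fu's F<sub>s</sub> (exact
Ewens recursion), and mismatch distributions with Harpending's raggedness
index.

**Synthetic data** (`pawprint.synthetic_data`): a Balding–Nichols-style
population simulator (Dirichlet ancestral frequencies, F<sub>ST</sub>-
parameterised drift, inbreeding, null alleles, missing data), Mendelian
pedigree simulation (trios and full-sib pairs), star-haplotype D-loop
sampling, and neutral constant-size coalescent alignments (msprime backend).

## Worked example

```bash
pawprint simulate --out-dir demo --seed 1     # study-shaped synthetic dataset
pawprint run --config demo/config.yaml       # full pipeline
cat demo/results/report.md
```

The report for seed 1 reads (abridged):

```
- mean Na = 5.293, mean AR = 4.860
- mean He = 0.634, mean Ho = 0.649, mean PIC = 0.585
- overall Weir-Cockerham FST = 0.0289
- AMOVA: 2.9% among populations, 0.3% among individuals, 96.8% within individuals
- combined P(ID)theoretical = 2.38e-13
- combined P(ID)sibs = 8.46e-06
- combined PE = 1.000000
- selected 3 loci: L02, L08, L10   (mean PIC = 0.822, 100.00% distinguished)
- 14 haplotypes over 423 retained sites (39 segregating)
```

Reading it: the five simulated breed populations are weakly differentiated
(F<sub>ST</sub> ≈ 0.03, almost all molecular variance within individuals), the
15-locus panel identifies individuals essentially perfectly (a random pair
shares a full genotype with probability ~10⁻¹³, and even full sibs only with
~10⁻⁵), parent-pair exclusion is complete, and the ant-colony search finds
that three highly informative loci already distinguish every individual in
this sample.

The same analyses run on real data: GenePop or CSV genotypes plus a FASTA
alignment (see `pawprint --help` for the `diversity`, `structure`, `ident`,
`panel` and `dloop` subcommands).

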
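# Methods

This note records the statistical conventions, estimators, and design choices
behind pawprint, in the spirit of the model documentation shipped with
mature population-genetics packages.

## Data model

Genotypes are diploid allele-size pairs (integer bp) per sample × locus,
stored in canonical ascending order; a genotype is missing when either allele
is 0, and every statistic uses pairwise (locus-wise) deletion. Each sample
carries two group labels — breed/population and locality — and every analysis
takes a grouping choice (`breed`, `locality`, or `pooled`), because studies of
managed breeds typically analyse both partitions. GenePop input carries no
metadata beyond POP blocks, so populations read from GenePop are named
`P1..Pk`; the wide CSV dialect round-trips everything.

## Diversity statistics

* H<sub>e</sub> = 1 − Σp² is reported alongside the unbiased
  (2n/(2n−1))·H<sub>e</sub>; published tables rarely say which convention they
  use, so both are emitted.
* Allelic richness uses FSTAT-style rarefaction,
  AR<sub>g</sub> = Σ<sub>alleles</sub> [1 − C(2n − N<sub>a</sub>, g)/C(2n, g)],
  with the default depth g = min over groups of 2·n_typed per locus.
* PIC follows Botstein: 1 − Σp² − Σ<sub>i&lt;j</sub> 2p<sub>i</sub>²p<sub>j</sub>²,
  computed via power sums (1 − a₂ − a₂² + a₄).
* F = 1 − H<sub>o</sub>/H<sub>e</sub> is emitted as NaN (never 0) for
  monomorphic loci; downstream means skip undefined values.
* The Hardy–Weinberg test is the exact conditional test on genotype
  configurations given allele counts (Levene's conditional distribution),
  with p = Σ P(config) over configurations no more probable than the observed
  one. Full enumeration is used when a combinatorial bound on the
  configuration space (compositions of n individuals over K(K+1)/2 genotype
  cells) stays below 10⁶; otherwise Monte Carlo, which samples the exact
  conditional distribution by randomly re-pairing the observed gene copies
  (vectorised; default 10⁵ draws, seeded). Monomorphic loci give p = 1.
* Null alleles: Brookfield-1, r = (H<sub>e</sub> − H<sub>o</sub>)/(1 + H<sub>e</sub>),
  truncated at 0; Chakraborty's (H<sub>e</sub> − H<sub>o</sub>)/(H<sub>e</sub> + H<sub>o</sub>)
  behind a flag. The estimator is deliberately simple — it is a screening
  statistic, not a genotyping-error model.
* M-ratio = k/(r + 1) with r the allele-size range in repeat units; the 0.68
  reference threshold flags candidate bottlenecks. Sizes off the repeat grid
  are rounded into units.
* The H<sub>o</sub>-vs-H<sub>e</sub> comparison is a Welch unequal-variance t
  on the two per-locus vectors treated as independent samples
  (Welch–Satterthwaite df). Raw HWE p-values are accompanied by a Holm
  column; no sequential-testing dashboard beyond that.

## Structure

* Relatedness: Queller–Goodnight, multilocus-weighted (sum numerators and
  denominators over loci, then divide) and symmetrised over the two
  directional forms. Reference frequencies default to the pooled sample;
  Lynch–Ritland is available behind a flag. The estimator is unbiased for
  unrelated pairs up to O(1/n) terms from estimating frequencies in-sample.
* F<sub>IS</sub>/F<sub>ST</sub>: Weir–Cockerham per-allele a/b/c variance
  components summed over alleles and loci. With a single group only b and c
  are defined, giving the within-population f. CIs for F<sub>IS</sub> come
  from a percentile bootstrap over loci (default 1000, seeded). Pairwise
  F<sub>ST</sub> p-values permute individuals between the two groups; the
  default of 110 permutations mirrors small published analyses, but ≥ 999 is
  recommended and configurable. Holm correction across pairs.
* Per-individual F<sub>IS</sub> is a documented proxy:
  1 − (observed heterozygote count)/(Σ per-locus H<sub>e</sub> over the
  individual's typed loci).
* R<sub>ST</sub>: allele sizes in repeat units; per-pair variance components
  (ANOVA on gene copies) give (S̄ − S<sub>w</sub>)/S̄ summed over loci.
* AMOVA: three-level codominant partition with the allele-mismatch metric
  (squared inter-copy distance 0/1, so individuals differ by their count of
  non-shared alleles). Sums of squares and df accumulate per locus with
  pairwise deletion; negative components are kept raw but truncated to 0 for
  percentage reporting, Arlequin-style.
* Genotypic LD: G statistic on the two-locus genotype contingency table; the
  null distribution comes from permuting one locus's genotypes among
  individuals (seeded). Calibration is checked empirically: on independent
  simulated loci the rejection rate at α = 0.05 is 5% ± 2% over 400 pairs.

## Identification and parentage

Per-locus statistics are polynomial functions of the allele-frequency power
sums a<sub>k</sub> = Σp<sup>k</sup>: P(ID) = 2a₂² − a₄, the
(n−1)(n−2)(n−3)-denominator unbiased variant (defined for n ≥ 4), the
full-sib variant, and the parent-pair exclusion probability
PE = 1 + 4a₄ − 4a₅ − 3a₆ − 8a₂² + 8a₂a₃ + 2a₃². PE's meaning is validated
empirically in the tests: the fraction of random unrelated pairs excluded as
joint parents of a random true offspring (one-allele-from-each-parent
compatibility) matches the polynomial within Monte Carlo error.

MP is reported as the per-locus random-match probability
Σ(genotype frequency)² — identical to P(ID) — because the literal product
over all genotype terms collapses toward 0 for any polymorphic locus and
cannot describe a per-locus match probability; the literal product is kept
behind `mp_formula="literal"` for auditability. Combined statistics multiply
across loci, except PE which combines as 1 − Π(1 − PE<sub>l</sub>).

Frequencies for identification default to the pooled dataset (per-group mode
available). Genotype-accumulation curves drop individuals missing any locus
of the drawn subset (the resampling is uniform over subsets without
replacement; the full-panel point is exact). The He-ordered P(ID)sibs curve
reports the smallest panel prefix reaching each threshold (defaults 0.01,
0.001, 0.0001 — the conventional sufficiency range for individual
identification), with He ties broken by locus name.

## Panel selection (ACO)

The objective is lexicographic: minimise panel size subject to
percent-distinguished ≥ 100 − e (e defaults to 5), then maximise mean PIC,
ties broken by locus names. Ants add loci with probability ∝ τ<sup>α</sup>η<sup>β</sup>
(η = PIC) until feasible, then greedily drop redundant loci; evaporation
τ ← (1−ρ)τ is followed by a deposit (1/size + 0.1·mean PIC) on the
iteration-best panel. Defaults: 50 ants, 200 iterations, α = 1, β = 2,
ρ = 0.2, τ₀ = 1 — chosen for reliability on ≤ 15-locus instances and checked
against the exhaustive oracle (identical optimum on ≥ 95% of seeded
instances, never better). Percent-distinguished during the search is exact on
the fixed subset (cached per subset), not resampled.

## D-loop statistics

Complete deletion is the default site filter (every column carrying a gap or
N anywhere is removed before all statistics; a pairwise mode is available).
On the retained L sites: h = n/(n−1)(1 − Σf²) with Nei's sampling variance;
k is the mean pairwise difference count, π = k/L with the standard
total (sampling + stochastic) variance; θ<sub>S</sub> = S/(a<sub>n</sub>L),
a<sub>n</sub> = Σ<sub>i&lt;n</sub>1/i.

Between populations, G<sub>ST</sub> = (H<sub>T</sub> − H<sub>S</sub>)/H<sub>T</sub>
uses plain haplotype frequencies, while the separately reported F<sub>ST</sub>
applies the Nei–Chesser small-sample corrections (harmonic-mean ñ), which is
why it can be slightly negative. Φ<sub>ST</sub> is a two-level AMOVA on
pairwise nucleotide differences. D<sub>xy</sub> and D<sub>a</sub> use Nei's
frequency-weighted forms — within-population π in this context carries the
n² denominator so that D<sub>a</sub> is exactly 0 for identical populations
and D<sub>a</sub> ≤ D<sub>xy</sub> always, with equality iff both populations
are internally monomorphic. N<sub>m</sub> = (1 − F<sub>ST</sub>)/(2F<sub>ST</sub>)
for a maternally inherited haploid marker (infinite when F<sub>ST</sub> ≤ 0).

Neutrality: Tajima's D with the standard e₁/e₂ constants; Fu & Li's D* and F*
without outgroup, using the total singleton count η<sub>s</sub> and the
corrected constant set used by the standard DNA-polymorphism packages; Fu's
F<sub>s</sub> = ln(S′/(1 − S′)) with S′ = P(K ≥ k<sub>obs</sub>) under the
Ewens sampling formula at θ̂ = k, computed by the exact unsigned-Stirling
recursion (validated against naive partition enumeration for n ≤ 8). All are
NaN when S = 0 or n < 4.

Mismatch distributions compare observed pairwise-difference frequencies with
the constant-size geometric expectation F<sub>i</sub> = θ<sup>i</sup>/(1+θ)<sup>i+1</sup>
at θ̂ = k. The raggedness index follows the Harpending convention with one
trailing zero class: r = Σ<sub>i=1..d+1</sub>(x<sub>i</sub> − x<sub>i−1</sub>)²,
x<sub>d+1</sub> = 0 (so a point mass at 0 differences gives r = 1). Raggedness
significance and expansion-model p-values require coalescent resampling under
the alternative and are out of scope; only index values are reported.

## Synthetic data

The generator emulates the study conditions this package targets: five breed
populations of 59/29/41/37/18 diploids, 15 dinucleotide loci with 5–12
alleles each, weak differentiation, and mean H<sub>e</sub> near 0.69.
Ancestral frequencies are symmetric-Dirichlet (concentration 0.45, which puts
the expected H<sub>e</sub> for 5–12 alleles at ≈ 0.685); population
frequencies follow a Balding–Nichols-style Dirichlet with concentration
p(1−F<sub>ST</sub>)/F<sub>ST</sub> (mean p, variance inflation F<sub>ST</sub>);
genotypes are drawn with probability f<sub>is</sub> of an identical-by-descent
homozygote; a hidden null allele at frequency r makes null/visible genotypes
appear homozygous and null/null genotypes missing. The truth record stores
the realised frequencies and the model-expected
H<sub>e</sub> = mean over loci of (1 − F<sub>ST</sub>)(1 − Σp<sub>anc</sub>²),
so parameter-recovery checks compare against the realised expectation, not a
round number. All randomness flows from one seed through generator spawning.

Pedigrees draw founders in Hardy–Weinberg proportions and transmit one
uniformly chosen allele per parent (optional per-allele error rate). The
D-loop sampler builds a star topology: 14 haplotypes each carrying 3 private
substitutions on a 423-bp background, sampled per population from Dirichlet
haplotype frequencies with largest-remainder rounding (deterministic counts).

What the generator does **not** emulate: mutation processes on allele sizes
(no stepwise-mutation dynamics beyond the size grid), linkage, realistic
D-loop phylogenies (the star topology has no internal coalescent structure),
sequencing error, or allele-size binning artefacts. Passing tests therefore
demonstrate correctness of the estimators under their own model assumptions,
not robustness to real-data artefacts.

Neutrality-test calibration uses a separate constant-size coalescent sampler
(msprime; haploid, Jukes–Cantor finite sites, scaled so θ equals the expected
mean pairwise difference count). The calibration check runs at θ = 20 over
423 bp (n = 25): at small θ the exact null mean of Tajima's D is genuinely
negative (≈ −0.09 at θ = 5 in our measurements, confirmed by tskit's own
implementation on identical tree sequences), whereas at θ = 20 the statistic
is in its asymptotic regime with null mean ≈ +0.02, measured across three
disjoint 600-simulation seed ranges.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations use the study-shaped fixture
(184 diploids × 15 loci; 184 D-loop sequences) and parameter-recovery runs of
2 × 300 diploids × 20 loci; Monte Carlo validations use 10⁵ pairs/trials;
ACO-vs-oracle checks use 20 instances of 10 loci. These sizes make every
Monte Carlo tolerance at least ~3 SE wide while keeping the default runs
fast. Probabilities in the HWE test are compared in log space with a 10⁻⁹
slack to make "no more probable than observed" robust to rounding; percentage
constraints in the panel search carry a 10⁻⁹ slack; bootstrap and permutation
p-values use the (hits + 1)/(N + 1) convention.

## Known limitations

* The exact HWE enumeration is gated by a combinatorial bound, so moderately
  polymorphic loci always take the Monte Carlo path.
* Null-allele frequencies are moment estimates; no maximum-likelihood
  genotyping-error model is fitted.
* AMOVA reports components and Φ statistics without permutation p-values.
* R<sub>ST</sub> and M-ratio assume allele sizes on the repeat grid; off-grid
  sizes are rounded with a warning-level convention rather than rejected.
* The D-loop module requires a pre-aligned input; no alignment, haplotype
  network, or haplogroup assignment is performed.
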
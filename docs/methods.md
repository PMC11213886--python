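# Methods

This note documents the statistical models implemented in `capriscan`, the
design of the synthetic-data generator the test-suite runs on, and the
numerical and design choices a maintainer should know about.

## Statistics

**Heterozygosity and π.** Per-site expected heterozygosity uses the
unbiased small-sample estimator 2p̂q̂·n/(n−1), where n is the number of
non-missing allele calls at the site. This makes windowed π exactly equal
to the mean pairwise Hamming distance among sampled chromosomes divided by
window length, a property the tests verify by brute force. π windows are
tiled per contig from coordinate 0 (0-based half-open internally; VCF/GFF
coordinates are converted only at the file boundary); trailing partial
windows are kept and divided by the full window length, so per-window
values remain comparable — the alternative (span normalisation) would
inflate sparse trailing windows.

**F_HOM.** Per sample, F = (O_hom − E_hom)/(L − E_hom) with E_hom summed
over the sites where the sample has a call, using the sample's own
population frequencies. Monomorphic sites contribute identically to O, E
and L and therefore cancel; the degenerate case L = E_hom is reported as
missing.

**DST / D.** For each within-population sample pair, DST = (IBS2 +
0.5·IBS1)/N over co-non-missing sites, with the IBS state of two dosage
genotypes g₁, g₂ equal to 2 − |g₁ − g₂|; D = 1 − DST. Both the similarity
and the distance are reported.

**ROH.** The caller reproduces the genotype-window mechanism of the
standard tooling: 50-SNP windows tolerating 1 heterozygote vote on every
SNP they cover; SNPs supported by ≥ 5% of their windows (the tool default —
the source protocol does not print this value) seed candidate runs, which
are split at inter-SNP gaps > 100 kb and wherever the heterozygote count
would exceed the window allowance, then filtered at ≥ 10 SNPs, ≥ 100 kb and
≤ 10 kb/SNP. Missing genotypes count as neither homozygous nor
heterozygous and do not break runs. The printed flag set also names a
5000 kb window span; the SNP-count window is the operative mechanism, so
the span is recorded but non-binding. Length classes use closed upper
bounds (a 0.25 Mb run falls in 0.1–0.25).

**LD and Ne.** r² is the squared Pearson correlation of genotype dosage
vectors (composite LD, usable unphased). The Ne trajectory uses a
Sved-type inversion with explicit constants: α = 2 (mutation-adjusted) and
the 1/(2n) sample-size correction; both are configuration, not inference,
because the source protocol delegates them to a cited method. Bins need
≥ 100 pairs; non-positive adjusted r² drops the bin with a warning; the
trajectory is truncated at t = 1000 generations.

**Weir–Cockerham F_ST.** Per-site variance components a, b, c follow the
1984 two-population formulas including the heterozygosity terms; every
reported F_ST — the population matrix and the windowed scan — is the
weighted ratio of sums Σa/Σ(a+b+c). Negative estimates are kept in reports
but clamped to zero when the matrix feeds neighbour joining, which needs a
dissimilarity. The windowed scan averages components within the window
first and Z-standardises the window values genome-wide; a per-SNP-Z
alternative (standardise per-site ratios, then average within windows) is
available behind a flag.

**Hp / ZHp.** n_MAJ and n_MIN are copies of the most and least abundant
allele per SNP within one population, taken from genotype allele counts
(an AD read-depth mode would be the only faithful alternative for pooled
data; genotype counts are the default because the pipeline consumes
genotype VCFs). Window Hp = 2·Σn_MAJ·Σn_MIN/(Σn_MAJ + Σn_MIN)²; windows
with fewer than 10 SNPs are discarded before the genome-wide Z-transform.
Z-transforms always use the sample standard deviation over all retained
windows of one population (or pair), i.e. a single global distribution.

**EHH / XP-EHH.** The carrier-conditioned EHH profile at marker distance x
is Σᵢ C(eᵢ,2)/C(n,2) over groups of carrier haplotypes identical from the
core to x (EHH(core) = 1). XP-EHH uses the allele-agnostic site version
(groups seeded by the core alleles over all haplotypes of a population):
per core SNP, iHH is the trapezoidal integral of EHH over physical
distance, both directions, truncated where the combined two-population EHH
falls below 0.05 or at 1 Mb; the raw statistic ln(iHH_A/iHH_B) is
standardised genome-wide and converted to two-sided standard-normal
p-values. Positive scores mean longer haplotypes in population A. Cores
where either integral is zero are flagged and excluded from
standardisation. Physical distance stands in for genetic distance at a
uniform configurable rate. For speed, group refinement happens only at
markers polymorphic in the pooled sample (others cannot split any group)
and in chunks of 16 markers, with marker-by-marker replay at the chunk
where the truncation threshold is crossed — the refinement itself uses
every marker, so the grouping is exact and only the integration grid
coarsens slightly.

**Candidate tiers.** The candidate tier is ZHp < −3.9, ZF_ST > 4 and
|XP-EHH| ≥ 5, with the XP-EHH rule taken as the union of the fixed score
and the top 0.001% of the empirical |score| distribution (the protocol
states the two as alternatives). The top tier is ZHp ≤ −7.0, ZF_ST ≥ 7.0,
|XP-EHH| ≥ 6.0. |XP-EHH| is used because a sweep in either population is
reportable. Window hits merge when overlapping or book-ended; SNP-level
XP-EHH hits merge within 200 kb (configurable; candidate regions in data
of this type are on the 100–300 kb scale). A gene annotates a region on
any ≥ 1 bp overlap; regions may carry no genes.

## The synthetic-data generator

`simpop` emulates the post-variant-calling structure of a multi-population
resequencing cohort: several populations of ~5 diploids, biallelic SNPs on
one autosome, genome background π ≈ 0.002, LD decaying within a few
hundred kb, drift-driven window F_ST in the 0.05–0.3 range, and localized
sweeps in single populations.

**Model.** Standing variation is initialised by drawing per-site
frequencies from the neutral 1/i site-frequency spectrum over the 2Nₑ
ancestral haplotypes at linkage equilibrium; each population then evolves
independently by discrete Wright–Fisher generations (each offspring draws
two gametes from random diploid parents; during selfing generations both
gametes come from one parent). Meioses carry Poisson-distributed crossover
counts with mean equal to the chromosome's map length; breakpoints are
uniform on the marker grid, which matches a uniform map because marker
positions are uniform. No new mutation enters during drift; the initial
site count is calibrated so the sampled panel reaches the target π after
the expected heterozygosity decay (1 − 1/(2Nₑ))ᵗ, and the realized value
is required only to land within 25% of the target. A full mutation–drift
burn-in would cost orders of magnitude more time for no additional
property the pipeline tests; the SFS initialisation reproduces the drift
F_ST expectation, the build-up of LD toward the Sved equilibrium, and the
haplotype substrate sweeps need.

**Sweeps** are imposed post hoc, deterministically: the first haplotype of
the target population donates its alleles to recipients over nested
intervals centred on the sweep position, with widths shrinking linearly
from the sweep width to ~0 across recipients — the taper recombination
would produce. This creates the low-Hp valley and the long-shared-
haplotype signal without selection-coefficient dynamics.

**Rescaled drift regime.** Desk-scale tests cannot run thousands of
diploids for thousands of generations, so cohorts are simulated in a
standard rescaled regime: Nₑ = 150 diploids, 30 generations and 8 cM/Mb
reproduce the drift level (E[F_ST] ≈ 0.095) and the population-scaled
recombination Nₑ·c of a realistic population (Nₑ ≈ 1000–1500, 1 cM/Mb,
200–300 generations). The rescaling keeps background identity-by-descent
tracts short relative to a 300 kb sweep, which is what makes XP-EHH
informative; with an unscaled map at small Nₑ the whole chromosome drifts
as a handful of linked blocks and no haplotype statistic can separate a
sweep from background coalescence.

**What the generator does not emulate.** Mutation during drift (so no new
rare variants arise after the split), gene conversion, non-uniform
recombination and mutation maps, genotyping error and missingness
structure, overlapping generations, and migration after the split. Passing
tests therefore demonstrate correctness of the statistical machinery under
a clean neutral-plus-sweep model, not robustness to the artefacts of real
resequencing data.

**Determinism.** One `numpy` generator seeded from the config drives every
draw in documented order (positions, ancestral frequencies, ancestral
alleles, then per-population drift), so identical configs give
bit-identical VCFs; sweeps add no randomness.

## Calibrations observed in testing

Two known effects are worth recording. First, conditioning on sites that
remain polymorphic in the sample biases genome-wide Weir–Cockerham F_ST
slightly below the unconditional drift expectation
1 − (1 − 1/(2Nₑ))ᵗ when the ancestral spectrum is rare-heavy (the neutral
1/i spectrum is); the two-population test asserts the ±0.05 band around
the expectation, which comfortably covers the effect. Second, a single
panel's Ne trajectory fluctuates with the realized genealogy, so recovery
is asserted per distance bin on LD pairs pooled over five seeded
replicates, after which every bin in t ∈ [10, 100] sits within a factor of
two of the simulated value.

## Problem sizes used by the tests

Sweep-recovery replicates use the full stated conditions (20 Mb, 5
diploids per population, π ≈ 0.002, sweep frequency 0.95 and width 300 kb,
10 seeds) with XP-EHH cores thinned deterministically to every 50th SNP —
~3,000 cores genome-wide, ample for a top-1% rule. Neutral-tail checks
pool three replicates. Drift-F_ST uses five 10 Mb replicates; Ne recovery
pools five 10 Mb constant-Nₑ=200 panels with 500 generations of drift at
reduced site density (π target 2×10⁻⁴ — LD does not depend on it);
pipeline determinism runs a 1.5 Mb three-population cohort twice. The
oracle-equivalence suite uses ≤30-SNP panels (≤200 SNPs for ROH) over 100
seeds each.

## Known limitations

- The ROH caller's final-run heterozygote allowance (one per run segment)
  follows the window allowance; tools differ in this corner and the
  protocol does not pin it down.
- XP-EHH integrates over physical distance with a uniform rate; a genetic
  map input is not supported.
- The LD-pruning guarantee is scoped to pairs co-resident in at least one
  sliding window; pairs further apart than (window − step) that never share
  a window are not examined, matching the standard tool's behaviour.
- ADMIXTURE-style model fitting is deliberately out of scope; only a
  Q-matrix reader is provided for downstream plotting or intersection.
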
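# Methods

## Genotype model and file dialect

Genotypes are diploid alt-allele dosages (0/1/2) with a distinguished
missing sentinel, over loci carrying (id, chromosome, 1-based position,
allele a1, allele a2). Dosage counts copies of a2, the second-listed
allele, matching the dominant PED dialect; the PED missing code is `0`.
PLINK text MAP files carry no allele columns, so `write_genotypes` records
allele order (and per-population altitude class) in `#`-comment lines that
`read_genotypes` honours; files from other tools fall back to
first-observed-allele order. Chromosome labels are opaque strings — the
"autosome" set is supplied explicitly in the QC configuration rather than
hard-coding a species' karyotype.

## Quality control

Filters run in a fixed, documented order: (1) samples with missing
fraction > 0.10; (2) loci with call rate < 0.90 or missingness > 0.10;
(3) loci with minor allele frequency < 0.05 (computed after sample
removal); (4) optional restriction to configured autosomes. All
inequalities are strict, so a locus at MAF exactly 0.05 survives. The
filter is idempotent, and the removal report names every removed item with
its triggering rule.

## Linkage disequilibrium

All LD statistics are genotype-based (composite) r² — the squared Pearson
correlation of dosage vectors — because array data carry no phase.
Pruning follows the sliding-window scheme (window 50 SNPs, step 5,
threshold r² > 0.2 by default): within each window, while any retained
pair exceeds the threshold one member is removed. The removal tie-break is
ours to define (external tools leave it unspecified): the lower-MAF member
goes, ties resolved against the later locus in map order. The postcondition
— no retained same-window pair above the threshold — is asserted by an
exhaustive pair scan in the tests.

## Weir–Cockerham θ and d_i

Per-locus pairwise F_ST uses the full Weir & Cockerham (1984) two-population
variance components a, b, c, including the observed-heterozygosity terms,
with θ = a/(a+b+c) (formulas in `fst.py`'s module docstring). Negative
per-locus θ estimates are retained, not truncated at zero: truncation would
bias the genome-wide moments that standardize d_i. A locus monomorphic in
both populations has a+b+c = 0 and is undefined — a flagged sentinel, not
an exception — and undefined loci are excluded per pair (a locus can be
defined against one reference and undefined against another). Genome-wide
pairwise θ is the ratio-of-sums estimator Σa/Σ(a+b+c), not the mean of
per-locus ratios.

d_i sums, over reference pairs, each pair's per-locus θ standardized by
that pair's genome-wide mean and sample standard deviation (n−1). Pairs
with undefined θ at a locus contribute 0 there; a pair whose genome-wide sd
is 0 (degenerate, e.g. a duplicated reference) contributes 0 everywhere and
is logged loudly rather than aborting the scan. Zero-sd detection uses a
small relative tolerance because a constant column realizes sd ≈ 1e-17
through rounding.

Empirical significance is the tail proportion P_E = #{d_k ≥ d}/N over
finite d_i values, ties sharing one P_E, and the candidate set is
P_E < 0.005 strictly. With N distinct values this keeps the top k where k
is the largest integer with k/N < 0.005 — 219 loci of 43,835 — which is why
the strict reading was adopted over "top ⌈0.005 N⌉". The scan-level MAF
filter retains loci with pooled MAF ≥ 0.05 over the union of focal plus
reference samples; pooling is the documented resolution of an ambiguity
(per-population filtering is the alternative).

Region merging is single-linkage chaining per chromosome: consecutive
position-sorted significant loci join one region when their gap is
≤ 500,000 bp (inclusive — 500,001 bp splits), and region bounds are member
SNP positions, not extended flanks, which reproduces the printed
150.2-kb and 51.6-kb widths from their endpoint coordinates. Singletons
form width-0 regions. BED export converts 1-based inclusive bounds to
0-based half-open.

## Synthetic data

The generator is Balding–Nichols: per locus an ancestral frequency p is
drawn uniformly on (0.05, 0.95); each population draws its frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F) — mean p, variance p(1−p)F — and genotypes are
two independent allele draws (Hardy–Weinberg within population). This was
chosen over coalescent simulation because the scan consumes only
allele-frequency structure, and closed-form control of F makes
parameter-recovery tests sharp: two populations with drift F each realize
pairwise θ ≈ F. Default cohort: 12 populations (4 highland, 8 lowland) of
15–37 diploids and 45,000 loci over 26 chromosomes at 50-kb spacing, drift
F = 0.06 per population so pairwise θ lands near the low end of the
0.08–0.20 range typical of sheep breed panels. Sweeps are end-state
overrides — highland genotypes redrawn from Hardy–Weinberg at a target
frequency (default scenarios use 0.95 over a pinned ~0.10 ancestral
background) — because the emulated study reports end-state frequencies, not
selection coefficients.

Loci are independent by default; an optional block-copy mode duplicates
genotype columns with per-entry resampling noise to create LD blocks for
pruning/decay tests. A uniform missing-rate parameter (default 0) exercises
QC. All draws flow from one root seed through named substreams
(per-population, per-stage), so each stage is independently reproducible
and same-seed runs are byte-identical.

The re-sequencing generator emits a VCF v4.2 window (default: 400 sites in
a 72-kb window, 4 highland vs 8 lowland diploids). Divergent sites are
fixed for the alternate allele in the highland group and strictly
polymorphic in the lowland group at a frequency drawn in (0.2, 0.8);
background sites share one frequency across groups.

What the generator does **not** emulate: ascertainment bias of array SNP
selection, linkage between array loci (unless block mode is enabled),
admixture or migration between breeds, genotyping error, or selection
acting over time. Passing tests therefore demonstrate the statistical
machinery under idealized drift + end-state selection, not performance on
real array data.

## Candidate-window follow-up

Fisher's exact test is two-sided by the as-or-less-probable-tables rule
(the common convention; only the test itself is prescribed by the design),
applied to the 2×2 table of (alt, ref) chromosomes × groups; a zero margin
gives p = 1, flagged degenerate. "Fixed" means all chromosomes in a group
carry one allele; "segregating" means both alleles observed. The site-level
MAF filter is pooled-group (the 12-individual pooled description) and
strict (> 0.05). At 4 vs 8 diploids the test's resolution is limited: a
site fixed in the highland group against lowland frequency 0.5 cannot
reach p < 0.001 (the minimal attainable p for fixed-vs-half is above the
threshold), so only strongly skewed divergent sites are callable —
documented and tested as a property of the design, not a defect.

Gene-model annotation classifies each position as exonic, intronic,
upstream, downstream or intergenic; upstream/downstream distances are
measured to the start codon (not the transcript start) respecting strand,
with a 5-kb flank beyond which sites are intergenic. VCF and gene-model
positions are 1-based; conservation tracks are 0-based half-open BED
intervals, and a site at position pos overlaps [start, end) iff
start ≤ pos−1 < end. The altitude-gradient summary sorts population
frequencies by altitude rank and reports Spearman ρ (midranks on ties;
constant frequencies flagged undefined).

## Population structure

PCA operates on the centred (optionally √(p(1−p))-standardized) dosage
matrix with per-locus mean imputation of missing values; components are
sign-fixed by making each component's largest-magnitude loading positive,
so output is deterministic. The population distance matrix defaults to
genome-wide ratio-of-sums θ (clamped at 0; Nei's 1972 standard distance is
the config alternative — the choice is cosmetic since real-data tree
topologies are not reproduction targets). Neighbor joining is the classic
Saitou–Nei agglomeration with Q-matrix minimization; ties join the
lowest-index pair, negative branch lengths are clamped to 0 with a
warning, and an additive input matrix is recovered exactly (asserted to
1e-9 in tests, cross-checked against an independent implementation).

## Problem sizes

The test suite and acceptance script run at desk scale, chosen to give
stable statistics: drift recovery at 5,000 loci × 2 × 50 diploids; sweep
power as 100 replicate full scans of a 2-highland/4-lowland,
25-diploid-per-population, 2,000-locus panel (each replicate an
independent seed); null Fisher calibration over 20 seeds × 300 sites. The
analysis scripts run the full 45,000-locus, 12-breed cohort.

## Known limitations

- Two-population θ only; joint multi-population estimators, bootstrap
  intervals and haplotype statistics (EHH/iHS) are out of scope.
- Binary PLINK BED, phased data and imputation are unsupported.
- The LD pruner is quadratic within windows and meant for panels up to a
  few thousand loci per run; the analysis driver prunes a thinned subset.
- The simulator's independence between loci makes merged sweep regions
  mostly singletons; region-merging behaviour on clustered signals is
  exercised with constructed coordinates instead.
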
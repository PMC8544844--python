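# Methods

This package implements the standard autozygosity toolkit for SNP-array
genotypes of livestock populations: runs of homozygosity (ROH) by the
consecutive method, the genomic inbreeding coefficient F_ROH overall and by
run-length class, ROH islands as candidate selection signatures, population
structure by identity-by-state (IBS) multidimensional scaling and ROH-count
PCA, and a multi-class homozygosity-by-descent (HBD) hidden Markov mixture
model yielding per-marker HBD posteriors and the genome-wide inbreeding
coefficients F_G and F_G−T. A synthetic mosaic-genome generator with full
truth tracks makes every stage verifiable end to end.

## Genotype data and quality control

Genotypes are diploid biallelic codes (0 = hom for the first-seen allele,
1 = het, 2 = hom alternate, −1 = missing) read from PLINK-text PED/MAP.
Because PED carries no reference allele, coding is per-marker first-seen;
every statistic computed here (MAF, IBS, homozygosity) is invariant to that
orientation. QC is deliberately minimal — restrict to a declared autosome
set and nothing else. MAF or LD pruning is *not* applied: both remove
precisely the low-diversity regions that ROH and HBD analyses are designed
to find. Instead the MAF spectrum is characterized (five classes:
monomorphic, (0, 0.005], (0.005, 0.01], (0.01, 0.05], (0.05, 0.5]) and
monomorphic-marker sharing between populations is tabulated, because an
excess of markers fixed in several populations can inflate apparent
homozygosity. Markers with no called genotype in a population cannot be
assigned a MAF class and are counted as "unclassified" — the one
classification rule the source analyses leave unstated, so it is a
documented guess here. "Monomorphic in both populations" counts markers
with MAF = 0 in each population regardless of which allele is fixed; a
stricter same-fixed-allele count is available via a flag.

Genetic positions are derived from physical positions at 1 cM per Mbp
(1e-8 Morgan/bp). This constant ties the HBD rate ladder to physical
scale: a class with rate 64/Morgan has expected segment length
1/64 Morgan = 1.5625 Mbp.

## ROH detection (consecutive method)

Each individual's markers are scanned left to right per chromosome, with
five constraints (defaults in parentheses): minimum SNPs per run (15),
minimum run length (1 Mbp), maximum inter-marker gap (1 Mbp), maximum
heterozygous calls per run (2), maximum missing calls per run (2). A
candidate run extends while the gap and the running het/missing counts stay
within bounds; on a violation the candidate is trimmed so both ends are
homozygous non-missing, emitted if it meets the SNP-count and length
minima, and scanning restarts just past the violation (no backtracking).
Run length is end_bp − start_bp throughout.

`enumerate_valid_intervals` provides an independent exhaustive oracle at
small scale (≤ 2,000 markers): all maximal marker intervals satisfying
every constraint, computed from closed-form prefix-index limits. The
scanner's restart rule means its output is a subset of *valid* intervals,
each contained in (but, when maximal valid intervals overlap, not always
equal to) an oracle interval; the test suite asserts exactly this
containment plus the five constraints re-derived from the raw genotype
matrix.

F_ROH is the summed length of an individual's runs divided by the
autosomal genome length, here defined as the map-covered length (sum over
chromosomes of last − first marker position); substitute an assembly
constant if preferred. Length-class views are provided in two forms:
cumulative minimum-length thresholds (≥1, ≥2, ≥4, ≥8, ≥16 Mbp — the
first threshold reproduces the overall F_ROH, and the vector is
non-increasing) and disjoint bins ([1,2), [2,4), [4,8), [8,16), [16,∞)
Mbp, half-open, so a 16.0 Mbp run falls in the open-ended class).

### Known bias of run-based inbreeding

On simulated mosaics with known truth, F_ROH (≥1 Mbp) systematically
*overestimates* the true ≥1 Mbp autozygous genome fraction by roughly
+0.02 at study-like conditions (chip-density maps, 25–40 qualifying runs
per 500 Mbp of genome). Two mechanisms, both intrinsic to the consecutive
definition rather than to this implementation: (i) each run may absorb up
to its het allowance beyond the true HBD boundary, extending on average by
the homozygous markers preceding the terminating third heterozygote
(~150–300 kbp per run at 50 kbp spacing and 40–45% background
heterozygosity); (ii) short non-HBD gaps between nearby HBD segments are
bridged when they contain at most two heterozygous markers. The bias grows
linearly with the number of runs, so it is mild for genomes whose
autozygosity sits in few long (recent) segments and material when it sits
in many short (ancient) segments. The acceptance suite reports this
honestly: the per-individual ±0.02 recovery check fails at study-like run
densities, and the measured error is written out by the acceptance script.

## ROH islands

Per SNP and population, incidence = fraction of individuals carrying at
least one run whose closed bp interval contains the SNP (run endpoints are
SNPs of the run). Islands are maximal stretches of consecutive
same-chromosome SNPs with incidence at or above the threshold (default
0.80, inclusive), discarded when shorter than the SNP minimum (default 15;
the filter can be disabled to inspect every qualifying run). The
denominator is all genotyped individuals of the population — no call-rate
exclusions, consistent with the absence of individual-level QC. Interval
overlap against annotations uses half-open coordinates; island bounds,
being closed SNP positions, are widened by +1 bp on the right before
intersecting.

## Population structure

IBS distance between two individuals is the mean over jointly called
markers of |g_i − g_j| / 2 (0 for identical genotypes, 0.5 for one shared
allele, 1 for opposite homozygotes); missing data are handled
pairwise-complete, and a pair with no jointly called marker is an error.
The embedding is classical (Torgerson) metric MDS: double-center the
squared distances, eigendecompose, scale the top-k eigenvectors by the
square roots of their (positive) eigenvalues. Eigenvector signs are fixed
by forcing each column's largest-magnitude entry positive, so output is
deterministic. Negative eigenvalues (the IBS matrix need not be Euclidean)
are excluded from variance accounting.

ROH-count PCA operates on the individuals × chromosomes count matrix,
column-centered without scaling, via SVD. Whether to use individual rows
or breed-mean rows is genuinely ambiguous in this family of analyses; both
modes are provided (individual rows by default, `by_breed` for means).

## HBD mixture model (fixed-rate MixKR)

The genome of an individual is a mosaic of segments from K classes: several
HBD age classes plus one non-HBD class. Segment lengths are exponential
with class rate R (1/Morgan); R/2 is the approximate number of generations
to the common ancestor of that class. Default ladder: six HBD classes at
R = 2, 4, 8, 16, 32, 64 and the non-HBD class fixed at the most ancient
rate, 64 — covering ancestors up to ~32 generations back and HBD segments
down to ~1.5625 Mbp expected length. Rates are never estimated; only the
per-individual mixing coefficients (the class probability of each new
segment) are fitted.

Emissions at a marker with allele-1 frequency f and error ε: non-HBD emits
Hardy–Weinberg (f², 2f(1−f), (1−f)²); HBD copies one allele,
(1−ε)·(f, 0, 1−f) + ε·HW. ε (default 0.001) absorbs genotyping error and
mutation; it is the one free modelling constant. Missing genotypes emit 1
in every class. Allele frequencies default to within-population sample
estimates. Between markers d Morgans apart the chain stays in its segment
with probability exp(−R_c d) or starts a new segment with class drawn from
the mixing vector; chromosomes are independent chains initialized at the
mixing distribution. Because the one-step transition has rank-one change
structure, forward–backward costs O(K) per marker, and individuals of a
population are batched through a single vectorized pass.

Mixing is estimated by EM: the E-step accumulates the expected number of
segment entries per class (the chromosome-start posterior plus the
posterior change mass at every inter-marker step), the M-step normalizes.
Initialization is uniform; the fit is deterministic, and the observed-data
log-likelihood is non-decreasing across iterations (asserted in tests).
Convergence: |Δ log-likelihood| < 1e-6 or the iteration cap. For the
population-scale analyses here the cap is 100 iterations with tol 1e-5 —
F_G is stable to ~1e-4 between 50 and 150 iterations on study-scale fits,
while full 1e-6 convergence of the log-likelihood can take several hundred
more iterations without changing the reported coefficients.

F_G is the genome-wide mean of the summed HBD-class posterior; F_G−T
restricts the sum to classes with R ≤ T (inbreeding relative to a base
population ~T/2 generations back); F_G−T is non-decreasing in T and equals
F_G at the ladder maximum. Genome partitioning reports each individual's
genome-averaged posterior per class; HBD columns sum to F_G.

Resolution limit: with a factor-2 rate grid, the likelihood distinguishes
adjacent classes only weakly at realistic per-individual segment counts
(~10 HBD segments), so posterior mass spreads to classes neighbouring the
true one — e.g. a genome simulated purely from R = 4 shows ~25% of its HBD
mass on R = 2. Classes ≥8× apart separate cleanly (measured leakage
~1e-6). Interpret per-class partitions as smoothed age profiles, not
point assignments.

## Synthetic data generator

`simulate_mosaic_population` lays each chromosome down as a renewal
process: class from the mixing vector, length Exponential(R_c) in Morgans
converted at 1 cM/Mbp, final segment truncated at the chromosome end.
Within HBD segments one allele per marker is drawn at its frequency and
copied to both haplotypes; non-HBD genotypes are Hardy–Weinberg draws.
Genotyping error flips a call to one of the other two codes uniformly;
missing calls are masked afterwards. Identical configs (including seed)
give byte-identical PED output. The truth track records the exact segment
tiling, the realized autozygous fraction, and the raw exponential length
draws per class (pre-truncation, so their distribution is exactly
exponential for distributional tests).

Defaults emulate a scaled-down low-density-chip study of a small, inbred
local cattle breed: 5 chromosomes × 100 Mbp × 1,000 markers (evenly
spaced), frequencies Uniform(0.05, 0.5) plus 10% monomorphic markers,
error 0.002, missing 0.01, and a mixing vector (0, 0.005, 0.005, 0.01,
0.02, 0.16, 0.80) whose expected autozygosity ≈ 0.31 — dominated by the
ancient R = 64 class with a tail of recent classes, matching the
inbreeding profile such studies report. For estimator-recovery fixtures
the tests use chip-ascertained common-variant frequencies
(Uniform(0.2, 0.5), no monomorphic markers) and error = missing = 0,
since monomorphic stretches are homozygous regardless of ancestry and
would confound the truth comparison by construction.

What the generator does *not* emulate: linkage disequilibrium within
non-HBD segments (genotypes are locus-independent given frequencies),
ascertainment structure of real chips beyond the frequency range, pedigree
constraints between individuals (each genome is drawn independently), and
selection. Passing recovery tests therefore demonstrate correctness of the
estimators under the model's own assumptions, not robustness to LD or
shared ancestry between sampled animals.

Truth autozygosity restricted to a minimum length merges adjacent HBD
segments of different classes first, because back-to-back HBD segments are
genotypically one homozygous stretch — the entity any run-based or
posterior-based estimator can see.

## Numerical choices

- Forward–backward is scaled per marker; the scaling factors give the exact
  log-likelihood. A marker where every class has zero emission raises an
  error naming the marker index (this can only happen when allele
  frequencies are inconsistent with the genotypes they are applied to).
- Degenerate inputs: all-missing chromosomes contribute exactly 0 to the
  log-likelihood; a constant ROH-count matrix yields a flagged
  zero-variance PCA; an all-zero distance matrix embeds at the origin.
- Tie-breaks: eigenvector/score signs fixed by the largest-magnitude-entry
  rule; island runs are split by any below-threshold SNP (never merged
  across); length-class bins are half-open on the right.
- The ROH scanner restart rule (resume after the violating marker, no
  backtracking) can skip part of an overlapping maximal interval; the
  exhaustive oracle bounds the consequence and the containment property is
  what tests assert.

## Scale of the shipped analyses

Tests and the acceptance script run on 60–100 individuals and 3,000–10,000
markers, with the EM capped as described above; these sizes were chosen so
the full verification pipeline (simulation → detection → fits → recovery
checks) completes quickly on one CPU while leaving Monte-Carlo error well
below every asserted tolerance.
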
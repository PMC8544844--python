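# autozyg

Autozygosity analysis of SNP-array genotypes for population-genetic studies
of livestock (and other diploid) populations — written for researchers who
need to quantify inbreeding and demographic history in small or endangered
breeds from low-density chip data.

When both copies of a genomic region descend from a common ancestor the
region is *autozygous*: it shows up as a run of homozygosity (ROH) in chip
genotypes, and its length reflects the age of the inbreeding event (long
runs = recent ancestors; short runs = ancient ones, broken up by
recombination). `autozyg` implements the standard analysis stack around
this idea:

- **ROH detection** by the consecutive method: left-to-right scan per
  individual and chromosome under five constraints (≥15 SNPs, ≥1 Mbp,
  gap ≤1 Mbp, ≤2 heterozygous, ≤2 missing calls per run), with an
  exhaustive-interval oracle for verification, length-class summaries and
  per-chromosome counts.
- **Genomic inbreeding** F_ROH = ΣL_ROH / L_genome, overall and per
  length class (cumulative thresholds and disjoint bins).
- **ROH islands**: per-SNP within-breed ROH incidence, with islands called
  at ≥80% incidence over ≥15 consecutive SNPs — candidate selection
  signatures — plus interval overlap against annotations.
- **Population structure**: genome-wide pairwise identity-by-state (IBS)
  distances with classical (Torgerson) MDS, and PCA of per-chromosome ROH
  counts.
- **HBD mixture model** (fixed-rate MixKR): a hidden Markov model in which
  the genome is a mosaic of homozygous-by-descent segments from age
  classes with exponential lengths (rates R = 2, 4, …, 64 per Morgan;
  ancestors ≈ R/2 generations back) plus a non-HBD class fixed at the most
  ancient rate. Per-individual mixing coefficients are fitted by EM;
  per-marker HBD posteriors give the genome-wide inbreeding coefficient
  F_G, its base-population-restricted version F_G−T (classes with R ≤ T),
  and the partition of each genome over age classes.
- **Synthetic data**: a mosaic-genome generator with exact truth tracks
  (segment tilings, realized autozygosity, raw length draws) so every
  estimator above can be validated against known truth.

Genotypes are read from PLINK-text PED/MAP (or built in memory); all
tabular outputs are TSV. A thin CLI (`autozyg simulate|maf|roh|mds|
roh-pca|islands|hbd`) wraps the library.

## Worked example

Simulate a small inbred population, detect ROH, and fit the HBD mixture:

```python
import numpy as np
from autozyg import (
    HBDMixtureModel, ROHParams, SimulationConfig,
    detect_roh_consecutive, froh_table, roh_summary,
    simulate_mosaic_population,
)

cfg = SimulationConfig(seed=1)          # 5 chr x 100 Mbp x 1000 markers
ds, truth = simulate_mosaic_population(cfg, n_individuals=40, breed="LOC")

segments = detect_roh_consecutive(ds, ROHParams())
summary, per_chrom = roh_summary(segments, ds)
print(summary)
print(froh_table(segments, ds).mean(numeric_only=True).round(4))

results = HBDMixtureModel(ds).fit(tol=1e-5, max_iter=100)
print(results.summary(thresholds=(4.0, 16.0, 64.0)).round(4))
print("truth autozygosity:", truth.realized_autozygosity.mean().round(4))
```

Output:

```
       n_individuals  n_roh_total  mean_roh_per_individual  mean_length_mbp
breed
LOC               40         2454                    61.35          3.46846
>=1.0Mbp     0.4260
>=2.0Mbp     0.3371
>=4.0Mbp     0.2335
>=8.0Mbp     0.1293
>=16.0Mbp    0.0541
dtype: float64
          F_G  non_HBD  F_G-T(T=4)  F_G-T(T=16)  F_G-T(T=64)
breed
LOC    0.2812   0.7188      0.0366        0.091       0.2812
truth autozygosity: 0.2845
```

Reading this: each simulated individual carries ~61 runs averaging
3.5 Mbp; cumulative F_ROH falls from 0.426 (all runs ≥1 Mbp) to 0.054
(only runs ≥16 Mbp, i.e. recent ancestors). The HBD model's genome-wide
F_G of 0.281 tracks the simulated truth (0.284) closely, while F_ROH
substantially over-covers it on this deliberately realistic low-density
chip: the simulated panel includes 10% monomorphic markers and the run
definition tolerates two heterozygous calls, so runs extend beyond and
bridge between true autozygous segments (quantified in
`docs/methods.md`). F_G−T shows most inbreeding derives from ancestors
older than ~8 generations (T = 16 captures only 0.091 of the 0.281),
matching the simulated mixing, which puts most HBD mass on the most
ancient class.

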
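"""ROH islands: within-breed ROH incidence per SNP and island calling.

The per-SNP incidence is the fraction of a breed's individuals that carry at
least one ROH covering the SNP.  A region where incidence stays at or above
a threshold (here 80% by default) across a sufficient number of consecutive
SNPs is called an island — a putative selection signature, since sustained
near-fixation of a haplotype depresses local variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeDataset
from .roh import ROHSegment


@dataclass(frozen=True)
class IslandRegion:
    breed: str
    chromosome: int
    start_snp_id: str
    end_snp_id: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_frequency: float

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def snp_roh_frequency(
    segments: Sequence[ROHSegment], ds: GenotypeDataset, breed: str
) -> np.ndarray:
    """Fraction of the breed's individuals with a ROH covering each SNP.

    A SNP is inside a ROH when its position falls in the closed interval
    [start_bp, end_bp] on the run's chromosome (the run endpoints are
    themselves SNPs of the run).  The denominator is every genotyped
    individual of the breed.
    """
    ind_idx = ds.individuals_of(breed)
    id_set = {str(ds.ids[i]) for i in ind_idx}
    covered = {str(ds.ids[i]): np.zeros(ds.n_markers, dtype=bool) for i in ind_idx}
    chrom_index: dict[int, np.ndarray] = {}
    for chrom in np.unique(ds.map.chromosome):
        chrom_index[int(chrom)] = np.flatnonzero(ds.map.chromosome == chrom)
    for s in segments:
        if s.breed != breed or s.individual_id not in id_set:
            continue
        on_chrom = chrom_index[s.chromosome]
        pos = ds.map.position_bp[on_chrom]
        lo = np.searchsorted(pos, s.start_bp, side="left")
        hi = np.searchsorted(pos, s.end_bp, side="right")
        covered[s.individual_id][on_chrom[lo:hi]] = True
    stack = np.vstack([covered[str(ds.ids[i])] for i in ind_idx])
    return stack.sum(axis=0) / len(ind_idx)


def call_islands(
    incidence: np.ndarray,
    ds: GenotypeDataset,
    breed: str,
    threshold: float = 0.80,
    min_snps: int | None = 15,
) -> list[IslandRegion]:
    """Maximal runs of consecutive SNPs with incidence >= threshold.

    The threshold is inclusive; runs shorter than ``min_snps`` are discarded
    (pass ``min_snps=None`` to keep every qualifying run).  Runs never cross
    chromosome boundaries and are reported with the bp bounds of their first
    and last SNP.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    incidence = np.asarray(incidence, dtype=float)
    if incidence.shape != (ds.n_markers,):
        raise ValueError("incidence length must equal marker count")
    above = incidence >= threshold
    regions: list[IslandRegion] = []
    for chrom in np.unique(ds.map.chromosome):
        idx = np.flatnonzero(ds.map.chromosome == chrom)
        flags = above[idx]
        # run-length encode the qualifying flags
        k = 0
        while k < len(flags):
            if not flags[k]:
                k += 1
                continue
            start = k
            while k < len(flags) and flags[k]:
                k += 1
            run = idx[start:k]
            if min_snps is not None and len(run) < min_snps:
                continue
            regions.append(
                IslandRegion(
                    breed=breed,
                    chromosome=int(chrom),
                    start_snp_id=str(ds.map.snp_id[run[0]]),
                    end_snp_id=str(ds.map.snp_id[run[-1]]),
                    start_bp=int(ds.map.position_bp[run[0]]),
                    end_bp=int(ds.map.position_bp[run[-1]]),
                    n_snps=len(run),
                    peak_frequency=float(incidence[run].max()),
                )
            )
    return regions


def find_islands(
    segments: Sequence[ROHSegment],
    ds: GenotypeDataset,
    threshold: float = 0.80,
    min_snps: int | None = 15,
) -> list[IslandRegion]:
    """Incidence computation + island calling for every breed."""
    out: list[IslandRegion] = []
    for breed in ds.breed_names:
        incidence = snp_roh_frequency(segments, ds, breed)
        out.extend(call_islands(incidence, ds, breed, threshold, min_snps))
    return out


def intersect_regions(
    regions: Sequence[IslandRegion | tuple],
    annotation: Sequence[tuple[int, int, int, str]],
) -> pd.DataFrame:
    """Overlap regions against an annotation of half-open intervals.

    ``annotation`` rows are ``(chromosome, start_bp, end_bp, name)`` with
    half-open coordinates; island regions (whose bp bounds are the closed
    positions of their first/last SNP) are widened to ``[start, end + 1)``.
    Returns every (region, feature) pair overlapping by >= 1 bp.
    """
    for chrom, start, end, name in annotation:
        if start >= end:
            raise ValueError(f"malformed annotation interval {name}: {start} >= {end}")
    rows = []
    for region in regions:
        if isinstance(region, IslandRegion):
            r_chrom, r_start, r_end = region.chromosome, region.start_bp, region.end_bp + 1
            r_name = f"{region.breed}:{region.chromosome}:{region.start_bp}"
        else:
            r_chrom, r_start, r_end = region[:3]
            if r_start >= r_end:
                raise ValueError(f"malformed region interval: {r_start} >= {r_end}")
            r_name = str(region[3]) if len(region) > 3 else f"{r_chrom}:{r_start}"
        for chrom, start, end, name in annotation:
            if chrom != r_chrom:
                continue
            overlap = min(r_end, end) - max(r_start, start)
            if overlap >= 1:
                rows.append(
                    {
                        "region": r_name,
                        "chromosome": r_chrom,
                        "feature": name,
                        "overlap_bp": int(overlap),
                    }
                )
    return pd.DataFrame(rows, columns=["region", "chromosome", "feature", "overlap_bp"])


def islands_to_frame(regions: Sequence[IslandRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "breed": r.breed,
                "chromosome": r.chromosome,
                "start_snp_id": r.start_snp_id,
                "end_snp_id": r.end_snp_id,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "length_mbp": r.length_bp / 1e6,
                "n_snps": r.n_snps,
                "peak_frequency": r.peak_frequency,
            }
            for r in regions
        ]
    )
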
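"""Runs-of-homozygosity detection by the consecutive method, and F_ROH.

A run of homozygosity (ROH) is detected by scanning each individual's
markers left to right, chromosome by chromosome, without windows.  A
candidate run keeps extending while the inter-marker gap stays within
``max_gap_bp`` and the running heterozygous/missing counts stay within
their caps; when a constraint is violated the candidate is closed, trimmed
so that both ends are homozygous non-missing markers, and emitted if it
contains at least ``min_snps`` markers and spans at least
``min_length_bp``.  Scanning then restarts just past the violation (no
backtracking), so emitted runs are valid but not always the maximal valid
interval; :func:`enumerate_valid_intervals` provides the exhaustive maximal
set for verification at small scale.

The genomic inbreeding coefficient F_ROH of an individual is the summed
length of its ROH divided by the autosomal map length, optionally keeping
only runs above a minimum length: long runs reflect recent inbreeding,
short runs ancient inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeDataset


@dataclass(frozen=True)
class ROHParams:
    """The five constraints of the consecutive scan (defaults are the usual
    low-density-chip settings: >=15 SNPs, >=1 Mbp, gap <=1 Mbp, at most 2
    heterozygous and 2 missing calls per run)."""

    min_snps: int = 15
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 1_000_000
    max_het: int = 2
    max_missing: int = 2

    def __post_init__(self) -> None:
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        if min(self.min_length_bp, self.max_gap_bp, self.max_het, self.max_missing) < 0:
            raise ValueError("ROH parameters must be non-negative")


@dataclass(frozen=True)
class ROHSegment:
    individual_id: str
    breed: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int
    start_idx: int  # global marker index of the first SNP in the run
    end_idx: int  # global marker index of the last SNP in the run

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def _scan_vector(
    g: np.ndarray, pos: np.ndarray, params: ROHParams
) -> list[tuple[int, int]]:
    """Consecutive scan of one individual-chromosome genotype vector.

    Returns (first, last) marker-index pairs of emitted runs.
    """
    n = len(g)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        het = miss = 0
        j = i
        restart = None
        while j < n:
            if j > i and pos[j] - pos[j - 1] > params.max_gap_bp:
                restart = j  # the distant marker may start a new run
                break
            if g[j] == 1:
                het += 1
            elif g[j] == MISSING:
                miss += 1
            if het > params.max_het or miss > params.max_missing:
                restart = j + 1
                break
            j += 1
        # candidate is [i, j-1]; trim ends to homozygous non-missing markers
        a, b = i, j - 1
        while a <= b and g[a] in (1, MISSING):
            a += 1
        while b >= a and g[b] in (1, MISSING):
            b -= 1
        if a <= b:
            n_snps = b - a + 1
            length = pos[b] - pos[a]
            if n_snps >= params.min_snps and length >= params.min_length_bp:
                runs.append((a, b))
        i = restart if restart is not None else n
    return runs


def detect_roh_consecutive(
    ds: GenotypeDataset, params: ROHParams = ROHParams()
) -> list[ROHSegment]:
    """Detect ROH for every individual on every chromosome."""
    segments: list[ROHSegment] = []
    chrom_values = np.unique(ds.map.chromosome)
    chrom_blocks = []
    for chrom in chrom_values:
        idx = np.flatnonzero(ds.map.chromosome == chrom)
        pos = ds.map.position_bp[idx]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"marker positions unsorted on chromosome {chrom}")
        chrom_blocks.append((int(chrom), idx, pos))

    for ind in range(ds.n_individuals):
        for chrom, idx, pos in chrom_blocks:
            g = ds.genotypes[ind, idx]
            for a, b in _scan_vector(g, pos, params):
                run = g[a : b + 1]
                segments.append(
                    ROHSegment(
                        individual_id=str(ds.ids[ind]),
                        breed=str(ds.breeds[ind]),
                        chromosome=chrom,
                        start_bp=int(pos[a]),
                        end_bp=int(pos[b]),
                        n_snps=b - a + 1,
                        n_het=int((run == 1).sum()),
                        n_missing=int((run == MISSING).sum()),
                        start_idx=int(idx[a]),
                        end_idx=int(idx[b]),
                    )
                )
    return segments


def enumerate_valid_intervals(
    genotypes: np.ndarray, positions: np.ndarray, params: ROHParams = ROHParams()
) -> list[tuple[int, int]]:
    """Exhaustive maximal valid intervals of one genotype vector.

    Enumerates, by closed-form limits from prefix index arrays, every marker
    interval with homozygous non-missing endpoints that satisfies all five
    run constraints, and filters to intervals not strictly contained in
    another valid interval.  Intended as an independent oracle at small
    scale (documented limit: 2,000 markers).
    """
    g = np.asarray(genotypes)
    pos = np.asarray(positions)
    n = len(g)
    if n > 2000:
        raise ValueError("oracle is documented for vectors of <= 2000 markers")
    if n == 0:
        return []

    het_idx = np.flatnonzero(g == 1)
    mis_idx = np.flatnonzero(g == MISSING)
    hom = (g == 0) | (g == 2)

    # first index at/after i that cannot be included: the (cap+1)-th het or
    # missing marker at/after i, or the far side of an oversized gap
    starts = np.arange(n)

    def cap_limit(idx_arr: np.ndarray, cap: int) -> np.ndarray:
        # rank of each start within idx_arr
        rank = np.searchsorted(idx_arr, starts, side="left")
        take = rank + cap
        limit = np.full(n, n)
        ok = take < len(idx_arr)
        limit[ok] = idx_arr[take[ok]]
        return limit

    lim_het = cap_limit(het_idx, params.max_het)
    lim_mis = cap_limit(mis_idx, params.max_missing)

    big_gap_after = np.flatnonzero(np.diff(pos) > params.max_gap_bp)  # gap (k, k+1)
    # for start i, first blocked index is the k+1 of the first big gap with k >= i
    rank = np.searchsorted(big_gap_after, starts, side="left")
    lim_gap = np.full(n, n)
    ok = rank < len(big_gap_after)
    lim_gap[ok] = big_gap_after[rank[ok]] + 1

    exclusive_end = np.minimum(np.minimum(lim_het, lim_mis), lim_gap)

    # largest homozygous index < exclusive_end (and >= i)
    last_hom_upto = np.full(n, -1)
    running = -1
    for k in range(n):
        if hom[k]:
            running = k
        last_hom_upto[k] = running

    candidates = []
    for i in range(n):
        if not hom[i]:
            continue
        e = exclusive_end[i]
        b = last_hom_upto[e - 1] if e > 0 else -1
        if b < i:
            continue
        if (b - i + 1) >= params.min_snps and (pos[b] - pos[i]) >= params.min_length_bp:
            candidates.append((i, int(b)))

    # maximality: for start i the candidate end is the largest feasible, so a
    # candidate is non-maximal iff an earlier start reaches at least as far
    maximal = []
    best_end = -1
    for i, b in candidates:
        if b > best_end:
            maximal.append((i, b))
            best_end = b
    return maximal


LENGTH_BIN_EDGES_MBP = (1.0, 2.0, 4.0, 8.0, 16.0)
LENGTH_BIN_LABELS = ("1-2", "2-4", "4-8", "8-16", ">16")
CUMULATIVE_THRESHOLDS_MBP = (1.0, 2.0, 4.0, 8.0, 16.0)


def classify_roh_lengths(
    segments: Sequence[ROHSegment],
    edges_mbp: Sequence[float] = LENGTH_BIN_EDGES_MBP,
    labels: Sequence[str] = LENGTH_BIN_LABELS,
) -> pd.DataFrame:
    """Per-breed ROH counts in half-open length bins ([1,2), [2,4), ... Mbp,
    with the last bin open-ended)."""
    if list(edges_mbp) != sorted(edges_mbp):
        raise ValueError("length bin edges must be increasing")
    edges_bp = [e * 1e6 for e in edges_mbp] + [np.inf]
    breeds = sorted({s.breed for s in segments})
    out = pd.DataFrame(0, index=breeds, columns=list(labels), dtype=int)
    for s in segments:
        for lab, lo, hi in zip(labels, edges_bp[:-1], edges_bp[1:]):
            if lo <= s.length_bp < hi:
                out.loc[s.breed, lab] += 1
                break
    return out


def roh_summary(
    segments: Sequence[ROHSegment], ds: GenotypeDataset
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptive statistics per breed and per-chromosome counts.

    Returns ``(summary, per_chromosome)``: the summary holds the total ROH
    count, the mean count per individual (averaged over *all* genotyped
    individuals of the breed, including those without any ROH) and the mean
    segment length in Mbp.
    """
    breeds = ds.breed_names
    chroms = list(np.unique(ds.map.chromosome))
    per_chrom = pd.DataFrame(0, index=breeds, columns=chroms, dtype=int)
    totals = {b: 0 for b in breeds}
    lengths: dict[str, list[int]] = {b: [] for b in breeds}
    for s in segments:
        totals[s.breed] += 1
        lengths[s.breed].append(s.length_bp)
        per_chrom.loc[s.breed, s.chromosome] += 1
    rows = []
    for b in breeds:
        n_ind = len(ds.individuals_of(b))
        rows.append(
            {
                "breed": b,
                "n_individuals": n_ind,
                "n_roh_total": totals[b],
                "mean_roh_per_individual": totals[b] / n_ind,
                "mean_length_mbp": (np.mean(lengths[b]) / 1e6) if lengths[b] else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("breed"), per_chrom


def froh(
    segments: Sequence[ROHSegment],
    genome_length_bp: int,
    min_length_bp: int = 0,
) -> float:
    """Summed ROH length / genome length, over runs >= ``min_length_bp``."""
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    total = sum(s.length_bp for s in segments if s.length_bp >= min_length_bp)
    return total / genome_length_bp


def froh_by_threshold(
    segments: Sequence[ROHSegment],
    genome_length_bp: int,
    thresholds_mbp: Sequence[float] = CUMULATIVE_THRESHOLDS_MBP,
) -> np.ndarray:
    """Cumulative F_ROH of one individual at each minimum-length threshold.

    The vector is non-increasing in the threshold; the value at the smallest
    threshold is the overall F_ROH.
    """
    if list(thresholds_mbp) != sorted(thresholds_mbp):
        raise ValueError("thresholds must be increasing")
    return np.array(
        [froh(segments, genome_length_bp, t * 1e6) for t in thresholds_mbp]
    )


def froh_by_bin(
    segments: Sequence[ROHSegment],
    genome_length_bp: int,
    edges_mbp: Sequence[float] = LENGTH_BIN_EDGES_MBP,
) -> np.ndarray:
    """Disjoint-bin F_ROH: genome fraction in runs of each length bin."""
    edges_bp = [e * 1e6 for e in edges_mbp] + [np.inf]
    out = np.zeros(len(edges_mbp))
    for s in segments:
        for k, (lo, hi) in enumerate(zip(edges_bp[:-1], edges_bp[1:])):
            if lo <= s.length_bp < hi:
                out[k] += s.length_bp
                break
    return out / genome_length_bp


def froh_table(
    segments: Sequence[ROHSegment],
    ds: GenotypeDataset,
    thresholds_mbp: Sequence[float] = CUMULATIVE_THRESHOLDS_MBP,
) -> pd.DataFrame:
    """Per-individual cumulative F_ROH at each minimum-length threshold."""
    genome = ds.genome_length_bp()
    by_ind: dict[str, list[ROHSegment]] = {str(i): [] for i in ds.ids}
    for s in segments:
        by_ind[s.individual_id].append(s)
    rows = {}
    for ind_id, segs in by_ind.items():
        rows[ind_id] = froh_by_threshold(segs, genome, thresholds_mbp)
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f">={t}Mbp" for t in thresholds_mbp]
    )
    frame.insert(0, "breed", [ds.breeds[ds.index_of(i)] for i in frame.index])
    return frame


def segments_to_frame(segments: Sequence[ROHSegment]) -> pd.DataFrame:
    """Tabulate detected segments (one row per ROH)."""
    return pd.DataFrame(
        [
            {
                "individual_id": s.individual_id,
                "breed": s.breed,
                "chromosome": s.chromosome,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "length_bp": s.length_bp,
                "n_snps": s.n_snps,
                "n_het": s.n_het,
                "n_missing": s.n_missing,
            }
            for s in segments
        ]
    )


def segments_to_bed(segments: Sequence[ROHSegment], path) -> None:
    """Write segments as BED (0-based half-open; name = individual,
    score = SNP count)."""
    lines = [
        f"{s.chromosome}\t{s.start_bp}\t{s.end_bp + 1}\t{s.individual_id}\t{s.n_snps}"
        for s in segments
    ]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
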
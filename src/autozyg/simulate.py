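"""Synthetic genotype generator with homozygosity-by-descent mosaic structure.

Each simulated genome is laid down chromosome by chromosome as a renewal
process of segments.  Every new segment draws its class from the mixing
vector (several HBD age classes plus one non-HBD class) and its length from
an exponential distribution with the class rate, in Morgans; physical length
follows from the constant 1 cM/Mbp map.  Within an HBD segment the two
haplotypes are identical: one allele is drawn per marker from the population
frequency and copied.  Within non-HBD segments genotypes are drawn from
Hardy-Weinberg proportions.  Genotyping error (uniform flip to one of the
other two codes) and missing calls are applied afterwards.

The generator returns the dataset together with a :class:`TruthTrack`
recording the exact segment tiling, which lets every downstream estimator
(ROH-based inbreeding, HBD posteriors) be checked against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotypes import MISSING, MORGANS_PER_BP, GenotypeDataset, MarkerMap

NON_HBD = -1

#: HBD class rates 2^1..2^6 plus the non-HBD class fixed at the most
#: ancient rate (the last entry).
DEFAULT_RATES = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 64.0)

#: Default mixing emulates a small, highly inbred local breed: most new
#: segments are non-HBD, HBD mass concentrated in the ancient (R=64) class
#: with a tail of more recent classes; expected autozygosity ~0.31.
DEFAULT_MIXING = (0.0, 0.005, 0.005, 0.01, 0.02, 0.16, 0.80)


@dataclass
class SimulationConfig:
    """Study-scale defaults: 5 chromosomes x 100 Mbp x 1,000 markers,
    frequencies Uniform(0.05, 0.5) plus 10% monomorphic markers, 0.2%
    genotyping error and 1% missing calls."""

    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    n_markers_per_chrom: int = 1000
    freq_low: float = 0.05
    freq_high: float = 0.5
    monomorphic_fraction: float = 0.10
    mixing: Sequence[float] = DEFAULT_MIXING
    rates: Sequence[float] = DEFAULT_RATES
    genotyping_error: float = 0.002
    missing_rate: float = 0.01
    seed: int = 0
    morgans_per_bp: float = MORGANS_PER_BP

    def validate(self) -> None:
        mixing = np.asarray(self.mixing, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        if len(mixing) != len(rates):
            raise ValueError("mixing and rates must have equal length")
        if abs(mixing.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixing sums to {mixing.sum()}, expected 1")
        if np.any(mixing < 0):
            raise ValueError("mixing entries must be non-negative")
        if np.any(rates <= 0):
            raise ValueError("rates must be strictly positive")
        if not (0 <= self.genotyping_error < 1 and 0 <= self.missing_rate < 1):
            raise ValueError("error/missing probabilities out of range")

    def to_text(self, path: str | Path) -> None:
        lines = []
        for key, val in vars(self).items():
            if isinstance(val, (tuple, list)):
                val = ",".join(repr(v) for v in val)
            lines.append(f"{key} = {val}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "SimulationConfig":
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            if key in ("mixing", "rates"):
                kwargs[key] = tuple(float(v) for v in val.split(","))
            elif key in ("n_chromosomes", "chrom_length_bp", "n_markers_per_chrom", "seed"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)


@dataclass
class TruthTrack:
    """Ground-truth segment tiling for a simulated population.

    ``segments[i]`` lists ``(chromosome, start_bp, end_bp, class_index)``
    tuples tiling each chromosome (half-open bp intervals, ``class_index``
    is an index into the rate vector or ``NON_HBD``).
    ``sampled_lengths[c]`` collects the raw exponential length draws (in
    Morgans, pre-truncation) for class ``c`` across all individuals.
    """

    segments: list[list[tuple[int, int, int, int]]]
    realized_autozygosity: np.ndarray
    allele_freq: np.ndarray
    hbd_class_count: int
    sampled_lengths: dict[int, list[float]] = field(default_factory=dict)

    def hbd_intervals(self, individual: int, merge_adjacent: bool = True):
        """HBD (chrom, start_bp, end_bp) intervals of one individual.

        Adjacent HBD segments of different age classes are genotypically a
        single homozygous stretch, so they are merged by default.
        """
        out: list[tuple[int, int, int]] = []
        for chrom, start, end, cls in self.segments[individual]:
            if cls == NON_HBD:
                continue
            if merge_adjacent and out and out[-1][0] == chrom and out[-1][2] == start:
                out[-1] = (chrom, out[-1][1], end)
            else:
                out.append((chrom, start, end))
        return out

    def autozygosity(
        self,
        individual: int,
        min_length_bp: int = 0,
        genome_length_bp: int | None = None,
        merge_adjacent: bool = True,
    ) -> float:
        """HBD-covered genome fraction, optionally restricted to HBD
        stretches of at least ``min_length_bp``."""
        if genome_length_bp is None:
            genome_length_bp = sum(
                end - start
                for _, start, end, _ in self.segments[individual]
            )
        covered = sum(
            end - start
            for _, start, end in self.hbd_intervals(individual, merge_adjacent)
            if end - start >= min_length_bp
        )
        return covered / genome_length_bp

    def to_bed(self, path: str | Path, ids: Sequence[str] | None = None) -> None:
        """Write all truth segments as 0-based half-open BED records."""
        lines = []
        for i, segs in enumerate(self.segments):
            name = ids[i] if ids is not None else f"ind{i:04d}"
            for chrom, start, end, cls in segs:
                label = "nonHBD" if cls == NON_HBD else f"HBD{cls}"
                lines.append(f"{chrom}\t{start}\t{end}\t{name}:{label}")
        Path(path).write_text("\n".join(lines) + "\n")


def _draw_segments(rng, config: SimulationConfig, truth_lengths):
    """Tile one chromosome with (start_bp, end_bp, class_index) segments."""
    mixing = np.asarray(config.mixing, dtype=float)
    rates = np.asarray(config.rates, dtype=float)
    n_classes = len(rates)
    non_hbd_index = n_classes - 1
    bp_per_morgan = 1.0 / config.morgans_per_bp
    length = config.chrom_length_bp
    segs = []
    pos = 0
    while pos < length:
        cls = int(rng.choice(n_classes, p=mixing))
        seg_morgans = rng.exponential(1.0 / rates[cls])
        truth_lengths.setdefault(cls, []).append(seg_morgans)
        seg_bp = max(1, int(round(seg_morgans * bp_per_morgan)))
        end = min(pos + seg_bp, length)
        label = NON_HBD if cls == non_hbd_index else cls
        segs.append((pos, end, label))
        pos = end
    return segs


def simulate_mosaic_population(
    config: SimulationConfig,
    n_individuals: int,
    breed: str = "SIM",
    allele_freq: np.ndarray | None = None,
) -> tuple[GenotypeDataset, TruthTrack]:
    """Simulate a population of HBD/non-HBD mosaic genomes.

    Identical ``config`` (including seed) yields identical output.  An
    explicit per-marker ``allele_freq`` vector overrides the config's
    frequency distribution (useful for simulating diverged breeds that share
    a marker panel).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_chrom = config.n_chromosomes
    m_per = config.n_markers_per_chrom
    n_markers = n_chrom * m_per

    spacing = config.chrom_length_bp / m_per
    pos_one = np.round((np.arange(m_per) + 0.5) * spacing).astype(np.int64)
    chrom_col = np.repeat(np.arange(1, n_chrom + 1), m_per)
    pos_col = np.tile(pos_one, n_chrom)
    snp_ids = np.array(
        [f"snp_{c}_{i}" for c in range(1, n_chrom + 1) for i in range(m_per)],
        dtype=object,
    )
    marker_map = MarkerMap(
        chromosome=chrom_col,
        snp_id=snp_ids,
        position_bp=pos_col,
        morgans_per_bp=config.morgans_per_bp,
    )

    if allele_freq is None:
        freq = rng.uniform(config.freq_low, config.freq_high, size=n_markers)
        mono = rng.random(n_markers) < config.monomorphic_fraction
        freq = np.where(mono, 1.0, freq)
    else:
        freq = np.asarray(allele_freq, dtype=float)
        if freq.shape != (n_markers,):
            raise ValueError("allele_freq length must equal total marker count")

    genome_length = n_chrom * config.chrom_length_bp
    genotypes = np.empty((n_individuals, n_markers), dtype=np.int8)
    all_segments: list[list[tuple[int, int, int, int]]] = []
    realized = np.empty(n_individuals)
    sampled_lengths: dict[int, list[float]] = {}

    for ind in range(n_individuals):
        segs_ind: list[tuple[int, int, int, int]] = []
        hbd_bp = 0
        is_hbd = np.zeros(n_markers, dtype=bool)
        for c in range(n_chrom):
            segs = _draw_segments(rng, config, sampled_lengths)
            offset = c * m_per
            for start, end, cls in segs:
                segs_ind.append((c + 1, start, end, cls))
                if cls != NON_HBD:
                    hbd_bp += end - start
                    lo = offset + np.searchsorted(pos_one, start, side="left")
                    hi = offset + np.searchsorted(pos_one, end, side="left")
                    is_hbd[lo:hi] = True
        all_segments.append(segs_ind)
        realized[ind] = hbd_bp / genome_length

        u = rng.random(n_markers)
        # HBD: copy one allele drawn at frequency f -> hom codes only
        g_hbd = np.where(u < freq, 0, 2).astype(np.int8)
        # non-HBD: Hardy-Weinberg draw
        g_hw = np.select(
            [u < freq**2, u < freq**2 + 2 * freq * (1 - freq)], [0, 1], default=2
        ).astype(np.int8)
        g = np.where(is_hbd, g_hbd, g_hw)

        if config.genotyping_error > 0:
            flip = rng.random(n_markers) < config.genotyping_error
            shift = rng.integers(1, 3, size=n_markers)  # one of the 2 other codes
            g = np.where(flip, (g + shift) % 3, g).astype(np.int8)
        if config.missing_rate > 0:
            g = np.where(rng.random(n_markers) < config.missing_rate, MISSING, g)
        genotypes[ind] = g

    ids = np.asarray([f"{breed}_{i:04d}" for i in range(n_individuals)], dtype=object)
    breeds = np.asarray([breed] * n_individuals, dtype=object)
    ds = GenotypeDataset(map=marker_map, ids=ids, breeds=breeds, genotypes=genotypes)
    n_hbd_classes = len(config.rates) - 1
    truth = TruthTrack(
        segments=all_segments,
        realized_autozygosity=realized,
        allele_freq=freq,
        hbd_class_count=n_hbd_classes,
        sampled_lengths=sampled_lengths,
    )
    return ds, truth


def simulate_breeds(
    config: SimulationConfig,
    breed_sizes: dict[str, int],
    freq_low: float = 0.05,
    freq_high: float = 0.95,
) -> GenotypeDataset:
    """Simulate several diverged breeds sharing one marker panel.

    Each breed gets an independent per-marker frequency vector drawn
    Uniform(freq_low, freq_high); independent drift histories make the
    breed frequency profiles well separated, which is all the population
    structure analyses need.
    """
    rng = np.random.default_rng(config.seed)
    n_markers = config.n_chromosomes * config.n_markers_per_chrom
    parts = []
    for k, (breed, n) in enumerate(breed_sizes.items()):
        freq = rng.uniform(freq_low, freq_high, size=n_markers)
        sub_config = SimulationConfig(**{**vars(config), "seed": config.seed + 1 + k})
        ds_b, _ = simulate_mosaic_population(sub_config, n, breed=breed, allele_freq=freq)
        parts.append(ds_b)
    base = parts[0]
    genotypes = np.vstack([p.genotypes for p in parts])
    ids = np.concatenate([p.ids for p in parts])
    breeds = np.concatenate([p.breeds for p in parts])
    return GenotypeDataset(map=base.map, ids=ids, breeds=breeds, genotypes=genotypes)


def plant_roh(
    ds: GenotypeDataset,
    placements: Sequence[tuple[str | int, int, int, int]],
) -> GenotypeDataset:
    """Force maximal homozygous runs at given intervals.

    Every marker inside each ``(individual, chromosome, start_bp, end_bp)``
    closed interval is set homozygous (code 0) and the markers immediately
    flanking the interval are set heterozygous, so the planted run cannot
    extend beyond its boundaries.
    """
    genotypes = ds.genotypes.copy()
    seen: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for individual, chrom, start_bp, end_bp in placements:
        idx = (
            ds.index_of(individual) if isinstance(individual, str) else int(individual)
        )
        if start_bp > end_bp:
            raise ValueError(f"interval start {start_bp} > end {end_bp}")
        for s, e in seen.get((idx, chrom), []):
            if start_bp <= e and s <= end_bp:
                raise ValueError(
                    f"overlapping placements for individual {ds.ids[idx]} "
                    f"on chromosome {chrom}"
                )
        seen.setdefault((idx, chrom), []).append((start_bp, end_bp))

        on_chrom = np.flatnonzero(ds.map.chromosome == chrom)
        pos = ds.map.position_bp[on_chrom]
        lo = np.searchsorted(pos, start_bp, side="left")
        hi = np.searchsorted(pos, end_bp, side="right")
        genotypes[idx, on_chrom[lo:hi]] = 0
        if lo > 0:
            genotypes[idx, on_chrom[lo - 1]] = 1
        if hi < len(on_chrom):
            genotypes[idx, on_chrom[hi]] = 1
    return GenotypeDataset(
        map=ds.map,
        ids=ds.ids.copy(),
        breeds=ds.breeds.copy(),
        genotypes=genotypes,
        allele1=ds.allele1.copy(),
        allele2=ds.allele2.copy(),
    )
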
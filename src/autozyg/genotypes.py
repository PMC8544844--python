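"""Genotype container, PLINK-text I/O and marker characterization.

The central object is :class:`GenotypeDataset`: a marker map, a table of
individuals with breed labels, and an ``n_individuals x n_markers`` matrix of
genotype codes (0 = homozygous for the first-seen allele, 1 = heterozygous,
2 = homozygous for the alternate allele, -1 = missing).  All downstream
analyses (ROH scanning, IBS distances, the HBD mixture model) consume this
object.

Marker quality control follows the minimal convention of low-density-chip
autozygosity studies: restrict to a declared autosome set and apply *no*
MAF or LD pruning, because both remove exactly the homozygous stretches the
analyses look for.  Characterization of the minor-allele-frequency spectrum
(including monomorphic markers and their sharing between breeds) is provided
because an excess of shared monomorphic markers can inflate apparent
homozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1
GENOTYPE_CODES = (0, 1, 2, MISSING)

#: default physical-to-genetic map scaling: 1 cM per Mbp, i.e. 1e-8 Morgan/bp
MORGANS_PER_BP = 1e-8

#: cattle autosome labels
BOVINE_AUTOSOMES = frozenset(range(1, 30))


class PlinkParseError(ValueError):
    """Raised when a PED/MAP file does not conform to the text dialect."""


@dataclass(frozen=True)
class MarkerMap:
    """Positions and identifiers of the genotyped markers.

    ``genetic_pos_morgan`` is derived from the physical position with the
    1 cM/Mbp constant rather than read from the MAP file's cM column, which
    is typically zero-filled on array data.
    """

    chromosome: np.ndarray  # int
    snp_id: np.ndarray  # str
    position_bp: np.ndarray  # int
    morgans_per_bp: float = MORGANS_PER_BP

    def __post_init__(self) -> None:
        n = len(self.snp_id)
        if not (len(self.chromosome) == len(self.position_bp) == n):
            raise ValueError("marker map columns have unequal lengths")
        if len(np.unique(self.snp_id)) != n:
            ids, counts = np.unique(self.snp_id, return_counts=True)
            dup = ids[counts > 1][:5]
            raise PlinkParseError(f"duplicate snp_id(s): {', '.join(map(str, dup))}")
        for chrom in np.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.snp_id)

    @property
    def genetic_pos_morgan(self) -> np.ndarray:
        return self.position_bp * self.morgans_per_bp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "snp_id": self.snp_id,
                "position_bp": self.position_bp,
                "genetic_pos_morgan": self.genetic_pos_morgan,
            }
        )


@dataclass
class GenotypeDataset:
    """Marker map + individuals + genotype code matrix.

    ``allele1``/``allele2`` keep the per-marker allele labels so that a
    written PED file round-trips; code 0 is homozygous ``allele1``.
    """

    map: MarkerMap
    ids: np.ndarray  # str, per individual
    breeds: np.ndarray  # str, per individual
    genotypes: np.ndarray  # int8, n_individuals x n_markers
    allele1: np.ndarray | None = None
    allele2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.ids), self.map.n_markers):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.ids)} individuals x {self.map.n_markers} markers"
            )
        bad = ~np.isin(self.genotypes, GENOTYPE_CODES)
        if bad.any():
            raise ValueError("genotype codes outside {0, 1, 2, missing}")
        if any(not b for b in self.breeds):
            raise ValueError("breed labels must be non-empty")
        if self.allele1 is None:
            self.allele1 = np.full(self.map.n_markers, "A", dtype=object)
        if self.allele2 is None:
            self.allele2 = np.full(self.map.n_markers, "B", dtype=object)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return self.map.n_markers

    @property
    def breed_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.breeds:
            seen.setdefault(b, None)
        return list(seen)

    def individuals_of(self, breed: str) -> np.ndarray:
        idx = np.flatnonzero(self.breeds == breed)
        if idx.size == 0:
            raise KeyError(f"breed {breed!r} not present")
        return idx

    def index_of(self, individual_id: str) -> int:
        hits = np.flatnonzero(self.ids == individual_id)
        if hits.size != 1:
            raise KeyError(f"individual {individual_id!r} not found (or ambiguous)")
        return int(hits[0])

    def subset_markers(self, marker_idx: np.ndarray) -> "GenotypeDataset":
        marker_idx = np.asarray(marker_idx)
        new_map = MarkerMap(
            chromosome=self.map.chromosome[marker_idx],
            snp_id=self.map.snp_id[marker_idx],
            position_bp=self.map.position_bp[marker_idx],
            morgans_per_bp=self.map.morgans_per_bp,
        )
        return GenotypeDataset(
            map=new_map,
            ids=self.ids.copy(),
            breeds=self.breeds.copy(),
            genotypes=self.genotypes[:, marker_idx].copy(),
            allele1=self.allele1[marker_idx].copy(),
            allele2=self.allele2[marker_idx].copy(),
        )

    def genome_length_bp(self) -> int:
        """Map-covered autosomal length: sum over chromosomes of the span
        between the first and last marker."""
        total = 0
        for chrom in np.unique(self.map.chromosome):
            pos = self.map.position_bp[self.map.chromosome == chrom]
            total += int(pos[-1] - pos[0])
        return total


# ---------------------------------------------------------------------------
# PLINK text dialect


def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    breed_of: Mapping[str, str] | None = None,
    morgans_per_bp: float = MORGANS_PER_BP,
) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    Allele coding is per-marker first-seen: the first non-missing allele
    encountered while reading becomes allele1 (code 0 = hom allele1).  The
    "0" allele denotes a missing call ("0 0" pairs -> missing genotype).

    Parameters
    ----------
    breed_of
        Optional mapping from individual id to breed label.  When omitted the
        PED family id column is used as the breed.
    """
    map_path = Path(map_path)
    ped_path = Path(ped_path)

    chroms, snp_ids, positions = [], [], []
    for lineno, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 4:
            raise PlinkParseError(
                f"{map_path.name}:{lineno}: expected 4 MAP columns, got {len(fields)}"
            )
        chroms.append(int(fields[0]))
        snp_ids.append(fields[1])
        positions.append(int(fields[3]))
    n_markers = len(snp_ids)
    marker_map = MarkerMap(
        chromosome=np.asarray(chroms, dtype=np.int64),
        snp_id=np.asarray(snp_ids, dtype=object),
        position_bp=np.asarray(positions, dtype=np.int64),
        morgans_per_bp=morgans_per_bp,
    )

    ids: list[str] = []
    fids: list[str] = []
    rows: list[np.ndarray] = []
    allele1 = np.full(n_markers, None, dtype=object)
    allele2 = np.full(n_markers, None, dtype=object)

    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 6 + 2 * n_markers:
            raise PlinkParseError(
                f"{ped_path.name}:{lineno}: expected {6 + 2 * n_markers} fields "
                f"(6 + 2 x {n_markers} markers), got {len(fields)}"
            )
        fids.append(fields[0])
        ids.append(fields[1])
        codes = np.empty(n_markers, dtype=np.int8)
        alleles = fields[6:]
        for m in range(n_markers):
            a, b = alleles[2 * m], alleles[2 * m + 1]
            if a == "0" or b == "0":
                codes[m] = MISSING
                continue
            for al in (a, b):
                if allele1[m] is None:
                    allele1[m] = al
                elif allele2[m] is None and al != allele1[m]:
                    allele2[m] = al
                elif al != allele1[m] and al != allele2[m]:
                    raise PlinkParseError(
                        f"{ped_path.name}:{lineno}: marker {snp_ids[m]} has >2 alleles"
                    )
            codes[m] = int(a != allele1[m]) + int(b != allele1[m])
        rows.append(codes)

    allele1[allele1 == None] = "A"  # noqa: E711 - markers never called
    allele2[allele2 == None] = "B"  # noqa: E711 - monomorphic markers

    ids_arr = np.asarray(ids, dtype=object)
    if breed_of is not None:
        unknown = [i for i in ids if i not in breed_of]
        if unknown:
            raise KeyError(
                "individuals missing from breed mapping: " + ", ".join(unknown[:10])
            )
        breeds = np.asarray([breed_of[i] for i in ids], dtype=object)
    else:
        breeds = np.asarray(fids, dtype=object)

    return GenotypeDataset(
        map=marker_map,
        ids=ids_arr,
        breeds=breeds,
        genotypes=np.vstack(rows) if rows else np.empty((0, n_markers), dtype=np.int8),
        allele1=allele1,
        allele2=allele2,
    )


def write_plink_text(
    ds: GenotypeDataset, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write PED/MAP files that round-trip through :func:`read_plink_text`."""
    map_lines = []
    for chrom, sid, bp in zip(ds.map.chromosome, ds.map.snp_id, ds.map.position_bp):
        map_lines.append(f"{chrom}\t{sid}\t0\t{bp}")
    Path(map_path).write_text("\n".join(map_lines) + "\n")

    ped_lines = []
    for i in range(ds.n_individuals):
        fields = [str(ds.breeds[i]), str(ds.ids[i]), "0", "0", "0", "-9"]
        g = ds.genotypes[i]
        for m in range(ds.n_markers):
            if g[m] == MISSING:
                fields += ["0", "0"]
            elif g[m] == 0:
                fields += [str(ds.allele1[m])] * 2
            elif g[m] == 2:
                fields += [str(ds.allele2[m])] * 2
            else:
                # lexicographic order keeps het pairs byte-stable across
                # re-reads, where first-seen allele coding may flip a1/a2
                fields += sorted((str(ds.allele1[m]), str(ds.allele2[m])))
        ped_lines.append(" ".join(fields))
    Path(ped_path).write_text("\n".join(ped_lines) + "\n")


# ---------------------------------------------------------------------------
# QC and MAF characterization


def filter_autosomes(
    ds: GenotypeDataset, autosomes: Iterable[int] = BOVINE_AUTOSOMES
) -> GenotypeDataset:
    """Keep only markers on the declared autosomes, preserving marker order."""
    autosomes = set(autosomes)
    if not autosomes:
        raise ValueError("autosome set is empty")
    keep = np.flatnonzero(np.isin(ds.map.chromosome, list(autosomes)))
    if keep.size == 0:
        raise ValueError("no autosomal markers remain after filtering")
    return ds.subset_markers(keep)


def allele_frequencies(
    ds: GenotypeDataset, breed: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker allele1 frequency and called-genotype count.

    Returns ``(freq_a1, n_called)``; markers with no called genotype get
    ``freq_a1 = nan`` (flagged, not an error).
    """
    if breed is None:
        g = ds.genotypes
    else:
        g = ds.genotypes[ds.individuals_of(breed)]
    called = g != MISSING
    n_called = called.sum(axis=0)
    n_a1 = np.where(called, 2 - g, 0).sum(axis=0)  # code 0 -> 2 copies, 1 -> 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, n_a1 / (2.0 * n_called), np.nan)
    return freq, n_called


MAF_CLASS_LABELS = ("monomorphic", "0-0.005", "0.005-0.01", "0.01-0.05", ">0.05")


def classify_maf(
    freqs: np.ndarray, boundaries: Sequence[float] = (0.005, 0.01, 0.05)
) -> pd.Series:
    """Count markers per minor-allele-frequency class.

    Classes are ``{0}``, ``(0, b1]``, ``(b1, b2]``, ``(b2, b3]``, ``(b3, 0.5]``
    plus ``unclassified`` for markers with no called genotype (nan frequency).
    """
    boundaries = tuple(boundaries)
    if list(boundaries) != sorted(boundaries) or not (
        0 < boundaries[0] and boundaries[-1] < 0.5
    ):
        raise ValueError("boundaries must be strictly increasing within (0, 0.5)")
    freqs = np.asarray(freqs, dtype=float)
    maf = np.minimum(freqs, 1.0 - freqs)
    counts = dict.fromkeys(MAF_CLASS_LABELS + ("unclassified",), 0)
    counts["unclassified"] = int(np.isnan(maf).sum())
    ok = maf[~np.isnan(maf)]
    counts["monomorphic"] = int((ok == 0).sum())
    edges = (0.0,) + boundaries + (0.5,)
    for lab, lo, hi in zip(MAF_CLASS_LABELS[1:], edges[:-1], edges[1:]):
        counts[lab] = int(((ok > lo) & (ok <= hi)).sum())
    return pd.Series(counts)


def maf_class_table(
    ds: GenotypeDataset, boundaries: Sequence[float] = (0.005, 0.01, 0.05)
) -> pd.DataFrame:
    """MAF class counts per breed (rows = classes, columns = breeds)."""
    table = {}
    for breed in ds.breed_names:
        freqs, _ = allele_frequencies(ds, breed)
        table[breed] = classify_maf(freqs, boundaries)
    return pd.DataFrame(table)


def monomorphic_markers(ds: GenotypeDataset, breed: str) -> np.ndarray:
    """Indices of markers with MAF exactly 0 in the breed (among called)."""
    freqs, n_called = allele_frequencies(ds, breed)
    maf = np.minimum(freqs, 1 - freqs)
    return np.flatnonzero((n_called > 0) & (maf == 0))


def monomorphic_sharing(
    ds: GenotypeDataset, same_allele: bool = False
) -> pd.DataFrame:
    """Breed x breed matrix of (shared) monomorphic marker counts.

    Diagonal holds each breed's monomorphic count; off-diagonal the size of
    the pairwise intersection.  A marker counts as shared when it has MAF 0
    in both breeds; with ``same_allele=True`` the fixed allele must also be
    the same one.
    """
    breeds = ds.breed_names
    mono_sets = {}
    fixed_allele = {}
    for b in breeds:
        idx = monomorphic_markers(ds, b)
        mono_sets[b] = set(idx.tolist())
        freqs, _ = allele_frequencies(ds, b)
        fixed_allele[b] = {int(m): (0 if freqs[m] == 1.0 else 2) for m in idx}
    out = pd.DataFrame(0, index=breeds, columns=breeds, dtype=int)
    for i, bi in enumerate(breeds):
        for j, bj in enumerate(breeds):
            common = mono_sets[bi] & mono_sets[bj]
            if same_allele and i != j:
                common = {
                    m for m in common if fixed_allele[bi][m] == fixed_allele[bj][m]
                }
            out.loc[bi, bj] = len(common)
    return out


def monomorphic_by_chromosome(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-breed count of monomorphic markers on each chromosome."""
    chroms = np.unique(ds.map.chromosome)
    out = pd.DataFrame(0, index=ds.breed_names, columns=chroms, dtype=int)
    for b in ds.breed_names:
        idx = monomorphic_markers(ds, b)
        chrom_of = ds.map.chromosome[idx]
        vals, counts = np.unique(chrom_of, return_counts=True)
        for c, n in zip(vals, counts):
            out.loc[b, c] = int(n)
    return out
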
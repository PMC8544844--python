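"""Population structure: genome-wide IBS distances with classical MDS, and
PCA on per-chromosome ROH counts.

The identity-by-state (IBS) distance between two individuals averages, over
jointly called markers, the allele-sharing mismatch: 0 for identical
genotypes, 0.5 when the pair shares exactly one allele (het vs hom), 1 for
opposite homozygotes.  Classical (Torgerson) multidimensional scaling of
that matrix gives a deterministic low-dimensional configuration; PCA of the
individuals x chromosomes ROH-count matrix summarizes how the chromosomal
distribution of runs differs between populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeDataset
from .roh import ROHSegment


@dataclass
class DistanceMatrix:
    values: np.ndarray  # n x n, symmetric, zero diagonal, entries in [0, 1]
    ids: np.ndarray
    n_markers_used: np.ndarray  # n x n int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # n x k
    eigenvalues: np.ndarray  # descending
    variance_explained: np.ndarray  # fraction per returned dimension
    ids: np.ndarray | None = None
    loadings: np.ndarray | None = None
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coordinates.shape[1])]
        idx = self.ids if self.ids is not None else np.arange(len(self.coordinates))
        return pd.DataFrame(self.coordinates, index=idx, columns=cols)


def ibs_distance_matrix(ds: GenotypeDataset) -> DistanceMatrix:
    """Pairwise IBS distance over pairwise-complete markers.

    distance = 1 - (#IBS2 + 0.5 #IBS1) / #jointly-called markers, which for
    codes {0,1,2} equals the mean of |g_i - g_j| / 2.
    """
    if ds.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    g = ds.genotypes.astype(np.float64)
    called = ds.genotypes != MISSING
    g[~called] = 0.0
    n = ds.n_individuals
    dist = np.zeros((n, n))
    used = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = called[i] & called[i + 1 :]
        diff = np.abs(g[i] - g[i + 1 :]) * both
        cnt = both.sum(axis=1)
        zero = cnt == 0
        if zero.any():
            j = i + 1 + int(np.flatnonzero(zero)[0])
            raise ValueError(
                f"no jointly called markers for pair ({ds.ids[i]}, {ds.ids[j]})"
            )
        d = diff.sum(axis=1) / (2.0 * cnt)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
        used[i, i + 1 :] = cnt
        used[i + 1 :, i] = cnt
        used[i, i] = int(called[i].sum())
    return DistanceMatrix(values=dist, ids=ds.ids.copy(), n_markers_used=used)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (deterministic
    orientation; eigenvectors are otherwise sign-ambiguous)."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            out[:, k] = -col
    return out


def classical_mds(dist: DistanceMatrix | np.ndarray, k: int = 3) -> EmbeddingResult:
    """Torgerson metric MDS: double-center the squared distances, then
    eigendecompose; coordinates are top-k eigenvectors scaled by the square
    root of their (positive) eigenvalues."""
    if isinstance(dist, DistanceMatrix):
        values, ids = dist.values, dist.ids
    else:
        values, ids = np.asarray(dist, dtype=float), None
    n = values.shape[0]
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than n = {n}")
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b_mat = -0.5 * j_mat @ (values**2) @ j_mat
    eigvals, eigvecs = np.linalg.eigh(b_mat)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    top_vals = eigvals[:k]
    scale = np.sqrt(np.clip(top_vals, 0.0, None))
    coords = _fix_signs(eigvecs[:, :k]) * scale
    positive = eigvals[eigvals > 0]
    total = positive.sum() if positive.size else 1.0
    var_frac = np.clip(top_vals, 0.0, None) / total
    return EmbeddingResult(
        coordinates=coords,
        eigenvalues=eigvals,
        variance_explained=var_frac,
        ids=ids,
    )


def roh_count_matrix(
    segments: Sequence[ROHSegment], ds: GenotypeDataset, by_breed: bool = False
) -> pd.DataFrame:
    """ROH counts per chromosome, one row per individual (or per breed when
    ``by_breed`` is set)."""
    chroms = list(np.unique(ds.map.chromosome))
    counts = pd.DataFrame(0, index=list(ds.ids), columns=chroms, dtype=float)
    for s in segments:
        counts.loc[s.individual_id, s.chromosome] += 1
    if by_breed:
        counts["__breed"] = ds.breeds
        counts = counts.groupby("__breed").mean()
        counts.index.name = "breed"
    return counts


def pca_roh_counts(counts: pd.DataFrame | np.ndarray, k: int | None = None) -> EmbeddingResult:
    """PCA of the ROH-count matrix: column-center (no scaling), SVD.

    Scores are in ``coordinates``, right singular vectors in ``loadings``;
    a constant input matrix is flagged ``degenerate`` with zero variance.
    """
    if isinstance(counts, pd.DataFrame):
        ids = np.asarray(counts.index, dtype=object)
        x = counts.to_numpy(dtype=float)
    else:
        ids = None
        x = np.asarray(counts, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if k is None:
        k = len(s)
    k = min(k, len(s))
    total = (s**2).sum()
    degenerate = total <= 1e-12
    var_frac = np.zeros(k) if degenerate else (s[:k] ** 2) / total
    signs = np.ones(k)
    scores = u[:, :k] * s[:k]
    fixed = _fix_signs(scores)
    signs = np.where((fixed == scores).all(axis=0), 1.0, -1.0)
    return EmbeddingResult(
        coordinates=fixed,
        eigenvalues=s**2 / max(x.shape[0] - 1, 1),
        variance_explained=var_frac,
        ids=ids,
        loadings=vt[:k].T * signs,
        degenerate=degenerate,
    )
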
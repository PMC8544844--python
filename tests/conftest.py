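import numpy as np
import pytest

from autozyg import GenotypeDataset, MarkerMap


def make_dataset(genotypes, chrom=None, positions=None, breeds=None, spacing=100_000):
    """Small GenotypeDataset from a genotype matrix (rows = individuals)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_markers = genotypes.shape
    if chrom is None:
        chrom = np.ones(n_markers, dtype=np.int64)
    if positions is None:
        positions = (np.arange(n_markers, dtype=np.int64) + 1) * spacing
    mmap = MarkerMap(
        chromosome=np.asarray(chrom, dtype=np.int64),
        snp_id=np.asarray([f"snp{i}" for i in range(n_markers)], dtype=object),
        position_bp=np.asarray(positions, dtype=np.int64),
    )
    if breeds is None:
        breeds = ["B1"] * n_ind
    return GenotypeDataset(
        map=mmap,
        ids=np.asarray([f"ind{i}" for i in range(n_ind)], dtype=object),
        breeds=np.asarray(breeds, dtype=object),
        genotypes=genotypes,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)
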
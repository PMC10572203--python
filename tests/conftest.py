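import numpy as np
import pytest

import rohmix
from rohmix.markers import MarkerMap


@pytest.fixture(scope="session")
def dense_map():
    """3 chromosomes × 1600 SNPs over 40 Mb each (~25 kb spacing): dense
    enough to satisfy the 1-SNP-per-100 kb ROH density criterion."""
    return rohmix.gen_marker_map(3, 1600, 40_000_000, "uniform", seed=11)


@pytest.fixture(scope="session")
def map5k():
    """18 autosomes × 278 SNPs ≈ 5K genome-wide, GBC panel scale."""
    return rohmix.gen_marker_map(18, 278, 125_000_000, "uniform", seed=12)


@pytest.fixture(scope="session")
def freqs5k(map5k):
    return rohmix.gen_breed_frequencies(map5k, seed=13)


def evenly_spaced_map(n_snps: int, spacing_bp: int, n_chrom: int = 1) -> MarkerMap:
    """Exactly regular single- or multi-chromosome map starting at 1."""
    pos = 1 + spacing_bp * np.arange(n_snps)
    return MarkerMap(
        np.array([f"c{c}s{i}" for c in range(1, n_chrom + 1) for i in range(n_snps)], dtype=object),
        np.repeat(np.arange(1, n_chrom + 1), n_snps),
        np.tile(pos, n_chrom),
    )
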
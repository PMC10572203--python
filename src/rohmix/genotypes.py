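"""Genotype matrix container: animals × SNPs allele-A dosage codes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markers import MarkerMap

#: Sentinel for a missing genotype call in the int8 dosage matrix.
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Diploid genotypes coded as counts of allele A.

    ``dosage[i, k]`` is the number of A alleles (0, 1 or 2) carried by animal
    ``i`` at SNP ``k``, or :data:`MISSING` (−1) for a failed call.  Columns
    are aligned with ``markers``.
    """

    animal_ids: np.ndarray
    markers: MarkerMap
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (animals × SNPs)")
        n, m = self.dosage.shape
        if n != len(self.animal_ids):
            raise ValueError("row count must equal number of animal ids")
        if m != len(self.markers):
            raise ValueError("column count must equal marker map length")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage codes must be in {0, 1, 2, missing}")

    @property
    def n_animals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def subset(self, animals: np.ndarray | None = None, snps: np.ndarray | None = None) -> "GenotypeMatrix":
        ids, mk, d = self.animal_ids, self.markers, self.dosage
        if animals is not None:
            ids = ids[animals]
            d = d[animals, :]
        if snps is not None:
            mk = mk.subset(snps)
            d = d[:, snps]
        return GenotypeMatrix(ids, mk, d)

    def allele_a_frequency(self) -> np.ndarray:
        """Observed allele-A frequency per SNP over non-missing calls (NaN if none)."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0
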
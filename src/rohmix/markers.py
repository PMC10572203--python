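"""Marker map container: SNP identifiers with autosomal chromosome/position."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MarkerMap:
    """Ordered autosomal SNP map.

    Markers are sorted by (chromosome, position); positions are 1-based base
    pairs and must be strictly increasing within a chromosome.  Sex
    chromosomes are not represented — analyses here are autosome-only.
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.position = np.asarray(self.position, dtype=np.int64)
        if not (len(self.snp_id) == len(self.chromosome) == len(self.position)):
            raise ValueError("snp_id, chromosome and position must be equal length")
        if np.any(self.chromosome < 1):
            raise ValueError("chromosome codes must be positive (autosomes only)")
        if np.any(self.position < 1):
            raise ValueError("positions must be 1-based positive integers")
        # sorted by (chrom, pos), strictly increasing within chromosome
        order_ok = np.all(np.diff(self.chromosome) >= 0)
        if not order_ok:
            raise ValueError("markers must be sorted by chromosome")
        same = np.diff(self.chromosome) == 0
        if np.any(same & (np.diff(self.position) <= 0)):
            raise ValueError("positions must be strictly increasing within a chromosome")

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def chromosomes(self) -> np.ndarray:
        """Distinct chromosome codes, ascending."""
        return np.unique(self.chromosome)

    def chrom_slice(self, chrom: int) -> slice:
        """Contiguous index slice of markers on one chromosome."""
        lo = int(np.searchsorted(self.chromosome, chrom, side="left"))
        hi = int(np.searchsorted(self.chromosome, chrom, side="right"))
        return slice(lo, hi)

    def subset(self, index: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.snp_id[index], self.chromosome[index], self.position[index])

    def chrom_spans(self) -> dict[int, tuple[int, int]]:
        """Per chromosome: (first SNP position, last SNP position)."""
        out = {}
        for c in self.chromosomes:
            s = self.chrom_slice(int(c))
            out[int(c)] = (int(self.position[s][0]), int(self.position[s][-1]))
        return out

    def snp_covered_length(self) -> int:
        """Sum over chromosomes of (last − first + 1) bp: the SNP-covered autosome."""
        return sum(hi - lo + 1 for lo, hi in self.chrom_spans().values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_id, "chromosome": self.chromosome, "position": self.position}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMap":
        return cls(
            df["snp_id"].to_numpy(dtype=object),
            df["chromosome"].to_numpy(),
            df["position"].to_numpy(),
        )
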
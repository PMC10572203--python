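"""Runs-of-homozygosity (ROH) detection from dosage genotypes.

The scanner follows the classic sliding-window recipe: a fixed-size window
of consecutive SNPs slides one SNP at a time along each chromosome of each
animal; a window is a "hit" when it contains at most a small number of
heterozygous and missing calls.  Each SNP is scored by the fraction of
overlapping windows that are hits, SNPs scoring above a threshold (and not
themselves heterozygous) become ROH-eligible, and maximal runs of eligible
SNPs — split at large inter-marker gaps — are kept as segments when they
are long enough, dense enough, and contain enough homozygous SNPs.

Defaults: 50-SNP window with ≤1 heterozygote and ≤2 missing calls allowed,
minimum segment length 1 Mb, at least 50 homozygous SNPs, at least one SNP
per 100 kb on average, and a 1 Mb maximum gap between consecutive SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = ["ROHParams", "ROHSegment", "window_scan", "call_segments", "detect_roh",
           "segments_to_frame"]


@dataclass(frozen=True)
class ROHParams:
    min_length_bp: int = 1_000_000
    min_snps: int = 50  # minimum homozygous SNPs in a segment
    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 2
    min_density_bp_per_snp: int = 100_000  # ≥1 SNP per 100 kb on average
    max_gap_bp: int = 1_000_000
    window_hit_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_length_bp", "min_snps", "window_snps",
                     "min_density_bp_per_snp", "max_gap_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.window_hit_fraction <= 1:
            raise ValueError("window_hit_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run in one animal."""

    animal: str
    chromosome: int
    start: int  # bp, 1-based inclusive
    end: int
    n_snps: int  # SNPs spanned by the run
    n_homozygous: int

    @property
    def length(self) -> int:
        """Length in bp, end − start + 1."""
        return self.end - self.start + 1

    @property
    def length_mb(self) -> float:
        return self.length / 1e6


def window_scan(genotypes: np.ndarray, params: ROHParams = ROHParams()) -> np.ndarray:
    """Per-SNP hit fraction for one animal on one chromosome.

    A window is a hit when its heterozygote count ≤ ``max_het_per_window``
    and its missing count ≤ ``max_missing_per_window``.  Each SNP's score is
    the proportion of hit windows among those that cover it; SNPs near
    chromosome ends simply use the windows that exist.  A chromosome shorter
    than the window is scanned as a single truncated window.
    """
    g = np.asarray(genotypes)
    n = len(g)
    if n == 0:
        return np.empty(0)
    w = min(params.window_snps, n)  # truncated single window when n < window
    het = (g == 1).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)

    def sliding(a):
        c = np.concatenate([[0], np.cumsum(a)])
        return c[w:] - c[:-w]  # sums of each length-w window

    hits = (sliding(het) <= params.max_het_per_window) & (
        sliding(mis) <= params.max_missing_per_window
    )
    n_win = n - w + 1
    h = np.concatenate([[0], np.cumsum(hits.astype(np.int64))])
    i = np.arange(n)
    first = np.maximum(0, i - w + 1)
    last = np.minimum(i, n_win - 1)
    # SNPs past the last window start (possible only if w was truncated away)
    first = np.minimum(first, n_win - 1)
    covering = last - first + 1
    hit_cover = h[last + 1] - h[first]
    return hit_cover / covering


def call_segments(
    hit_fractions: np.ndarray,
    genotypes: np.ndarray,
    positions: np.ndarray,
    params: ROHParams = ROHParams(),
    animal: str = "",
    chromosome: int = 0,
) -> list[ROHSegment]:
    """Assemble ROH segments from per-SNP hit fractions on one chromosome."""
    g = np.asarray(genotypes)
    pos = np.asarray(positions, dtype=np.int64)
    frac = np.asarray(hit_fractions, dtype=float)
    if not (len(g) == len(pos) == len(frac)):
        raise ValueError("hit fractions, genotypes and positions must align")
    eligible = (frac >= params.window_hit_fraction) & (g != 1)
    segments: list[ROHSegment] = []
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return segments
    # maximal runs of consecutive eligible SNPs, split at large bp gaps
    breaks = np.flatnonzero((np.diff(idx) > 1) | (np.diff(pos[idx]) > params.max_gap_bp))
    for run in np.split(idx, breaks + 1):
        start, end = int(pos[run[0]]), int(pos[run[-1]])
        length = end - start + 1
        n_snps = len(run)
        n_hom = int(np.sum((g[run] == 0) | (g[run] == 2)))
        if length < params.min_length_bp:
            continue
        if n_hom < params.min_snps:
            continue
        if length / n_snps > params.min_density_bp_per_snp:
            continue
        segments.append(ROHSegment(animal, chromosome, start, end, n_snps, n_hom))
    return segments


def detect_roh(gm: GenotypeMatrix, params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """All ROH segments in a genotype matrix, ordered (animal, chrom, start)."""
    out: list[ROHSegment] = []
    for i, aid in enumerate(gm.animal_ids):
        for c in gm.markers.chromosomes:
            s = gm.markers.chrom_slice(int(c))
            g = gm.dosage[i, s]
            frac = window_scan(g, params)
            out.extend(
                call_segments(frac, g, gm.markers.position[s], params,
                              animal=str(aid), chromosome=int(c))
            )
    return out


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """Tab-friendly segment table (PLINK .hom essentials)."""
    return pd.DataFrame(
        [
            {
                "animal": s.animal,
                "chromosome": s.chromosome,
                "start": s.start,
                "end": s.end,
                "n_snps": s.n_snps,
                "n_homozygous": s.n_homozygous,
                "length_mb": round(s.length_mb, 2),
            }
            for s in segments
        ],
        columns=["animal", "chromosome", "start", "end", "n_snps", "n_homozygous", "length_mb"],
    )


def segments_from_frame(df: pd.DataFrame) -> list[ROHSegment]:
    return [
        ROHSegment(
            str(r.animal), int(r.chromosome), int(r.start), int(r.end),
            int(r.n_snps), int(r.n_homozygous),
        )
        for r in df.itertuples()
    ]
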
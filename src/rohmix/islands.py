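"""ROH islands: shared-autozygosity hotspots across a population.

For every SNP, the incidence is the percentage of animals whose ROH cover
its position.  SNPs in the top fraction (default 1%) of incidence qualify,
and maximal runs of map-adjacent qualifying SNPs are merged into islands —
candidate selective-sweep regions.  Islands can then be intersected with
user-supplied annotation intervals (BED or GFF3: genes, QTL) to list the
features they contain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import MarkerMap
from .roh import ROHSegment

__all__ = [
    "ROHIsland",
    "snp_incidence",
    "island_threshold",
    "merge_islands",
    "read_intervals",
    "annotate_islands",
]


@dataclass(frozen=True)
class ROHIsland:
    chromosome: int
    start: int  # bp of first qualifying SNP
    end: int  # bp of last qualifying SNP
    n_snps: int

    @property
    def length_mb(self) -> float:
        return (self.end - self.start + 1) / 1e6


def snp_incidence(
    segments: list[ROHSegment], marker_map: MarkerMap, n_animals: int
) -> pd.DataFrame:
    """Per-SNP count and percentage of animals with an ROH covering it.

    A SNP counts for an animal iff its position lies within [start, end] of
    any of that animal's segments (scanner segments never overlap within an
    animal, so each animal contributes at most once per SNP).
    """
    if n_animals <= 0:
        raise ValueError("n_animals must be positive")
    diff = np.zeros(len(marker_map) + 1, dtype=np.int64)
    for s in segments:
        sl = marker_map.chrom_slice(s.chromosome)
        pos = marker_map.position[sl]
        lo = sl.start + int(np.searchsorted(pos, s.start, side="left"))
        hi = sl.start + int(np.searchsorted(pos, s.end, side="right"))
        diff[lo] += 1
        diff[hi] -= 1
    count = np.cumsum(diff[:-1])
    return pd.DataFrame(
        {
            "snp_id": marker_map.snp_id,
            "chromosome": marker_map.chromosome,
            "position": marker_map.position,
            "count": count,
            "incidence_pct": 100.0 * count / n_animals,
        }
    )


def island_threshold(incidence_pct: np.ndarray, top_fraction: float = 0.01) -> float:
    """Incidence percentage at the (1 − top_fraction) empirical quantile.

    Linear interpolation between order statistics; SNPs at or above the
    returned value qualify for island membership.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    v = np.asarray(incidence_pct, dtype=float)
    if v.size == 0:
        raise ValueError("empty incidence set")
    return float(np.quantile(v, 1.0 - top_fraction))


def merge_islands(
    qualifying: np.ndarray,
    marker_map: MarkerMap,
    max_internal_gap_bp: int | None = None,
) -> list[ROHIsland]:
    """Merge map-adjacent qualifying SNPs into islands.

    ``qualifying`` is a boolean mask over the map.  By default a single
    below-threshold SNP breaks a run; ``max_internal_gap_bp`` optionally
    allows jumping over non-qualifying SNPs when the bp gap between
    consecutive qualifying SNPs is no larger than the allowance.
    """
    qualifying = np.asarray(qualifying, dtype=bool)
    if qualifying.shape != (len(marker_map),):
        raise ValueError("qualifying mask must align with the marker map")
    idx = np.flatnonzero(qualifying)
    if idx.size == 0:
        return []
    gap_idx = np.diff(idx)
    same_chrom = np.diff(marker_map.chromosome[idx]) == 0
    if max_internal_gap_bp is None:
        contiguous = gap_idx == 1
    else:
        contiguous = np.diff(marker_map.position[idx]) <= max_internal_gap_bp
    breaks = np.flatnonzero(~(contiguous & same_chrom))
    islands = []
    for run in np.split(idx, breaks + 1):
        islands.append(
            ROHIsland(
                chromosome=int(marker_map.chromosome[run[0]]),
                start=int(marker_map.position[run[0]]),
                end=int(marker_map.position[run[-1]]),
                n_snps=len(run),
            )
        )
    return islands


def islands_to_frame(islands: list[ROHIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": i.chromosome,
                "start": i.start,
                "end": i.end,
                "n_snps": i.n_snps,
                "length_mb": round(i.length_mb, 2),
            }
            for i in islands
        ],
        columns=["chromosome", "start", "end", "n_snps", "length_mb"],
    )


# ---------------------------------------------------------------------------
# annotation intervals


def read_intervals(path: str, fmt: str | None = None) -> pd.DataFrame:
    """Read annotation intervals from BED or GFF3 into 1-based inclusive form.

    BED is 0-based half-open and is normalized (start+1, end); GFF3 is
    already 1-based inclusive.  Returns columns chromosome (str), start,
    end, name.  Format is inferred from the extension unless given.
    """
    if fmt is None:
        low = str(path).lower()
        fmt = "gff3" if low.endswith((".gff", ".gff3")) else "bed"
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 3:
            raise ValueError("BED needs at least chrom, start, end")
        out = pd.DataFrame(
            {
                "chromosome": df[0].astype(str),
                "start": df[1].astype(int) + 1,  # 0-based half-open → 1-based incl.
                "end": df[2].astype(int),
                "name": df[3].astype(str) if df.shape[1] > 3 else "",
            }
        )
    elif fmt == "gff3":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=range(9), dtype=str)
        if df.shape[1] < 9:
            raise ValueError("GFF3 needs 9 tab-separated columns")

        def attr_name(attrs: str) -> str:
            for key in ("Name=", "ID="):
                for fieldv in str(attrs).split(";"):
                    if fieldv.startswith(key):
                        return fieldv[len(key):]
            return ""

        out = pd.DataFrame(
            {
                "chromosome": df[0].astype(str),
                "start": df[3].astype(int),
                "end": df[4].astype(int),
                "name": df[8].map(attr_name),
            }
        )
    else:
        raise ValueError("fmt must be 'bed' or 'gff3'")
    if (out["start"] > out["end"]).any():
        raise ValueError("interval start exceeds end after normalization")
    return out


def annotate_islands(
    islands: list[ROHIsland], intervals: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Features overlapping each island by ≥1 bp (1-based inclusive).

    ``intervals`` is a frame as returned by :func:`read_intervals`; its
    chromosome names are matched against island chromosome numbers (a
    leading ``chr`` prefix is tolerated).  Returns (overlap table, count of
    interval records skipped for unrecognized chromosome names).
    """
    known = {str(i.chromosome) for i in islands}
    chrom = intervals["chromosome"].astype(str).str.removeprefix("chr")
    usable = chrom.isin(known) if known else pd.Series(False, index=intervals.index)
    skipped = int((~chrom.str.fullmatch(r"\d+")).sum())
    rows = []
    iv = intervals[usable]
    ivc = chrom[usable].astype(int).to_numpy()
    ivs = iv["start"].to_numpy()
    ive = iv["end"].to_numpy()
    ivn = iv["name"].to_numpy()
    for k, isl in enumerate(islands):
        hit = (ivc == isl.chromosome) & (ivs <= isl.end) & (ive >= isl.start)
        for j in np.flatnonzero(hit):
            rows.append(
                {
                    "island_index": k,
                    "chromosome": isl.chromosome,
                    "island_start": isl.start,
                    "island_end": isl.end,
                    "feature_name": ivn[j],
                    "feature_start": int(ivs[j]),
                    "feature_end": int(ive[j]),
                }
            )
    cols = ["island_index", "chromosome", "island_start", "island_end",
            "feature_name", "feature_start", "feature_end"]
    return pd.DataFrame(rows, columns=cols), skipped
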
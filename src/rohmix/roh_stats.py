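"""Summaries of detected ROH: length classes, F_ROH inbreeding, age dating.

The genomic inbreeding coefficient is F_ROH = Σ L_ROH / L_genome — the
fraction of the autosomal genome covered by an animal's ROH.  Segments are
binned into five length classes (1–5, 5–10, 10–20, 20–40, >40 Mb); short
classes reflect ancient common ancestors, long classes recent inbreeding.
The expected age follows Fisher's result that an autozygous segment
surviving g generations has exponentially distributed length with mean
100/(2g) cM; with the 1 cM = 1 Mb shortcut, a class with mean length L Mb
points to a common ancestor about 100/(2L) generations back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MarkerMap
from .roh import ROHSegment

__all__ = [
    "LengthClassScheme",
    "ROHSummary",
    "f_roh",
    "bin_segments",
    "summarize_roh",
    "summarize_from_class_counts",
    "inbreeding_records",
    "chromosome_coverage",
    "generations_from_length",
]


@dataclass(frozen=True)
class LengthClassScheme:
    """Contiguous half-open length bins over Mb, covering [floor, ∞)."""

    edges_mb: tuple = (1.0, 5.0, 10.0, 20.0, 40.0)  # last bin is open-ended

    def __post_init__(self) -> None:
        e = self.edges_mb
        if len(e) < 1 or any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("class edges must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        e = self.edges_mb
        out = [f"{_fmt(a)}-{_fmt(b)} Mb" for a, b in zip(e, e[1:])]
        out.append(f">{_fmt(e[-1])} Mb")
        return out

    @property
    def n_classes(self) -> int:
        return len(self.edges_mb)

    def assign(self, lengths_mb: np.ndarray) -> np.ndarray:
        """Class index per length; half-open [low, high) convention."""
        lengths_mb = np.asarray(lengths_mb, dtype=float)
        if np.any(lengths_mb < self.edges_mb[0]):
            raise ValueError(
                f"segment length below the scheme floor ({self.edges_mb[0]} Mb)"
            )
        return np.searchsorted(self.edges_mb, lengths_mb, side="right") - 1


def _fmt(x: float) -> str:
    return f"{x:g}"


def f_roh(segments: list[ROHSegment], l_genome: int) -> float:
    """Σ segment lengths ÷ genome length, for one animal's segments."""
    if l_genome <= 0:
        raise ValueError("genome length must be positive")
    return sum(s.length for s in segments) / l_genome


def bin_segments(
    segments: list[ROHSegment], scheme: LengthClassScheme = LengthClassScheme()
) -> np.ndarray:
    """Length-class index for each segment."""
    return scheme.assign(np.array([s.length_mb for s in segments]))


@dataclass
class ROHSummary:
    """Class-level descriptive table plus per-animal averages."""

    table: pd.DataFrame  # rows: one per class + "All"; cols N, N%, Mean_L (Mb), TL%
    mean_count_per_animal: float
    mean_total_mb_per_animal: float
    n_animals: int

    @property
    def overall_mean_length_mb(self) -> float:
        return float(self.table.loc["All", "Mean_L (Mb)"])


def _summary_from_counts(counts, total_mb, n_animals, labels) -> ROHSummary:
    counts = np.asarray(counts, dtype=float)
    total_mb = np.asarray(total_mb, dtype=float)
    n_all, l_all = counts.sum(), total_mb.sum()
    if n_all == 0:
        raise ValueError("no segments to summarize")
    with np.errstate(invalid="ignore"):
        mean_l = np.where(counts > 0, total_mb / np.where(counts > 0, counts, 1), 0.0)
    table = pd.DataFrame(
        {
            "N": np.append(counts, n_all).astype(int),
            "N%": np.append(100 * counts / n_all, 100.0),
            "Mean_L (Mb)": np.append(mean_l, l_all / n_all),
            "TL%": np.append(100 * total_mb / l_all, 100.0),
        },
        index=labels + ["All"],
    )
    return ROHSummary(
        table=table,
        mean_count_per_animal=float(n_all / n_animals),
        mean_total_mb_per_animal=float(l_all / n_animals),
        n_animals=n_animals,
    )


def summarize_roh(
    segments: list[ROHSegment],
    scheme: LengthClassScheme = LengthClassScheme(),
    n_animals: int | None = None,
) -> ROHSummary:
    """Per-class count, count share, mean length and length share.

    ``n_animals`` defaults to the number of distinct animals carrying a
    segment; pass the full cohort size to average over animals without ROH.
    """
    if not segments:
        raise ValueError("no segments to summarize")
    if n_animals is None:
        n_animals = len({s.animal for s in segments})
    cls = bin_segments(segments, scheme)
    lengths = np.array([s.length_mb for s in segments])
    k = scheme.n_classes
    counts = np.bincount(cls, minlength=k)[:k]
    total = np.bincount(cls, weights=lengths, minlength=k)[:k]
    return _summary_from_counts(counts, total, n_animals, scheme.labels)


def summarize_from_class_counts(
    counts,
    mean_lengths_mb,
    n_animals: int,
    scheme: LengthClassScheme = LengthClassScheme(),
) -> ROHSummary:
    """Summary arithmetic from already-binned class counts and mean lengths.

    Useful for recomputing overall means and per-animal averages from a
    published class table without the underlying segments.
    """
    counts = np.asarray(counts, dtype=float)
    mean_lengths_mb = np.asarray(mean_lengths_mb, dtype=float)
    if counts.shape != mean_lengths_mb.shape or len(counts) != scheme.n_classes:
        raise ValueError("counts and mean lengths must match the class scheme")
    return _summary_from_counts(counts, counts * mean_lengths_mb, n_animals, scheme.labels)


def inbreeding_records(
    segments: list[ROHSegment],
    animal_ids,
    l_genome: int,
    scheme: LengthClassScheme = LengthClassScheme(),
) -> pd.DataFrame:
    """Per-animal F_ROH: overall, per length class and per chromosome.

    All entries share the same L_genome denominator, so the per-class values
    of an animal sum exactly to its overall F_ROH.
    """
    if l_genome <= 0:
        raise ValueError("genome length must be positive")
    ids = list(animal_ids)
    cols = (
        ["F_ROH"]
        + [f"F_ROH[{lab}]" for lab in scheme.labels]
        + [f"F_ROH[chr{c}]" for c in sorted({s.chromosome for s in segments})]
    )
    df = pd.DataFrame(0.0, index=ids, columns=cols)
    df.index.name = "animal"
    if segments:
        cls = bin_segments(segments, scheme)
        for s, c in zip(segments, cls):
            frac = s.length / l_genome
            df.loc[s.animal, "F_ROH"] += frac
            df.loc[s.animal, f"F_ROH[{scheme.labels[c]}]"] += frac
            df.loc[s.animal, f"F_ROH[chr{s.chromosome}]"] += frac
    df["L_genome"] = l_genome
    return df


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    iv = sorted(iv)
    out: list[list[int]] = []
    for s, e in iv:
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def chromosome_coverage(
    segments: list[ROHSegment],
    marker_map: MarkerMap | None = None,
    chrom_lengths: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Per chromosome: segment count, share of total ROH length, % covered.

    Coverage uses the union of segments (overlaps across animals merged);
    chromosome extents come from ``chrom_lengths`` or the marker map span.
    """
    if chrom_lengths is None:
        if marker_map is None:
            raise ValueError("need a marker map or explicit chromosome lengths")
        chrom_lengths = {c: hi for c, (_, hi) in marker_map.chrom_spans().items()}
    rows = []
    total_len = sum(s.length for s in segments)
    for c in sorted(chrom_lengths):
        segs = [s for s in segments if s.chromosome == c]
        for s in segs:
            if s.end > chrom_lengths[c]:
                raise ValueError(
                    f"segment {s.start}-{s.end} exceeds chromosome {c} extent"
                )
        merged = _merge_intervals([(s.start, s.end) for s in segs])
        covered = sum(e - s + 1 for s, e in merged)
        chrom_total = sum(s.length for s in segs)
        rows.append(
            {
                "chromosome": c,
                "n_segments": len(segs),
                "share_of_total_pct": 100 * chrom_total / total_len if total_len else 0.0,
                "covered_pct": 100 * covered / chrom_lengths[c],
            }
        )
    return pd.DataFrame(rows).set_index("chromosome")


def generations_from_length(mean_len_mb: float) -> tuple[int, float]:
    """Generations to the common ancestor from a mean segment length.

    g = 100 / (2 L) with L in Mb ≡ cM; returns (rounded, exact), rounding
    half away from zero.
    """
    if mean_len_mb <= 0:
        raise ValueError("mean length must be positive")
    exact = 100.0 / (2.0 * mean_len_mb)
    rounded = int(math.floor(exact + 0.5))
    return rounded, exact
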
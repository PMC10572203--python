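"""Synthetic multi-breed SNP data with known ground truth.

This module generates every input the analysis pipeline consumes:

* a marker map emulating a ~12K uniformly spaced autosomal SNP panel
  (18 autosomes, no sex chromosomes);
* a breeds × SNPs allele-A frequency table with *structured* between-breed
  correlation, produced by hierarchical Balding–Nichols drift down a breed
  tree — breeds in the same subtree (e.g. an indigenous cluster) correlate
  strongly, breeds across a deep split barely at all;
* purebred genotypes drawn under Hardy–Weinberg equilibrium;
* two-breed crosses (F1 / F2 / backcross) with the realized per-animal
  breed-origin fraction returned as ground truth;
* diploid genomes with planted autozygous segments whose lengths follow an
  exponential law, for validating the ROH scanner and F_ROH estimates.

Throughout, the genetic map is taken as 1 cM = 1 Mb, so segment lengths in
Mb double as lengths in cM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .markers import MarkerMap

__all__ = [
    "BreedFrequencyTable",
    "CrossDesign",
    "TrueSegmentSet",
    "DEFAULT_BREED_TREE",
    "gen_marker_map",
    "gen_breed_frequencies",
    "gen_purebred_genotypes",
    "gen_cross_genotypes",
    "gen_autozygous_genomes",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class BreedFrequencyTable:
    """Allele-A frequencies x_jk for T reference breeds at M SNPs."""

    breeds: list[str]
    freq: np.ndarray  # T × M, entries in [0, 1]
    snp_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[0] != len(self.breeds):
            raise ValueError("freq must be T × M with one row per breed")
        if np.any((self.freq < 0) | (self.freq > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.snp_ids is not None:
            self.snp_ids = np.asarray(self.snp_ids, dtype=object)
            if len(self.snp_ids) != self.freq.shape[1]:
                raise ValueError("snp_ids length must equal column count")

    @property
    def n_breeds(self) -> int:
        return self.freq.shape[0]

    @property
    def n_snps(self) -> int:
        return self.freq.shape[1]

    def row(self, breed: str) -> np.ndarray:
        try:
            j = self.breeds.index(breed)
        except ValueError as e:
            raise KeyError(f"unknown breed label: {breed!r}") from e
        return self.freq[j]

    def subset_snps(self, index: np.ndarray) -> "BreedFrequencyTable":
        ids = None if self.snp_ids is None else self.snp_ids[index]
        return BreedFrequencyTable(list(self.breeds), self.freq[:, index], ids)

    def to_tsv(self, path) -> None:
        cols = (
            [f"snp{k + 1}" for k in range(self.n_snps)]
            if self.snp_ids is None
            else list(self.snp_ids)
        )
        df = pd.DataFrame(self.freq, index=self.breeds, columns=cols)
        df.index.name = "breed"
        df.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "BreedFrequencyTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float), np.asarray(df.columns, dtype=object))


_CROSS_TYPES = {"F1": (0.5, 0.5), "F2": (0.5, 0.5), "BC_A": (0.75, 0.25), "BC_B": (0.25, 0.75)}


@dataclass(frozen=True)
class CrossDesign:
    """A two-breed cross with its expected parental genome fractions."""

    breed_a: str
    breed_b: str
    cross_type: str  # F1 | F2 | BC_A | BC_B

    def __post_init__(self) -> None:
        if self.cross_type not in _CROSS_TYPES:
            raise ValueError(
                f"unknown cross type {self.cross_type!r}; expected one of {sorted(_CROSS_TYPES)}"
            )
        if self.breed_a == self.breed_b:
            raise ValueError("parental breeds must differ")

    @property
    def expected_proportions(self) -> tuple[float, float]:
        """Expected (breed A, breed B) genome fractions; always sums to 1."""
        return _CROSS_TYPES[self.cross_type]


@dataclass
class TrueSegmentSet:
    """Ground-truth planted autozygous intervals (animal, chrom, start, end)."""

    segments: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["animal", "chromosome", "start", "end"])
    )

    def __post_init__(self) -> None:
        need = ["animal", "chromosome", "start", "end"]
        if list(self.segments.columns) != need:
            self.segments = self.segments.reindex(columns=need)
        seg = self.segments.sort_values(need).reset_index(drop=True)
        # non-overlap within animal × chromosome
        for (_, _), grp in seg.groupby(["animal", "chromosome"], sort=False):
            s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
            if np.any(s[1:] <= e[:-1]):
                raise ValueError("planted intervals overlap within an animal/chromosome")
            if np.any(s > e):
                raise ValueError("interval start exceeds end")
        self.segments = seg

    def __len__(self) -> int:
        return len(self.segments)

    def lengths(self) -> np.ndarray:
        return (self.segments["end"] - self.segments["start"] + 1).to_numpy()

    def total_length_per_animal(self, animal_ids) -> pd.Series:
        s = pd.Series(0, index=list(animal_ids), dtype=float)
        if len(self.segments):
            tot = (self.segments["end"] - self.segments["start"] + 1).groupby(
                self.segments["animal"]
            ).sum()
            s.loc[tot.index] = tot
        return s

    def to_tsv(self, path) -> None:
        self.segments.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TrueSegmentSet":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# breed tree

#: A breed tree node is ``(fst, "LEAF_NAME")`` or ``(fst, [child, child, ...])``
#: where ``fst`` is the Balding–Nichols drift on the branch leading into the
#: node (the root's fst is ignored).
#:
#: The default emulates a pig reference panel: a deep split between an
#: indigenous Chinese cluster (NX, SZL, EH, BM, RC — tight, shallow leaves so
#: their frequencies correlate strongly) and a Western commercial cluster
#: (DC, LR, YK — longer leaf branches, hence looser within-cluster
#: correlation), with near-independent frequencies across the split.
DEFAULT_BREED_TREE = (
    0.0,
    [
        (
            0.35,
            [
                (0.08, [(0.05, "NX"), (0.05, "SZL")]),  # closest pair
                (0.15, "EH"),
                (0.18, "BM"),
                (0.18, "RC"),
            ],
        ),
        (0.20, [(0.50, "DC"), (0.50, "LR"), (0.45, "YK")]),
    ],
)


# ---------------------------------------------------------------------------
# generators


def gen_marker_map(
    n_chrom: int,
    snps_per_chrom: int,
    chrom_length: int = 125_000_000,
    spacing: str = "uniform",
    seed: int = 0,
) -> MarkerMap:
    """Lay out ``snps_per_chrom`` SNPs on each of ``n_chrom`` autosomes.

    ``spacing='uniform'`` places SNPs on an even grid from position 1 to
    ``chrom_length``; ``'jittered'`` perturbs each grid point by up to ±40%
    of the grid step (order-preserving), emulating a real array's uneven
    inter-marker distances.
    """
    if n_chrom < 1 or snps_per_chrom < 2:
        raise ValueError("need n_chrom >= 1 and snps_per_chrom >= 2")
    if chrom_length < snps_per_chrom:
        raise ValueError("chromosome too short for requested SNP count")
    if spacing not in ("uniform", "jittered"):
        raise ValueError("spacing must be 'uniform' or 'jittered'")
    rng = np.random.default_rng(seed)
    ids, chroms, poss = [], [], []
    grid = np.linspace(1, chrom_length, snps_per_chrom)
    step = (chrom_length - 1) / (snps_per_chrom - 1)
    for c in range(1, n_chrom + 1):
        pos = grid.copy()
        if spacing == "jittered":
            pos = pos + rng.uniform(-0.4 * step, 0.4 * step, size=snps_per_chrom)
        pos = np.clip(np.round(pos).astype(np.int64), 1, chrom_length)
        pos = np.unique(pos)
        while len(pos) < snps_per_chrom:  # collisions after rounding: refill
            extra = rng.integers(1, chrom_length + 1, size=snps_per_chrom - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        pos = pos[:snps_per_chrom]
        chroms.append(np.full(snps_per_chrom, c))
        poss.append(pos)
        ids.extend(f"chr{c}_snp{i + 1}" for i in range(snps_per_chrom))
    return MarkerMap(np.array(ids, dtype=object), np.concatenate(chroms), np.concatenate(poss))


def _bn_child(rng: np.random.Generator, parent: np.ndarray, fst: float) -> np.ndarray:
    """One Balding–Nichols drift step: Beta around the parent frequency."""
    if fst < 0 or fst >= 1:
        raise ValueError("branch drift F must lie in [0, 1)")
    if fst == 0.0:
        return parent.copy()  # no-drift limit
    p = np.clip(parent, 1e-12, 1 - 1e-12)
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return np.clip(rng.beta(a, b), 0.0, 1.0)


def gen_breed_frequencies(
    marker_map: MarkerMap,
    tree=DEFAULT_BREED_TREE,
    seed: int = 0,
    base_freq_range: tuple[float, float] = (0.05, 0.95),
) -> BreedFrequencyTable:
    """Hierarchical Balding–Nichols breed frequencies down a breed tree.

    The ancestral frequency at each SNP is drawn Uniform over
    ``base_freq_range`` (bounded away from 0/1 so no breed is monomorphic
    genome-wide), then drifts independently along every branch:
    child ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around its parent's p.  Breeds
    sharing a recent ancestor therefore show correlated frequencies.
    """
    rng = np.random.default_rng(seed)
    m = len(marker_map)
    base = rng.uniform(*base_freq_range, size=m)
    breeds: list[str] = []
    rows: list[np.ndarray] = []

    def walk(node, parent_freq):
        fst, payload = node
        freq = _bn_child(rng, parent_freq, float(fst))
        if isinstance(payload, str):
            breeds.append(payload)
            rows.append(freq)
        else:
            for child in payload:
                walk(child, freq)

    _, top = tree
    if isinstance(top, str):  # single-leaf tree
        walk(tree, base)
    else:
        for child in top:
            walk(child, base)
    if len(set(breeds)) != len(breeds):
        raise ValueError("breed labels in the tree must be unique")
    return BreedFrequencyTable(breeds, np.vstack(rows), marker_map.snp_id.copy())


def _mask_missing(rng: np.random.Generator, dosage: np.ndarray, missing_rate: float) -> np.ndarray:
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage = dosage.copy()
        dosage[mask] = MISSING
    return dosage


def _animal_ids(prefix: str, n: int) -> np.ndarray:
    return np.array([f"{prefix}{i + 1}" for i in range(n)], dtype=object)


def gen_purebred_genotypes(
    marker_map: MarkerMap,
    freq_row: np.ndarray,
    n_animals: int,
    missing_rate: float = 0.0,
    seed: int = 0,
    id_prefix: str = "ind",
) -> GenotypeMatrix:
    """Purebred genotypes under HWE: dosage at SNP k ~ Binomial(2, x_k)."""
    freq_row = np.asarray(freq_row, dtype=float)
    if freq_row.shape != (len(marker_map),):
        raise ValueError("frequency row length must match the marker map")
    if n_animals < 1:
        raise ValueError("need at least one animal")
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, freq_row, size=(n_animals, len(marker_map))).astype(np.int8)
    dosage = _mask_missing(rng, dosage, missing_rate)
    return GenotypeMatrix(_animal_ids(id_prefix, n_animals), marker_map, dosage)


def gen_cross_genotypes(
    marker_map: MarkerMap,
    freq_a: np.ndarray,
    freq_b: np.ndarray,
    design: CrossDesign,
    n_animals: int,
    seed: int = 0,
    missing_rate: float = 0.0,
    id_prefix: str = "cross",
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Two-breed cross genotypes plus the realized breed-A origin fraction.

    An F1 carries exactly one allele from each parental breed at every SNP,
    so its realized origin fraction is 0.5 by construction.  For F2 and
    backcrosses, each of the two alleles at each SNP draws its breed of
    origin Bernoulli(expected A-fraction) independently, then the allele is
    sampled from that breed's frequency — a marker-level idealization with
    no linkage between adjacent SNPs.
    """
    freq_a = np.asarray(freq_a, dtype=float)
    freq_b = np.asarray(freq_b, dtype=float)
    m = len(marker_map)
    if freq_a.shape != (m,) or freq_b.shape != (m,):
        raise ValueError("frequency rows must both align with the marker map")
    rng = np.random.default_rng(seed)
    prop_a = design.expected_proportions[0]
    if design.cross_type == "F1":
        origin = np.empty((n_animals, m, 2), dtype=bool)
        origin[:, :, 0] = True  # one allele from each breed
        origin[:, :, 1] = False
    else:
        origin = rng.random((n_animals, m, 2)) < prop_a
    p = np.where(origin, freq_a[None, :, None], freq_b[None, :, None])
    alleles = rng.random((n_animals, m, 2)) < p
    dosage = alleles.sum(axis=2).astype(np.int8)
    dosage = _mask_missing(rng, dosage, missing_rate)
    realized = origin.reshape(n_animals, -1).mean(axis=1)
    gm = GenotypeMatrix(_animal_ids(id_prefix, n_animals), marker_map, dosage)
    return gm, realized


def gen_autozygous_genomes(
    marker_map: MarkerMap,
    base_freqs: np.ndarray,
    n_animals: int,
    target_f: float,
    mean_seg_len_mb: float = 5.0,
    seed: int = 0,
    missing_rate: float = 0.0,
    chrom_lengths: dict[int, int] | None = None,
    min_seg_len_mb: float = 0.0,
    id_prefix: str = "auto",
    max_attempts_per_segment: int = 1000,
) -> tuple[GenotypeMatrix, TrueSegmentSet]:
    """Genomes with planted autozygous segments at a target coverage.

    Segment lengths are Exponential with mean ``mean_seg_len_mb`` Mb (1 cM =
    1 Mb, so a mean of 100/(2g) Mb corresponds to a common ancestor g
    generations back).  Segments are placed uniformly, chromosome chosen
    proportional to its length, rejected on overlap, until the planted
    fraction of the genome reaches ``target_f``.  Inside a segment both
    alleles are copies of one haplotype sampled from ``base_freqs``, forcing
    homozygosity; elsewhere genotypes are HWE draws as for purebreds.
    """
    base_freqs = np.asarray(base_freqs, dtype=float)
    if base_freqs.shape != (len(marker_map),):
        raise ValueError("base_freqs length must match the marker map")
    if not 0 <= target_f < 1:
        raise ValueError("target_f must lie in [0, 1)")
    if mean_seg_len_mb <= 0:
        raise ValueError("mean segment length must be positive")
    if chrom_lengths is None:
        chrom_lengths = {c: hi for c, (_, hi) in marker_map.chrom_spans().items()}
    chroms = sorted(chrom_lengths)
    clen = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    l_genome = clen.sum()
    rng = np.random.default_rng(seed)

    dosage = rng.binomial(2, base_freqs, size=(n_animals, len(marker_map))).astype(np.int8)
    records = []
    ids = _animal_ids(id_prefix, n_animals)
    for i in range(n_animals):
        placed: dict[int, list[tuple[int, int]]] = {c: [] for c in chroms}
        covered = 0.0
        attempts = 0
        while covered < target_f * l_genome:
            attempts += 1
            if attempts > max_attempts_per_segment * max(1, len(records) + 1):
                raise RuntimeError(
                    f"could not reach target_f={target_f}: animal {ids[i]} stalled at "
                    f"coverage {covered / l_genome:.4f} (shortfall "
                    f"{target_f - covered / l_genome:.4f})"
                )
            c = chroms[rng.choice(len(chroms), p=clen / l_genome)]
            floor_bp = max(1, int(min_seg_len_mb * 1_000_000))
            length = max(int(round(rng.exponential(mean_seg_len_mb) * 1_000_000)), floor_bp)
            # trim the final segment to the remaining coverage budget so the
            # planted fraction lands on target instead of overshooting by up
            # to a whole segment (matters on small genomes)
            remaining = int(round(target_f * l_genome - covered))
            if length > remaining:
                length = max(remaining, floor_bp)
            if length > chrom_lengths[c]:
                continue
            start = int(rng.integers(1, chrom_lengths[c] - length + 2))
            end = start + length - 1
            if any(start <= e and end >= s for s, e in placed[c]):
                continue
            placed[c].append((start, end))
            covered += length
            records.append((ids[i], c, start, end))
            # force homozygosity from a single sampled haplotype
            s = marker_map.chrom_slice(c)
            pos = marker_map.position[s]
            lo = s.start + int(np.searchsorted(pos, start, side="left"))
            hi = s.start + int(np.searchsorted(pos, end, side="right"))
            if hi > lo:
                hap = rng.random(hi - lo) < base_freqs[lo:hi]
                dosage[i, lo:hi] = 2 * hap.astype(np.int8)
    dosage = _mask_missing(rng, dosage, missing_rate)
    truth = TrueSegmentSet(
        pd.DataFrame(records, columns=["animal", "chromosome", "start", "end"])
    )
    return GenotypeMatrix(ids, marker_map, dosage), truth
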
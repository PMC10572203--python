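"""Genotype quality control and uniform SNP-panel selection.

QC mirrors a standard array-genotype cleaning protocol: animals are removed
first on individual call rate, then SNPs on call rate, then SNPs whose
genotype counts fail a Hardy–Weinberg chi-square test at a stringent alpha.
Minor-allele-frequency pruning is deliberately NOT applied — rare-allele
SNPs are informative for runs of homozygosity, and removing them loses ROH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix
from .markers import MarkerMap


class EmptyResultError(RuntimeError):
    """QC removed every animal or every SNP; the result would be empty."""


@dataclass
class QCReport:
    """What each filter removed, and at which thresholds."""

    snp_call_rate: float
    ind_call_rate: float
    hwe_alpha: float
    n_animals_in: int = 0
    n_snps_in: int = 0
    animals_removed_call_rate: list = field(default_factory=list)
    snps_removed_call_rate: list = field(default_factory=list)
    snps_removed_hwe: list = field(default_factory=list)

    @property
    def n_animals_out(self) -> int:
        return self.n_animals_in - len(self.animals_removed_call_rate)

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - len(self.snps_removed_call_rate) - len(self.snps_removed_hwe)

    def summary_lines(self) -> list[str]:
        return [
            f"animals\tin={self.n_animals_in}\tremoved_call_rate={len(self.animals_removed_call_rate)}\tout={self.n_animals_out}",
            f"snps\tin={self.n_snps_in}\tremoved_call_rate={len(self.snps_removed_call_rate)}\tremoved_hwe={len(self.snps_removed_hwe)}\tout={self.n_snps_out}",
            f"thresholds\tsnp_call_rate={self.snp_call_rate}\tind_call_rate={self.ind_call_rate}\thwe_alpha={self.hwe_alpha}",
        ]


def hwe_chisq_pvalues(dosage: np.ndarray) -> np.ndarray:
    """Per-SNP Hardy–Weinberg chi-square p-values (1 df) from dosage codes.

    Expected genotype counts use the observed allele frequency; monomorphic
    SNPs get chi-square 0 and p = 1.  Missing calls are excluded.
    """
    n0 = (dosage == 0).sum(axis=0).astype(float)
    n1 = (dosage == 1).sum(axis=0).astype(float)
    n2 = (dosage == 2).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n2 + n1) / (2 * n)
        q = 1 - p
        e0, e1, e2 = n * q * q, 2 * n * p * q, n * p * p
        chi2 = np.zeros_like(n)
        for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
            chi2 += term
    chi2 = np.where(n > 0, chi2, 0.0)
    return stats.chi2.sf(chi2, df=1)


def qc_filter(
    gm: GenotypeMatrix,
    snp_call_rate: float = 0.95,
    ind_call_rate: float = 0.90,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply call-rate and HWE filters; animals first, then SNPs.

    Removal rules: individual call rate < ``ind_call_rate``; SNP call rate
    < ``snp_call_rate`` (computed on the retained animals); HWE chi-square
    p-value < ``hwe_alpha``.  Raises :class:`EmptyResultError` rather than
    returning an empty matrix.
    """
    for t in (snp_call_rate, ind_call_rate):
        if not 0 < t <= 1:
            raise ValueError("call-rate thresholds must lie in (0, 1]")
    report = QCReport(snp_call_rate, ind_call_rate, hwe_alpha, gm.n_animals, gm.n_snps)
    keep_animals = np.ones(gm.n_animals, dtype=bool)
    keep_snps = np.ones(gm.n_snps, dtype=bool)

    # Removing a bad SNP changes animal call rates and vice versa, so the
    # three passes (animals, SNP call rate, SNP HWE — in that order) repeat
    # until a full pass removes nothing: QC output is a fixed point.
    changed = True
    while changed:
        changed = False
        d = gm.dosage[np.ix_(keep_animals, keep_snps)]
        present = d != MISSING

        drop_a = present.mean(axis=1) < ind_call_rate
        if drop_a.any():
            changed = True
            ids = gm.animal_ids[keep_animals][drop_a]
            report.animals_removed_call_rate.extend(ids)
            keep_animals[np.flatnonzero(keep_animals)[drop_a]] = False
            if not keep_animals.any():
                raise EmptyResultError("every animal failed the call-rate filter")
            d = gm.dosage[np.ix_(keep_animals, keep_snps)]
            present = d != MISSING

        drop_cr = present.mean(axis=0) < snp_call_rate
        drop_hwe = (hwe_chisq_pvalues(d) < hwe_alpha) & ~drop_cr
        if drop_cr.any() or drop_hwe.any():
            changed = True
            sids = gm.markers.snp_id[keep_snps]
            report.snps_removed_call_rate.extend(sids[drop_cr])
            report.snps_removed_hwe.extend(sids[drop_hwe])
            keep_snps[np.flatnonzero(keep_snps)[drop_cr | drop_hwe]] = False
            if not keep_snps.any():
                raise EmptyResultError("every SNP failed QC")

    out = GenotypeMatrix(
        gm.animal_ids[keep_animals],
        gm.markers.subset(keep_snps),
        gm.dosage[np.ix_(keep_animals, keep_snps)],
    )
    return out, report


def uniform_panel_select(marker_map: MarkerMap, k: int) -> tuple[MarkerMap, np.ndarray]:
    """Select ``k`` SNPs approximating equal bp spacing per chromosome.

    The per-chromosome allocation is proportional to chromosome span
    (largest-remainder rounding, at least one SNP each); within a
    chromosome, SNPs nearest to an even grid of target positions are chosen
    greedily left-to-right.  Returns the subset map and the selected column
    indices into the input map.
    """
    m = len(marker_map)
    chroms = marker_map.chromosomes
    if k > m:
        raise ValueError(f"k={k} exceeds available SNP count {m}")
    if k < len(chroms):
        raise ValueError(
            f"k={k} cannot honor at least one SNP per chromosome ({len(chroms)} chromosomes)"
        )
    spans = marker_map.chrom_spans()
    widths = np.array([spans[int(c)][1] - spans[int(c)][0] + 1 for c in chroms], dtype=float)
    counts = np.array([marker_map.chrom_slice(int(c)).stop - marker_map.chrom_slice(int(c)).start
                       for c in chroms])
    # largest-remainder allocation with floor 1 and cap at available count
    raw = k * widths / widths.sum()
    alloc = np.maximum(np.floor(raw).astype(int), 1)
    alloc = np.minimum(alloc, counts)
    while alloc.sum() != k:
        if alloc.sum() < k:
            room = alloc < counts
            frac = np.where(room, raw - alloc, -np.inf)
            alloc[int(np.argmax(frac))] += 1
        else:
            reducible = alloc > 1
            frac = np.where(reducible, raw - alloc, np.inf)
            alloc[int(np.argmin(frac))] -= 1
    picked: list[np.ndarray] = []
    for c, kc in zip(chroms, alloc):
        s = marker_map.chrom_slice(int(c))
        pos = marker_map.position[s].astype(float)
        nc = len(pos)
        if kc >= nc:
            picked.append(np.arange(s.start, s.stop))
            continue
        targets = np.linspace(pos[0], pos[-1], int(kc))
        chosen = np.empty(int(kc), dtype=int)
        lo = 0
        for j, t in enumerate(targets):
            # nearest unused index at or after lo, leaving room for the rest
            hi = nc - (int(kc) - j)  # last admissible index
            idx = int(np.clip(np.searchsorted(pos, t), lo, hi))
            best = idx
            for cand in (idx - 1, idx):
                if lo <= cand <= hi and abs(pos[cand] - t) < abs(pos[best] - t):
                    best = cand
            chosen[j] = best
            lo = best + 1
        picked.append(s.start + chosen)
    index = np.concatenate(picked)
    return marker_map.subset(index), index
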
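"""PLINK genotype file input/output (text PED/MAP and binary BED/BIM/FAM).

Genotypes are coded as allele-A dosages, where "allele A" is fixed by the
variant file's A1 column (A1 count = dosage).  Written files use allele
symbols ``A`` (A1) and ``B`` (A2); readers accept arbitrary allele symbols
and count copies of A1.  The binary dialect is SNP-major with the standard
magic bytes and 2-bit genotype packing.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .markers import MarkerMap

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))  # SNP-major

# 2-bit BED code per dosage (count of A1): hom A1 = 00, missing = 01,
# het = 10, hom A2 = 11
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def _read_map_like(path: str, n_cols: int) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None)
    if df.shape[1] != n_cols:
        raise ValueError(f"{path}: expected {n_cols} columns, found {df.shape[1]}")
    return df


def _marker_map_from(df: pd.DataFrame) -> MarkerMap:
    return MarkerMap(
        df[1].astype(str).to_numpy(dtype=object),
        df[0].to_numpy(dtype=np.int64),
        df[3].to_numpy(dtype=np.int64),
    )


def read_plink(prefix: str, dialect: str | None = None) -> GenotypeMatrix:
    """Read a PED/MAP or BED/BIM/FAM trio sharing ``prefix``.

    ``dialect`` is ``'text'``, ``'binary'`` or None to auto-detect from the
    files present (binary preferred when both exist).
    """
    if dialect is None:
        dialect = "binary" if os.path.exists(prefix + ".bed") else "text"
    if dialect == "text":
        return _read_ped_map(prefix)
    if dialect == "binary":
        return _read_bed(prefix)
    raise ValueError("dialect must be 'text' or 'binary'")


def write_plink(gm: GenotypeMatrix, prefix: str, dialect: str = "text") -> None:
    if dialect == "text":
        _write_ped_map(gm, prefix)
    elif dialect == "binary":
        _write_bed(gm, prefix)
    else:
        raise ValueError("dialect must be 'text' or 'binary'")


# ---------------------------------------------------------------------------
# text dialect


def _write_ped_map(gm: GenotypeMatrix, prefix: str) -> None:
    mk = gm.markers
    with open(prefix + ".map", "w") as fh:
        for c, sid, pos in zip(mk.chromosome, mk.snp_id, mk.position):
            fh.write(f"{c}\t{sid}\t0\t{pos}\n")
    pair = {2: "A A", 1: "A B", 0: "B B", MISSING: "0 0"}
    with open(prefix + ".ped", "w") as fh:
        for i, aid in enumerate(gm.animal_ids):
            row = gm.dosage[i]
            geno = " ".join(pair[int(g)] for g in row)
            fh.write(f"{aid} {aid} 0 0 0 -9 {geno}\n")


def _read_ped_map(prefix: str) -> GenotypeMatrix:
    mk = _marker_map_from(_read_map_like(prefix + ".map", 4))
    m = len(mk)
    ids, rows = [], []
    # MAP files carry no allele columns, so the text dialect fixes A1 per
    # SNP itself.  A/B-symbol files (array-style A/B designations, what the
    # writer emits) always count allele "A" — the designation is fixed even
    # when a SNP is monomorphic in the sample.  Nucleotide-coded files fall
    # back to the alphabetically first allele observed at the SNP.
    with open(prefix + ".ped") as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    for parts in lines:
        if len(parts) != 6 + 2 * m:
            raise ValueError(
                f"{prefix}.ped: row has {len(parts)} fields, expected {6 + 2 * m}"
            )
    observed: list[set] = [set() for _ in range(m)]
    for parts in lines:
        alleles = parts[6:]
        for k in range(m):
            for al in (alleles[2 * k], alleles[2 * k + 1]):
                if al != "0":
                    observed[k].add(al)
    a1 = [
        "A" if obs <= {"A", "B"} else min(obs) if obs else "A"
        for obs in observed
    ]
    for parts in lines:
        ids.append(parts[1])
        alleles = parts[6:]
        row = np.empty(m, dtype=np.int8)
        for k in range(m):
            x, y = alleles[2 * k], alleles[2 * k + 1]
            if x == "0" or y == "0":
                row[k] = MISSING
            else:
                row[k] = (x == a1[k]) + (y == a1[k])
        rows.append(row)
    return GenotypeMatrix(np.array(ids, dtype=object), mk, np.vstack(rows))


# ---------------------------------------------------------------------------
# binary dialect


def _write_bed(gm: GenotypeMatrix, prefix: str) -> None:
    mk = gm.markers
    with open(prefix + ".bim", "w") as fh:
        for c, sid, pos in zip(mk.chromosome, mk.snp_id, mk.position):
            fh.write(f"{c}\t{sid}\t0\t{pos}\tA\tB\n")
    with open(prefix + ".fam", "w") as fh:
        for aid in gm.animal_ids:
            fh.write(f"{aid} {aid} 0 0 0 -9\n")
    n = gm.n_animals
    codes = np.empty_like(gm.dosage, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[gm.dosage == dosage] = code
    n_bytes = (n + 3) // 4
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        padded = np.zeros((gm.n_snps, 4 * n_bytes), dtype=np.uint8)
        padded[:, :n] = codes.T
        # pack 4 samples per byte, sample index growing from the LSB
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        packed = (padded.reshape(gm.n_snps, n_bytes, 4) << shifts).sum(
            axis=2, dtype=np.uint32
        ).astype(np.uint8)
        fh.write(packed.tobytes())


def _read_bed(prefix: str) -> GenotypeMatrix:
    bim = _read_map_like(prefix + ".bim", 6)
    mk = _marker_map_from(bim)
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None)
    ids = fam[1].astype(str).to_numpy(dtype=object)
    n, m = len(ids), len(mk)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(
                f"{prefix}.bed: malformed magic bytes {magic!r} (expected SNP-major BED)"
            )
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    n_bytes = (n + 3) // 4
    if raw.size != m * n_bytes:
        raise ValueError(
            f"{prefix}.bed: payload is {raw.size} bytes, expected {m * n_bytes} "
            f"for {n} animals × {m} SNPs"
        )
    raw = raw.reshape(m, n_bytes)
    codes = np.empty((m, 4 * n_bytes), dtype=np.uint8)
    for j, shift in enumerate((0, 2, 4, 6)):
        codes[:, j::4] = (raw >> shift) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T
    return GenotypeMatrix(ids, mk, dosage)
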
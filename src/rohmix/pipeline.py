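"""End-to-end orchestration: simulate or ingest → QC → GBC → ROH → islands.

A single :class:`PipelineConfig` (plain YAML on disk) drives every stage
with the analysis defaults: QC at SNP call rate 0.95 / individual call rate
0.90 / HWE alpha 1e-6; GBC nullification at 1% with a 0.94 purebred cut-off
and 5% two-breed typing threshold; the standard 50-SNP-window ROH criteria;
top-1% island thresholding.  Stage outputs are plain tab-separated tables
written to a run directory together with a manifest (seed, config echo,
SHA-256 checksums), so a rerun with the same config and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gbc import estimate_gbc, gbc_change_point, two_breed_composition
from .genotypes import GenotypeMatrix
from .islands import (annotate_islands, island_threshold, islands_to_frame,
                      merge_islands, read_intervals, snp_incidence)
from .plink import read_plink, write_plink
from .qc import qc_filter
from .roh import ROHParams, detect_roh, segments_to_frame
from .roh_stats import (LengthClassScheme, chromosome_coverage,
                        inbreeding_records, summarize_roh)
from .simulate import (DEFAULT_BREED_TREE, BreedFrequencyTable, CrossDesign,
                       gen_autozygous_genomes, gen_breed_frequencies,
                       gen_cross_genotypes, gen_marker_map,
                       gen_purebred_genotypes)
from .structure import (breed_frequency_correlation, cluster_breeds,
                        dendrogram_to_newick, pca_genotypes)


@dataclass
class SimulationBlock:
    """What the synthetic cohort looks like when no genotype files are given."""

    # ~44K SNPs genome-wide (≈51 kb spacing): dense enough for the ROH
    # density criterion of one SNP per 100 kb
    n_chrom: int = 18
    snps_per_chrom: int = 2450
    chrom_length: int = 125_000_000
    spacing: str = "jittered"
    target_breed: str = "NX"
    cross_breed: str = "DC"
    other_breed: str = "LR"
    n_purebred: int = 40
    n_f1: int = 8
    n_f2: int = 8
    n_bc: int = 8
    n_other: int = 4
    target_f: float = 0.10
    mean_seg_len_mb: float = 5.0
    missing_rate: float = 0.01


@dataclass
class PipelineConfig:
    seed: int = 0
    genotypes: str | None = None  # PLINK prefix; None → simulate
    frequencies: str | None = None  # breed frequency TSV; None → simulate
    annotation: str | None = None  # optional BED/GFF3 for island annotation
    simulation: SimulationBlock = field(default_factory=SimulationBlock)
    snp_call_rate: float = 0.95
    ind_call_rate: float = 0.90
    hwe_alpha: float = 1e-6
    nullify_threshold: float = 0.01
    purebred_cutoff: float = 0.94
    cross_threshold: float = 0.05
    roh: ROHParams = field(default_factory=ROHParams)
    island_top_fraction: float = 0.01
    pca_components: int = 2

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationBlock(**raw.pop("simulation", {}))
        roh = ROHParams(**raw.pop("roh", {}))
        return cls(simulation=sim, roh=roh, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _simulate_cohort(cfg: PipelineConfig, outdir: str):
    """Build the synthetic cohort and write its ground-truth files."""
    sim = cfg.simulation
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)
    mmap = gen_marker_map(sim.n_chrom, sim.snps_per_chrom, sim.chrom_length,
                          sim.spacing, seed=int(seeds[0]))
    freqs = gen_breed_frequencies(mmap, DEFAULT_BREED_TREE, seed=int(seeds[1]))
    target_row = freqs.row(sim.target_breed)
    cross_row = freqs.row(sim.cross_breed)

    parts, ids, truth_rows = [], [], []
    gm_pure, seg_truth = gen_autozygous_genomes(
        mmap, target_row, sim.n_purebred, sim.target_f, sim.mean_seg_len_mb,
        seed=int(seeds[2]), missing_rate=sim.missing_rate, id_prefix="pure",
    )
    parts.append(gm_pure.dosage)
    ids.extend(gm_pure.animal_ids)
    truth_rows += [(a, sim.target_breed, 1.0) for a in gm_pure.animal_ids]

    cross_specs = [("F1", sim.n_f1, "f1"), ("F2", sim.n_f2, "f2"), ("BC_B", sim.n_bc, "bc")]
    for j, (ctype, n, prefix) in enumerate(cross_specs):
        if n == 0:
            continue
        design = CrossDesign(sim.cross_breed, sim.target_breed, ctype)
        gm_c, realized = gen_cross_genotypes(
            mmap, cross_row, target_row, design, n, seed=int(seeds[3 + j]),
            missing_rate=sim.missing_rate, id_prefix=prefix,
        )
        parts.append(gm_c.dosage)
        ids.extend(gm_c.animal_ids)
        truth_rows += [
            (a, sim.target_breed, 1.0 - r) for a, r in zip(gm_c.animal_ids, realized)
        ]
    if sim.n_other:
        gm_o = gen_purebred_genotypes(
            mmap, freqs.row(sim.other_breed), sim.n_other,
            missing_rate=sim.missing_rate, seed=int(seeds[6]), id_prefix="other",
        )
        parts.append(gm_o.dosage)
        ids.extend(gm_o.animal_ids)
        truth_rows += [(a, sim.target_breed, 0.0) for a in gm_o.animal_ids]

    gm = GenotypeMatrix(np.array(ids, dtype=object), mmap, np.vstack(parts))
    write_plink(gm, os.path.join(outdir, "cohort"), dialect="text")
    freqs.to_tsv(os.path.join(outdir, "breed_frequencies.tsv"))
    seg_truth.to_tsv(os.path.join(outdir, "true_segments.tsv"))
    pd.DataFrame(truth_rows, columns=["animal", "breed", "true_fraction"]).to_csv(
        os.path.join(outdir, "true_breed_fractions.tsv"), sep="\t", index=False
    )
    return gm, freqs


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []

    def emit(name: str) -> str:
        written.append(name)
        return os.path.join(outdir, name)

    # --- inputs -----------------------------------------------------------
    if config.genotypes is None:
        gm, freqs = _simulate_cohort(config, outdir)
        written += ["cohort.ped", "cohort.map", "breed_frequencies.tsv",
                    "true_segments.tsv", "true_breed_fractions.tsv"]
    else:
        gm = read_plink(config.genotypes)
        if config.frequencies is None:
            raise ValueError("genotype input requires a breed frequency table")
        freqs = BreedFrequencyTable.from_tsv(config.frequencies)
    target = config.simulation.target_breed

    # --- QC ---------------------------------------------------------------
    gm_qc, report = qc_filter(gm, config.snp_call_rate, config.ind_call_rate,
                              config.hwe_alpha)
    with open(emit("qc_report.tsv"), "w") as fh:
        fh.write("\n".join(report.summary_lines()) + "\n")
    keep = np.isin(freqs.snp_ids, gm_qc.markers.snp_id)
    freqs_qc = freqs.subset_snps(keep)

    # --- GBC --------------------------------------------------------------
    rows = []
    for i, aid in enumerate(gm_qc.animal_ids):
        res = estimate_gbc(
            gm_qc.dosage[i], freqs_qc, animal_id=str(aid),
            nullify_threshold=config.nullify_threshold,
            classify_breed=target, cutoff=config.purebred_cutoff,
            seed=config.seed,
        )
        pair = two_breed_composition(
            res.weights, res.breeds, config.simulation.cross_breed, target,
            threshold=config.cross_threshold,
        )
        row = {"animal": aid, "label": res.label, "loglik": res.loglik,
               "converged": res.converged,
               "two_breed_fraction_a": None if pair is None else round(pair[0], 4)}
        row.update({f"w_{b}": round(res.weights[j], 6) for j, b in enumerate(res.breeds)})
        row.update({f"raw_{b}": round(res.raw_weights[j], 6) for j, b in enumerate(res.breeds)})
        rows.append(row)
    gbc_df = pd.DataFrame(rows)
    gbc_df.to_csv(emit("gbc.tsv"), sep="\t", index=False)
    cp = gbc_change_point(np.sort(gbc_df[f"w_{target}"].to_numpy()))
    with open(emit("gbc_change_point.tsv"), "w") as fh:
        fh.write("change_point\n")
        fh.write(("NA" if cp is None else f"{cp.value:.4f}") + "\n")

    # --- ROH on purebred-classified animals -------------------------------
    purebred_ids = gbc_df.loc[gbc_df["label"] == "purebred", "animal"]
    mask = np.isin(gm_qc.animal_ids, purebred_ids.to_numpy())
    gm_pure = gm_qc.subset(animals=mask)
    segments = detect_roh(gm_pure, config.roh)
    segments_to_frame(segments).to_csv(emit("roh_segments.tsv"), sep="\t", index=False)

    # --- ROH statistics ---------------------------------------------------
    scheme = LengthClassScheme()
    l_genome = gm_pure.markers.snp_covered_length()
    if segments:
        summary = summarize_roh(segments, scheme, n_animals=gm_pure.n_animals)
        summary.table.to_csv(emit("roh_summary.tsv"), sep="\t")
        chromosome_coverage(segments, gm_pure.markers).to_csv(
            emit("roh_chromosome_coverage.tsv"), sep="\t"
        )
    inbreeding_records(segments, gm_pure.animal_ids, l_genome, scheme).to_csv(
        emit("inbreeding.tsv"), sep="\t"
    )

    # --- ROH islands ------------------------------------------------------
    inc = snp_incidence(segments, gm_pure.markers, gm_pure.n_animals)
    inc.to_csv(emit("snp_incidence.tsv"), sep="\t", index=False)
    thr = island_threshold(inc["incidence_pct"].to_numpy(), config.island_top_fraction)
    islands = merge_islands(inc["incidence_pct"].to_numpy() >= thr, gm_pure.markers)
    idf = islands_to_frame(islands)
    idf.insert(0, "threshold_pct", round(thr, 4))
    idf.to_csv(emit("roh_islands.tsv"), sep="\t", index=False)
    if config.annotation:
        overlaps, skipped = annotate_islands(islands, read_intervals(config.annotation))
        overlaps.to_csv(emit("island_annotation.tsv"), sep="\t", index=False)

    # --- population structure --------------------------------------------
    corr = breed_frequency_correlation(freqs_qc)
    corr.to_csv(emit("breed_correlation.tsv"), sep="\t")
    link = cluster_breeds(corr)
    with open(emit("breed_dendrogram.nwk"), "w") as fh:
        fh.write(dendrogram_to_newick(link, list(corr.index)) + "\n")
    pca = pca_genotypes(gm_qc, k=min(config.pca_components, gm_qc.n_animals - 1))
    pca.to_frame().to_csv(emit("pca_scores.tsv"), sep="\t")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {name: _sha256(os.path.join(outdir, name)) for name in sorted(set(written))},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
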
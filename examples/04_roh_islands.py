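"""Detect ROH islands and annotate them with user-supplied intervals.

Forty percent of a cohort shares one autozygous region; the per-SNP ROH
incidence, the top-1% threshold and adjacent-SNP merging recover it as a
single island, which is then intersected with a small BED annotation.
"""

import os
import tempfile

import numpy as np

import rohmix

map_ = rohmix.gen_marker_map(3, 1000, 30_000_000, seed=1)
rng = np.random.default_rng(2)
base = rng.uniform(0.2, 0.8, len(map_))
gm = rohmix.gen_purebred_genotypes(map_, base, 30, seed=3)

# plant a shared 3 Mb autozygous block on chromosome 2 in 12 of 30 animals
block = map_.chrom_slice(2)
lo, hi = block.start + 300, block.start + 400
dosage = gm.dosage.copy()
hap = (rng.random(hi - lo) < base[lo:hi]).astype(np.int8) * 2
for a in rng.choice(30, size=12, replace=False):
    dosage[a, lo:hi] = hap
gm = rohmix.GenotypeMatrix(gm.animal_ids, map_, dosage)

segments = rohmix.detect_roh(gm)
inc = rohmix.snp_incidence(segments, map_, gm.n_animals)
thr = rohmix.island_threshold(inc["incidence_pct"].to_numpy(), top_fraction=0.01)
islands = rohmix.merge_islands(inc["incidence_pct"].to_numpy() >= thr, map_)
print(f"incidence threshold (top 1%): {thr:.2f}% of animals")
for isl in islands:
    print(f"island: chr{isl.chromosome} {isl.start/1e6:.2f}-{isl.end/1e6:.2f} Mb, "
          f"{isl.n_snps} SNPs, {isl.length_mb:.2f} Mb")

with tempfile.TemporaryDirectory() as tmp:
    bed = os.path.join(tmp, "features.bed")  # BED is 0-based half-open
    with open(bed, "w") as fh:
        fh.write(f"2\t{map_.position[lo+20]-1}\t{map_.position[lo+40]}\tQTL_growth\n")
        fh.write("1\t100\t200\tQTL_elsewhere\n")
    overlaps, skipped = rohmix.annotate_islands(islands, rohmix.islands.read_intervals(bed))
    print(f"annotation: {len(overlaps)} feature overlap(s), {skipped} skipped")
    if len(overlaps):
        print(overlaps[["chromosome", "feature_name", "feature_start", "feature_end"]])
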
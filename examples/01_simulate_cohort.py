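"""Simulate a multi-breed SNP cohort with known ground truth.

Builds a small marker map, draws correlated breed allele frequencies down a
breed tree, and generates purebred, crossbred and autozygosity-carrying
genomes.  Every quantity printed has a known true value by construction.
"""

import numpy as np

import rohmix
from rohmix.simulate import CrossDesign

map_ = rohmix.gen_marker_map(n_chrom=6, snps_per_chrom=800, chrom_length=40_000_000,
                             spacing="jittered", seed=1)
print(f"marker map: {len(map_)} SNPs on {len(map_.chromosomes)} autosomes, "
      f"~{np.diff(map_.position)[:10].mean()/1e3:.0f} kb spacing")

freqs = rohmix.gen_breed_frequencies(map_, seed=2)
print(f"frequency panel: {freqs.n_breeds} breeds × {freqs.n_snps} SNPs "
      f"({', '.join(freqs.breeds)})")

pure = rohmix.gen_purebred_genotypes(map_, freqs.row("NX"), n_animals=5, seed=3)
realized = pure.allele_a_frequency()
print(f"purebred HWE draws: realized vs panel frequency correlation "
      f"{np.corrcoef(realized, freqs.row('NX'))[0,1]:.3f}")

design = CrossDesign("DC", "NX", "BC_B")
cross, origin = rohmix.gen_cross_genotypes(map_, freqs.row("DC"), freqs.row("NX"),
                                           design, n_animals=3, seed=4)
print(f"backcross to NX: realized DC-origin fractions {np.round(origin, 3)} "
      f"(expected {design.expected_proportions[0]})")

gm, truth = rohmix.gen_autozygous_genomes(map_, freqs.row("NX"), n_animals=3,
                                          target_f=0.10, mean_seg_len_mb=5.0, seed=5)
cov = truth.total_length_per_animal(gm.animal_ids) / map_.snp_covered_length()
print(f"planted autozygosity: {len(truth)} segments, per-animal coverage "
      f"{np.round(cov.to_numpy(), 3)} (target 0.10)")
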
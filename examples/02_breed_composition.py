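"""Estimate genomic breed composition (GBC) and classify animals.

Fits the admixture likelihood for a purebred animal and an F1 cross against
an 8-breed reference panel, nullifies sub-1% components, classifies at the
0.94 purity cut-off, types the F1 as a two-breed cross, and locates the
purity change point on a sorted GBC curve.
"""

import numpy as np

import rohmix
from rohmix.simulate import CrossDesign

map_ = rohmix.gen_marker_map(18, 278, 125_000_000, seed=1)  # ~5K panel
freqs = rohmix.gen_breed_frequencies(map_, seed=2)

pure = rohmix.gen_purebred_genotypes(map_, freqs.row("NX"), 1, seed=3)
res = rohmix.estimate_gbc(pure.dosage[0], freqs, animal_id="pure1",
                          classify_breed="NX", cutoff=0.94)
print("purebred NX animal:")
print("  weights:", {b: round(w, 3) for b, w in zip(res.breeds, res.weights) if w > 0})
print(f"  label at cut-off 0.94: {res.label}  (log-likelihood {res.loglik:.1f})")

f1, _ = rohmix.gen_cross_genotypes(map_, freqs.row("DC"), freqs.row("NX"),
                                   CrossDesign("DC", "NX", "F1"), 1, seed=4)
res_f1 = rohmix.estimate_gbc(f1.dosage[0], freqs, animal_id="f1",
                             classify_breed="NX", cutoff=0.94)
print("F1 DC×NX animal:")
print("  weights:", {b: round(w, 3) for b, w in zip(res_f1.breeds, res_f1.weights) if w > 0})
pair = rohmix.two_breed_composition(res_f1.weights, res_f1.breeds, "DC", "NX",
                                    threshold=0.05)
print(f"  two-breed typing (5% filter): DC {pair[0]:.3f} / NX {pair[1]:.3f}, "
      f"label: {res_f1.label}")

# change point on a sorted GBC curve: crossbred tail then purebred plateau
rng = np.random.default_rng(5)
curve = np.sort(np.concatenate([rng.normal(0.55, 0.05, 30),
                                1.0 - np.abs(rng.normal(0, 0.004, 170))]))
cp = rohmix.gbc_change_point(curve)
print(f"change point: rank {cp.index}/200, GBC value {cp.value:.3f} "
      f"(start of the purebred plateau)")
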
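"""Breed frequency correlations, clustering and genotype PCA.

Reproduces the descriptive structure analyses: the correlation matrix of
breed allele-A frequencies, an average-linkage dendrogram on 1 − r, and a
PCA in which F1 crosses fall between their parental breeds' clusters.
"""

import numpy as np

import rohmix
from rohmix.simulate import CrossDesign
from rohmix.structure import dendrogram_to_newick

map_ = rohmix.gen_marker_map(18, 278, 125_000_000, seed=1)
freqs = rohmix.gen_breed_frequencies(map_, seed=2)

corr = rohmix.breed_frequency_correlation(freqs)
print("allele-A frequency correlations (rounded):")
print(corr.round(2))

link = rohmix.cluster_breeds(corr)
print("\ndendrogram:", dendrogram_to_newick(link, list(corr.index)))

dc = rohmix.gen_purebred_genotypes(map_, freqs.row("DC"), 10, seed=3, id_prefix="dc")
nx = rohmix.gen_purebred_genotypes(map_, freqs.row("NX"), 10, seed=4, id_prefix="nx")
f1, _ = rohmix.gen_cross_genotypes(map_, freqs.row("DC"), freqs.row("NX"),
                                   CrossDesign("DC", "NX", "F1"), 5, seed=5)
gm = rohmix.GenotypeMatrix(np.concatenate([dc.animal_ids, nx.animal_ids, f1.animal_ids]),
                           map_, np.vstack([dc.dosage, nx.dosage, f1.dosage]))
pca = rohmix.pca_genotypes(gm, k=2)
pc1 = pca.scores[:, 0]
print(f"\nPCA: PC1 explains {100*pca.explained_variance_ratio[0]:.1f}% of variance")
print(f"  DC mean {pc1[:10].mean():.1f}, NX mean {pc1[10:20].mean():.1f}, "
      f"F1 mean {pc1[20:].mean():.1f} (crosses sit between the parents)")
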
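"""Descriptive population-structure analyses.

Thin wrappers over scipy/numpy: Pearson correlation of breed allele-A
frequency vectors, average-linkage hierarchical clustering of breeds on the
1 − r distance, and genotype PCA (mean-centered dosages, SVD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genotypes import MISSING, GenotypeMatrix
from .simulate import BreedFrequencyTable

__all__ = [
    "breed_frequency_correlation",
    "cluster_breeds",
    "dendrogram_to_newick",
    "PCAProjection",
    "pca_genotypes",
]


def breed_frequency_correlation(freqs: BreedFrequencyTable) -> pd.DataFrame:
    """T × T Pearson correlation matrix of breed allele-frequency rows.

    A zero-variance frequency row has no defined correlation; its
    off-diagonal entries are NaN (flagged), the diagonal stays 1.
    """
    if freqs.n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    x = freqs.freq
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=freqs.breeds, columns=freqs.breeds)


def cluster_breeds(corr: pd.DataFrame) -> np.ndarray:
    """Average-linkage hierarchical clustering on distance 1 − r.

    Returns a scipy linkage matrix over the breeds in ``corr``'s label
    order (scipy's ordering rules give deterministic tie-breaking).
    """
    r = corr.to_numpy(dtype=float)
    if np.isnan(r).any():
        raise ValueError("correlation matrix contains undefined entries")
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)  # symmetrize against FP noise
    return hierarchy.linkage(squareform(d, checks=False), method="average")


def dendrogram_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        blen = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            blen = parent_height
            return f"{labels[node.id]}:{blen:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{blen:.6g}"

    body = walk(tree, tree.dist)
    # strip the root's zero-length branch
    return body.rsplit(":", 1)[0] + ";"


@dataclass
class PCAProjection:
    animal_ids: np.ndarray
    scores: np.ndarray  # N × k
    explained_variance_ratio: np.ndarray  # length k, non-increasing

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            index=self.animal_ids,
            columns=[f"PC{i + 1}" for i in range(self.scores.shape[1])],
        )
        df.index.name = "animal"
        return df


def pca_genotypes(gm: GenotypeMatrix, k: int = 2, scale: bool = False) -> PCAProjection:
    """Principal components of mean-centered dosage genotypes.

    Missing calls are imputed with the SNP mean before centering.  With
    ``scale=True`` each SNP is additionally divided by its standard
    deviation.  If ``k`` exceeds the matrix rank the projection is
    truncated.
    """
    if k < 1 or k > min(gm.n_animals, gm.n_snps):
        raise ValueError("k must lie in 1..min(N, M)")
    x = gm.dosage.astype(float)
    x[gm.dosage == MISSING] = np.nan
    mu = np.nanmean(x, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    inds = np.where(np.isnan(x))
    x[inds] = mu[inds[1]]
    x = x - mu
    if scale:
        sd = x.std(axis=0)
        x = x / np.where(sd > 0, sd, 1.0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    k_eff = min(k, rank) if rank else k
    scores = u[:, :k] * s[:k]
    total_var = float(np.sum(s**2))
    if total_var > 0:
        evr = (s[:k] ** 2) / total_var
    else:
        evr = np.zeros(k)
    if k_eff < k:
        scores[:, k_eff:] = 0.0
        evr[k_eff:] = 0.0
    return PCAProjection(gm.animal_ids.copy(), scores, evr)
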
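"""Genomic breed composition (GBC) via admixture-likelihood maximization.

The model: an animal's genotype at SNP k is a Hardy–Weinberg draw from a
*mixture* allele frequency f_k = Σ_j w_j x_jk, where x_jk is the allele-A
frequency of reference breed j and w = (w_1 … w_T) are non-negative
admixture coefficients summing to one.  The log-likelihood over M
independent SNPs,

    l(w) = Σ_k [ g_k ln f_k + (2 − g_k) ln(1 − f_k) ] + Σ_k ln C(2, g_k),

is maximized over the breed simplex with BFGS on a softmax
reparameterization.  After convergence, breeds whose removal barely changes
the fit are pruned, small surviving weights can be nullified and the rest
rescaled, and animals are classified purebred/crossbred against a GBC
cut-off.  GBC measured this way reflects identity-in-state with the
reference breeds, not identity-by-descent — correlated breeds leak small
weights into each other, which is exactly what nullification addresses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

__all__ = [
    "GBCResult",
    "genotype_prob",
    "mixture_freq",
    "admixture_loglik",
    "estimate_gbc",
    "nullify_rescale",
    "classify_purebred",
    "two_breed_composition",
    "gbc_change_point",
    "ChangePoint",
]

#: Frequency clamp guarding ln(f) and ln(1−f) at (near-)monomorphic SNPs.
FREQ_EPS = 1e-6

#: Default pruning tolerance: a breed is dropped while the log-likelihood
#: loss is below the 1-df likelihood-ratio critical value at α = 0.05
#: (2·Δll < 3.84), i.e. while its contribution is not statistically
#: significant.  This is what lets genuinely purebred animals end at a
#: weight of exactly 1.0 despite correlated reference breeds.
PRUNE_TOL_LRT: float = float(chi2.ppf(0.95, df=1) / 2.0)

_LN_BINOM = np.log(np.array([1.0, 2.0, 1.0]))  # ln C(2, g) for g = 0, 1, 2


def genotype_prob(g: int, f: float) -> float:
    """HWE probability of dosage ``g`` given allele-A frequency ``f``."""
    if g not in (0, 1, 2):
        raise ValueError("dosage must be 0, 1 or 2 (skip missing calls)")
    f = min(max(f, 0.0), 1.0)
    if g == 0:
        return (1 - f) ** 2
    if g == 1:
        return 2 * f * (1 - f)
    return f * f


def mixture_freq(w: np.ndarray, x_col: np.ndarray, eps: float = FREQ_EPS) -> float:
    """Weighted allele frequency Σ_j w_j x_jk, clamped to [eps, 1−eps]."""
    w = np.asarray(w, dtype=float)
    x_col = np.asarray(x_col, dtype=float)
    if w.shape != x_col.shape:
        raise ValueError("weights and per-breed frequencies must align")
    return float(np.clip(w @ x_col, eps, 1 - eps))


def _prepare(g_vec: np.ndarray, freq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop missing genotypes; returns (g, T×m frequency columns)."""
    g_vec = np.asarray(g_vec)
    if freq.ndim != 2:
        raise ValueError("frequency table must be T × M")
    if g_vec.shape[0] != freq.shape[1]:
        raise ValueError("genotype vector length must match frequency columns")
    keep = (g_vec == 0) | (g_vec == 1) | (g_vec == 2)
    if not keep.any():
        raise ValueError("animal has no non-missing genotype")
    return g_vec[keep].astype(float), freq[:, keep]


def admixture_loglik(
    g_vec: np.ndarray, freq: np.ndarray, w: np.ndarray, eps: float = FREQ_EPS
) -> float:
    """Admixture log-likelihood l(w), including the genotype-constant term."""
    g, x = _prepare(g_vec, np.asarray(freq, dtype=float))
    w = np.asarray(w, dtype=float)
    f = np.clip(w @ x, eps, 1 - eps)
    const = _LN_BINOM[g.astype(int)].sum()
    return float(np.sum(g * np.log(f) + (2 - g) * np.log(1 - f)) + const)


@dataclass
class GBCResult:
    """Per-animal admixture estimate with nullification and classification."""

    animal_id: str
    breeds: list[str]
    raw_weights: np.ndarray
    weights: np.ndarray  # after nullification + rescaling
    loglik: float
    converged: bool
    label: str | None = None  # "purebred" / "crossbred" when a breed was named
    n_snps_used: int = 0

    def weight_of(self, breed: str) -> float:
        try:
            return float(self.weights[self.breeds.index(breed)])
        except ValueError as e:
            raise KeyError(f"unknown breed label: {breed!r}") from e


def _neg_loglik_grad(theta, g, x, eps):
    """Negative log-likelihood and gradient in softmax coordinates."""
    z = theta - theta.max()
    ez = np.exp(z)
    w = ez / ez.sum()
    f = np.clip(w @ x, eps, 1 - eps)
    ll = np.sum(g * np.log(f) + (2 - g) * np.log(1 - f))
    dl_df = g / f - (2 - g) / (1 - f)
    dl_dw = x @ dl_df
    grad_theta = w * (dl_dw - w @ dl_dw)
    return -ll, -grad_theta


def _fit_simplex(g, x, eps, rng, max_restarts=5):
    """Maximize the likelihood over the simplex; returns (w, ll, converged)."""
    t = x.shape[0]
    if t == 1:
        w = np.ones(1)
        f = np.clip(x[0], eps, 1 - eps)
        return w, float(np.sum(g * np.log(f) + (2 - g) * np.log(1 - f))), True
    best = None
    theta0 = np.zeros(t)  # uniform weights
    for attempt in range(max_restarts + 1):
        res = minimize(
            _neg_loglik_grad, theta0, args=(g, x, eps), jac=True, method="BFGS",
            options={"gtol": 1e-7, "maxiter": 500},
        )
        z = res.x - res.x.max()
        w = np.exp(z) / np.exp(z).sum()
        cand = (w, -float(res.fun), bool(res.success))
        if best is None or cand[1] > best[1]:
            best = cand
        if res.success:
            return best
        theta0 = rng.normal(scale=1.0, size=t)
    return best


def estimate_gbc(
    g_vec: np.ndarray,
    freq,
    breeds: Sequence[str] | None = None,
    animal_id: str = "",
    nullify_threshold: float = 0.01,
    prune_tol: float = PRUNE_TOL_LRT,
    eps: float = FREQ_EPS,
    classify_breed: str | None = None,
    cutoff: float = 0.94,
    seed: int = 0,
) -> GBCResult:
    """Estimate admixture weights for one animal.

    ``freq`` may be a T × M array or a ``BreedFrequencyTable``.  After the
    BFGS fit, breeds are pruned back-to-front: the smallest nonzero weight
    is dropped and the model refitted as long as the log-likelihood falls by
    less than ``prune_tol`` per pruned breed (default: the 1-df
    likelihood-ratio bound at α = 0.05).  Weights below
    ``nullify_threshold`` are then zeroed and the remainder rescaled to sum
    to one.  When ``classify_breed`` is given, the result carries a
    purebred/crossbred label at the ``cutoff``.
    """
    if hasattr(freq, "freq"):  # BreedFrequencyTable
        breeds = list(freq.breeds)
        freq = freq.freq
    freq = np.asarray(freq, dtype=float)
    if breeds is None:
        breeds = [f"breed{j + 1}" for j in range(freq.shape[0])]
    g, x = _prepare(g_vec, freq)
    const = _LN_BINOM[g.astype(int)].sum()
    rng = np.random.default_rng(seed)

    w, ll, converged = _fit_simplex(g, x, eps, rng)
    t = len(breeds)
    active = list(range(t))
    # prune breeds whose removal does not significantly hurt the fit
    while len(active) > 1:
        drop_local = int(np.argmin(w))
        reduced = [a for i, a in enumerate(active) if i != drop_local]
        w_r, ll_r, conv_r = _fit_simplex(g, x[reduced], eps, rng)
        if ll - ll_r < prune_tol:
            active, w, ll, converged = reduced, w_r, ll_r, conv_r
        else:
            break
    raw = np.zeros(t)
    raw[active] = w
    filtered = nullify_rescale(raw, nullify_threshold)
    result = GBCResult(
        animal_id=animal_id,
        breeds=list(breeds),
        raw_weights=raw,
        weights=filtered,
        loglik=ll + const,
        converged=converged,
        n_snps_used=len(g),
    )
    if classify_breed is not None:
        result.label = classify_purebred(result, classify_breed, cutoff)
    return result


def estimate_gbc_matrix(gm, freq_table, **kwargs) -> list[GBCResult]:
    """Run :func:`estimate_gbc` for every animal of a GenotypeMatrix."""
    out = []
    for i, aid in enumerate(gm.animal_ids):
        out.append(estimate_gbc(gm.dosage[i], freq_table, animal_id=str(aid), **kwargs))
    return out


def nullify_rescale(w: np.ndarray, threshold: float = 0.01) -> np.ndarray:
    """Zero weights below ``threshold`` and rescale the rest to sum to one."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    w = np.asarray(w, dtype=float).copy()
    w[w < threshold] = 0.0
    s = w.sum()
    if s == 0:
        raise ValueError("nullification removed every component")
    return w / s


def classify_purebred(result, breed: str, cutoff: float = 0.94) -> str:
    """'purebred' iff the (filtered) weight of ``breed`` is ≥ ``cutoff``."""
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    if isinstance(result, GBCResult):
        weight = result.weight_of(breed)
    else:
        raise TypeError("pass a GBCResult")
    return "purebred" if weight >= cutoff else "crossbred"


def two_breed_composition(
    weights: np.ndarray,
    breeds: Sequence[str],
    breed_a: str,
    breed_b: str,
    threshold: float = 0.05,
) -> tuple[float, float] | None:
    """Type an animal as a two-breed cross of ``breed_a`` × ``breed_b``.

    Components below ``threshold`` are nullified; the animal qualifies only
    if the two named breeds, and no others, carry nonzero weight afterwards.
    Returns the pair rescaled to sum to one, or None if the animal is not a
    two-breed cross of these breeds (a third breed survives, or one of the
    pair is absent).
    """
    if breed_a == breed_b:
        raise ValueError("the two breeds must differ")
    breeds = list(breeds)
    ia, ib = breeds.index(breed_a), breeds.index(breed_b)
    w = np.asarray(weights, dtype=float).copy()
    w[w < threshold] = 0.0
    if w[ia] == 0 or w[ib] == 0:
        return None
    others = np.delete(w, [ia, ib])
    if np.any(others > 0):
        return None
    s = w[ia] + w[ib]
    return float(w[ia] / s), float(w[ib] / s)


class ChangePoint(NamedTuple):
    index: int  # first index of the upper segment
    value: float  # GBC value at that index


def gbc_change_point(values: np.ndarray) -> ChangePoint | None:
    """Single change point in an ascending-sorted GBC curve.

    Least-squares binary segmentation with one breakpoint: choose the split
    minimizing total within-segment squared error around the two segment
    means.  Used to locate where the purebred plateau (GBC ≈ 1) begins.
    Returns None for a constant sequence.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 10:
        raise ValueError("need at least 10 values for change-point detection")
    if np.any(np.diff(v) < 0):
        raise ValueError("values must be sorted ascending")
    if np.allclose(v, v[0]):
        return None
    s1 = np.cumsum(v)
    s2 = np.cumsum(v * v)
    tot1, tot2 = s1[-1], s2[-1]
    ks = np.arange(1, n)  # split before index k
    left1, left2 = s1[ks - 1], s2[ks - 1]
    sse_left = left2 - left1**2 / ks
    nr = n - ks
    sse_right = (tot2 - left2) - (tot1 - left1) ** 2 / nr
    k = int(ks[np.argmin(sse_left + sse_right)])
    return ChangePoint(index=k, value=float(v[k]))
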
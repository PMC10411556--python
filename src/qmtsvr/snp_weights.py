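"""Per-locus (co)variance weights for the weighted multitask kernel.

Marker effects are estimated one SNP at a time by regressing the trait
vector(s) on [intercept, dosage, leading genomic PCs]; the PCs absorb
population structure. For a trait pair (k, k') the raw weight of locus l
is the absolute (co)variance contribution |2 q_l (1 - q_l) delta_lk
delta_lk'| which is then normalized by its maximum over loci, so weights
lie in [0, 1] with the top locus at exactly 1. With t traits there are
t(t+1)/2 distinct weight vectors (pairs are unordered).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kernels import KernelMatrix
from .simdata import GenotypeMatrix

__all__ = [
    "SnpEffectMatrix",
    "LocusWeights",
    "top_genomic_pcs",
    "estimate_snp_effects",
    "compute_locus_weights",
]


@dataclass
class SnpEffectMatrix:
    """Allele-substitution effect estimates delta (p x t) with frequencies."""

    deltas: np.ndarray
    allele_freqs: np.ndarray
    n_pcs_used: int
    snp_ids: np.ndarray | None = None


@dataclass
class LocusWeights:
    """Max-normalized locus weights for one unordered trait pair."""

    weights: np.ndarray
    pair: tuple[int, int]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any() or (self.weights > 1 + 1e-12).any():
            raise ValueError("weights must lie in [0, 1]")


def top_genomic_pcs(Gmat: KernelMatrix, n: int) -> np.ndarray:
    """Leading principal-component scores of the genomic relationship matrix.

    Scores are eigenvectors scaled by sqrt(eigenvalue), ordered by
    decreasing eigenvalue, with a deterministic sign convention (the
    largest-magnitude element of each eigenvector is made positive).
    """
    N = Gmat.values.shape[0]
    if n > N - 1:
        raise ValueError(f"cannot extract {n} PCs from {N} individuals")
    eigval, eigvec = np.linalg.eigh(Gmat.values)
    order = np.argsort(eigval)[::-1][:n]
    vec = eigvec[:, order]
    val = np.maximum(eigval[order], 0.0)
    flip = np.sign(vec[np.argmax(np.abs(vec), axis=0), np.arange(n)])
    flip = np.where(flip == 0, 1.0, flip)
    return vec * flip * np.sqrt(val)


def estimate_snp_effects(
    G: GenotypeMatrix,
    Y: np.ndarray,
    pcs: np.ndarray | None = None,
) -> SnpEffectMatrix:
    """SNP-wise multivariate regression of traits on dosage plus PCs.

    For each locus independently, every trait is regressed by ordinary
    least squares on [1, dosage_l, PC_1..PC_m]; the dosage coefficient is
    the allele-substitution effect delta_lk. Because the design is shared
    across traits, equation-by-equation OLS coincides with the
    multivariate-regression point estimates. Computed via
    Frisch-Waugh partialling: dosages and traits are residualized against
    [1, PCs] once, after which each delta is a simple-regression slope.

    Monomorphic/collinear loci get delta = 0 (with a warning) so locus
    indexing stays aligned with the genotype matrix.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != G.n_individuals:
        raise ValueError("response rows must match genotyped individuals")
    if np.isnan(Y).any():
        raise ValueError("missing responses not allowed in SNP-effect estimation")
    X = G.dosages()
    n = X.shape[0]
    covars = np.ones((n, 1))
    n_pcs = 0
    if pcs is not None and pcs.size:
        pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
        covars = np.hstack([covars, pcs])
        n_pcs = pcs.shape[1]
    # residualize against [1, PCs] via a thin QR
    Qc, _ = np.linalg.qr(covars)
    X_res = X - Qc @ (Qc.T @ X)
    Y_res = Y - Qc @ (Qc.T @ Y)
    denom = (X_res * X_res).sum(axis=0)
    degenerate = denom <= n * 1e-12
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} loci degenerate after adjusting for "
            "covariates; their effects are set to 0"
        )
    safe = np.where(degenerate, 1.0, denom)
    deltas = (X_res.T @ Y_res) / safe[:, None]
    deltas[degenerate] = 0.0
    return SnpEffectMatrix(
        deltas=deltas,
        allele_freqs=G.allele_freqs(),
        n_pcs_used=n_pcs,
        snp_ids=G.snp_ids,
    )


def compute_locus_weights(effects: SnpEffectMatrix, k: int, kp: int) -> LocusWeights:
    """Normalized (co)variance weight per locus for trait pair (k, k').

    raw_l = |2 (1 - q_l) q_l delta_lk delta_lk'|; weights = raw / max(raw).
    For k = k' the raw value is the locus variance contribution, otherwise
    the absolute covariance contribution. Invariant to rescaling all
    effects of a trait by a positive constant.
    """
    q = effects.allele_freqs
    k, kp = min(k, kp), max(k, kp)  # (k,k') and (k',k) are the same pair
    raw = np.abs(2.0 * (1.0 - q) * q * effects.deltas[:, k] * effects.deltas[:, kp])
    mx = raw.max() if raw.size else 0.0
    if mx <= 0:
        raise ValueError(
            f"all loci have zero (co)variance for trait pair {(k, kp)}; "
            "weighted kernel undefined"
        )
    return LocusWeights(weights=raw / mx, pair=(min(k, kp), max(k, kp)))
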
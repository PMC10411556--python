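"""Distance matrices, genomic relationships, and the multitask RBF kernel.

The central object is the block kernel Q used by the quasi multitask SVR:
for t traits, Q is an (N*t) x (N*t) symmetric matrix partitioned into t^2
blocks of dimension N x N. Diagonal blocks are RBF kernels
``exp(-theta_kk * d2_ij / denom)`` built from squared Euclidean distances
between marker vectors; off-diagonal blocks are the same form scaled by an
association constant rho_kk' in [-1, 1] with a pair-specific bandwidth
theta_kk'. In the weighted variant each trait pair uses its own
SNP-(co)variance-weighted distance matrix and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simdata import GenotypeMatrix

__all__ = [
    "SquaredEDM",
    "KernelMatrix",
    "MTKernelSpec",
    "MTKernel",
    "compute_sq_edm",
    "compute_weighted_sq_edm",
    "compute_grm",
    "rbf_from_sq_edm",
    "build_mt_kernel",
    "stabilize_psd",
]

_SYM_TOL = 1e-9


@dataclass
class SquaredEDM:
    """Squared Euclidean distances between marker vectors.

    Stores the Hadamard-squared distances directly (no square-root round
    trip) together with the scale denominator used inside the RBF
    exponent: p for the unweighted distance, sum of locus weights for a
    weighted one.
    """

    values: np.ndarray
    scale_denominator: float
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL):
            raise ValueError("distance matrix must be symmetric")
        if (self.values < -_SYM_TOL).any():
            raise ValueError("squared distances must be nonnegative")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if self.scale_denominator <= 0:
            raise ValueError("scale_denominator must be positive")


@dataclass
class KernelMatrix:
    """A symmetric N x N kernel with its provenance kind."""

    values: np.ndarray
    ids: np.ndarray
    kind: str = "precomputed"  # {"rbf", "grm", "precomputed"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL):
            raise ValueError("kernel must be symmetric")
        if self.kind == "rbf" and not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("RBF kernel must have unit diagonal")
        if self.kind == "grm" and np.trace(self.values) <= 0:
            raise ValueError("GRM must have positive trace")


def _as_symmetric(mat: np.ndarray, t: int, name: str) -> np.ndarray:
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    if mat.shape != (t, t):
        raise ValueError(f"{name} must be {t}x{t}")
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be symmetric")
    return mat


@dataclass
class MTKernelSpec:
    """Hyperparameters of the multitask scaled RBF kernel.

    ``theta`` holds trait-specific bandwidths on the diagonal and
    trait-common bandwidths off it; ``rho`` holds the association
    constants (unit diagonal, |rho_kk'| <= 1). ``distances`` maps each
    unordered trait pair (k, k') with k <= k' to the SquaredEDM used for
    that block; in the plain (unweighted) kernel every pair shares one
    distance matrix.
    """

    theta: np.ndarray
    rho: np.ndarray
    distances: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        t = self.theta.shape[0]
        self.theta = _as_symmetric(self.theta, t, "theta")
        self.rho = _as_symmetric(self.rho, t, "rho")
        if (self.theta <= 0).any():
            raise ValueError("bandwidths theta must be positive")
        if not np.allclose(np.diag(self.rho), 1.0):
            raise ValueError("rho must have unit diagonal")
        if (np.abs(self.rho) > 1.0).any():
            raise ValueError("|rho| must not exceed 1")
        for k in range(t):
            for kp in range(k, t):
                if (k, kp) not in self.distances:
                    raise ValueError(f"missing distance matrix for trait pair {(k, kp)}")

    @property
    def n_traits(self) -> int:
        return self.theta.shape[0]

    def distance(self, k: int, kp: int) -> SquaredEDM:
        return self.distances[(min(k, kp), max(k, kp))]

    @classmethod
    def from_shared_distance(cls, theta, rho, D: SquaredEDM) -> "MTKernelSpec":
        """Plain variant: every trait-pair block uses the same distances."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        t = theta.shape[0]
        dist = {(k, kp): D for k in range(t) for kp in range(k, t)}
        return cls(theta=theta, rho=np.atleast_2d(np.asarray(rho, dtype=float)), distances=dist)

    @classmethod
    def single_trait(cls, theta: float, D: SquaredEDM) -> "MTKernelSpec":
        return cls.from_shared_distance([[theta]], [[1.0]], D)


@dataclass
class MTKernel:
    """Realized (N*t) x (N*t) block kernel, trait-major row layout."""

    values: np.ndarray
    n_individuals: int
    spec: MTKernelSpec
    jitter_applied: float = 0.0

    @property
    def n_traits(self) -> int:
        return self.spec.n_traits

    @property
    def ids(self) -> np.ndarray:
        return self.spec.distance(0, 0).ids

    def block(self, k: int, kp: int) -> np.ndarray:
        n = self.n_individuals
        return self.values[k * n : (k + 1) * n, kp * n : (kp + 1) * n]


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def compute_sq_edm(G: GenotypeMatrix) -> SquaredEDM:
    """Pairwise squared Euclidean distances over all genotyped individuals.

    Missing genotypes are mean-imputed per SNP before the distance is
    taken. The scale denominator is p, the number of SNPs.
    """
    X = G.dosages()
    sq = (X * X).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D, 0.0, out=D)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return SquaredEDM(values=D, scale_denominator=float(G.n_snps), ids=G.ids)


def compute_weighted_sq_edm(G: GenotypeMatrix, w: np.ndarray) -> SquaredEDM:
    """Locus-weighted squared distances; denominator is the weight sum."""
    w = np.asarray(w, dtype=float)
    if w.shape != (G.n_snps,):
        raise ValueError("weight vector length must equal the number of SNPs")
    if (w < 0).any() or (w > 1).any():
        raise ValueError("locus weights must lie in [0, 1]")
    wsum = float(w.sum())
    if wsum <= 0:
        raise ValueError("locus weights sum to zero; weighted distance undefined")
    X = G.dosages() * np.sqrt(w)
    sq = (X * X).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D, 0.0, out=D)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return SquaredEDM(values=D, scale_denominator=wsum, ids=G.ids)


def compute_grm(G: GenotypeMatrix) -> KernelMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Z = M - 2q (columns centered at twice the observed allele frequency),
    G = ZZ' / (2 * sum_l q_l (1 - q_l)).
    """
    q = G.allele_freqs()
    het = 2.0 * float((q * (1.0 - q)).sum())
    if het <= 0:
        raise ValueError("all SNPs monomorphic; GRM undefined")
    Z = G.dosages() - 2.0 * q
    vals = (Z @ Z.T) / het
    vals = (vals + vals.T) / 2.0
    return KernelMatrix(values=vals, ids=G.ids, kind="grm")


def rbf_from_sq_edm(D: SquaredEDM, theta: float) -> KernelMatrix:
    """Gaussian kernel ``exp(-theta * d2 / denom)`` with unit diagonal."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    K = np.exp(-theta * D.values / D.scale_denominator)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(values=K, ids=D.ids, kind="rbf")


# ---------------------------------------------------------------------------
# multitask kernel
# ---------------------------------------------------------------------------

def build_mt_kernel(spec: MTKernelSpec) -> MTKernel:
    """Assemble the block kernel Q from bandwidths, rho, and distances."""
    t = spec.n_traits
    n = spec.distance(0, 0).values.shape[0]
    Q = np.empty((n * t, n * t))
    for k in range(t):
        for kp in range(k, t):
            D = spec.distance(k, kp)
            if D.values.shape[0] != n:
                raise ValueError("all per-pair distance matrices must share dimension")
            block = np.exp(-spec.theta[k, kp] * D.values / D.scale_denominator)
            if k == kp:
                np.fill_diagonal(block, 1.0)
            else:
                block = spec.rho[k, kp] * block
            Q[k * n : (k + 1) * n, kp * n : (kp + 1) * n] = block
            if k != kp:
                Q[kp * n : (kp + 1) * n, k * n : (k + 1) * n] = block.T
    return MTKernel(values=Q, n_individuals=n, spec=spec)


def stabilize_psd(Q: MTKernel, min_eig_tol: float = 1e-8) -> MTKernel:
    """Repair indefiniteness by diagonal jitter.

    Q with arbitrary rho/theta need not be positive semidefinite. If the
    smallest eigenvalue is below ``-min_eig_tol``, |lambda_min| + 1e-8 is
    added to the diagonal (preserving off-diagonal structure); otherwise
    the kernel is returned unchanged.
    """
    lam_min = float(np.linalg.eigvalsh(Q.values)[0])
    if lam_min >= -min_eig_tol:
        return Q
    jitter = abs(lam_min) + 1e-8
    vals = Q.values + jitter * np.eye(Q.values.shape[0])
    return MTKernel(
        values=vals,
        n_individuals=Q.n_individuals,
        spec=Q.spec,
        jitter_applied=jitter,
    )
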
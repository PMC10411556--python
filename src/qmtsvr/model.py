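"""Quasi multitask SVR: data expansion, kernel assembly, fit and predict.

A single-trait epsilon-SVR becomes "quasi multitask" by stacking the
standardized records of t traits into one response vector and replacing
the kernel with the block matrix Q (see :mod:`qmtsvr.kernels`): row (k, i)
of the stacked problem is individual i's record on trait k, and the
kernel entry between rows (k, i) and (k', j) is block (k, k') of Q. One
shared bias, C and epsilon apply to all traits, so the standard SMO
solver handles the stacked problem unchanged.

Validation designs:

``ST``
    single trait — only the target trait's training records.
``CV1``
    training individuals contribute records on every trait; testing
    individuals contribute nothing.
``CV2``
    CV1 plus the secondary (non-target) trait records of the testing
    individuals, mimicking indicator traits measured on selection
    candidates.

Predictions are always for the target-trait records of the testing
individuals, returned on the original trait scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import svr as _svr
from .kernels import (
    MTKernel,
    MTKernelSpec,
    SquaredEDM,
    build_mt_kernel,
    compute_grm,
    compute_sq_edm,
    compute_weighted_sq_edm,
    stabilize_psd,
)
from .simdata import GenotypeMatrix, PhenotypeTable, Split
from .snp_weights import (
    LocusWeights,
    compute_locus_weights,
    estimate_snp_effects,
    top_genomic_pcs,
)

__all__ = [
    "StackedDataset",
    "QMTSVR",
    "QMTSVRResults",
    "build_stacked_dataset",
    "assemble_q_submatrices",
    "compute_pair_weights",
    "fit_qmtsvr",
]

DESIGNS = ("ST", "CV1", "CV2")


@dataclass
class StackedDataset:
    """Trait-stacked training/prediction rows with standardized responses.

    Rows are trait-major: all rows of the first trait in ``traits``, then
    the second, etc. ``train_ind`` / ``train_trait`` give, per training
    row, the individual's positional index in the phenotype table and the
    position of its trait within ``traits``; likewise for predict rows
    (always the target trait). Standardizers are per-trait (mean, sd)
    computed on training rows only.
    """

    traits: tuple[int, ...]
    target_pos: int
    design: str
    train_ind: np.ndarray
    train_trait: np.ndarray
    predict_ind: np.ndarray
    y_star: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    ids: np.ndarray

    @property
    def n_train(self) -> int:
        return len(self.train_ind)

    @property
    def n_predict(self) -> int:
        return len(self.predict_ind)

    def destandardize(self, y_star: np.ndarray) -> np.ndarray:
        """Map target-trait predictions back to the original scale."""
        return y_star * self.sds[self.target_pos] + self.means[self.target_pos]


def build_stacked_dataset(
    P: PhenotypeTable,
    split: Split,
    target_trait: int | str = 0,
    design: str = "CV2",
    traits=None,
) -> StackedDataset:
    """Apply the data-expansion scheme for the requested design."""
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    target = P.trait_index(target_trait)
    if traits is None:
        traits = (target,) if design == "ST" else tuple(range(P.n_traits))
    traits = tuple(P.trait_index(t) for t in traits)
    if target not in traits:
        raise ValueError("target trait must be among the modeled traits")
    target_pos = traits.index(target)

    Y = P.trait_values
    missing_target = np.isnan(Y[split.train_idx, target])
    if missing_target.any():
        raise ValueError(
            f"{design} design requires the target trait for every training "
            f"individual; {int(missing_target.sum())} training records missing"
        )

    train_ind, train_trait = [], []
    for pos, k in enumerate(traits):
        if design == "ST" and k != target:
            continue
        obs = split.train_idx[~np.isnan(Y[split.train_idx, k])]
        train_ind.append(obs)
        train_trait.append(np.full(len(obs), pos))
        if design == "CV2" and k != target:
            obs_test_mask = ~np.isnan(Y[split.test_idx, k])
            if not obs_test_mask.all():
                raise ValueError(
                    "CV2 design requires secondary-trait records for testing "
                    f"individuals; trait {k} missing for "
                    f"{int((~obs_test_mask).sum())} of them"
                )
            train_ind.append(split.test_idx)
            train_trait.append(np.full(len(split.test_idx), pos))
    train_ind = np.concatenate(train_ind)
    train_trait = np.concatenate(train_trait)

    # per-trait standardizers from training rows only (no test leakage)
    t = len(traits)
    means = np.zeros(t)
    sds = np.ones(t)
    for pos in range(t):
        vals = Y[train_ind[train_trait == pos], traits[pos]]
        if len(vals) == 0:
            raise ValueError(f"no training records for trait {traits[pos]}")
        means[pos] = vals.mean()
        sds[pos] = vals.std(ddof=0)
        if sds[pos] <= 0:
            raise ValueError(f"trait {traits[pos]} is constant on training rows")
    y_star = (Y[train_ind, np.array(traits)[train_trait]] - means[train_trait]) / sds[
        train_trait
    ]

    return StackedDataset(
        traits=traits,
        target_pos=target_pos,
        design=design,
        train_ind=train_ind,
        train_trait=train_trait,
        predict_ind=split.test_idx.copy(),
        y_star=y_star,
        means=means,
        sds=sds,
        ids=P.ids,
    )


def assemble_q_submatrices(
    Qfull: MTKernel, stacked: StackedDataset, id_order: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the training kernel and test-vs-train cross kernel from Q.

    ``Qfull`` is trait-major over the kernel's individuals; stacked rows
    are mapped by individual id. K_train follows the stacked train-row
    order; K_cross rows are the predict rows (target-trait block row).
    """
    kernel_ids = Qfull.ids if id_order is None else id_order
    pos = {str(i): p for p, i in enumerate(kernel_ids)}
    try:
        ind_pos_train = np.array([pos[str(stacked.ids[i])] for i in stacked.train_ind])
        ind_pos_pred = np.array([pos[str(stacked.ids[i])] for i in stacked.predict_ind])
    except KeyError as exc:  # pragma: no cover - defensive
        raise KeyError(f"individual {exc} not present in the kernel") from exc
    n = Qfull.n_individuals
    flat_train = stacked.train_trait * n + ind_pos_train
    flat_pred = stacked.target_pos * n + ind_pos_pred
    K_train = Qfull.values[np.ix_(flat_train, flat_train)]
    K_cross = Qfull.values[np.ix_(flat_pred, flat_train)]
    return K_train, K_cross


def compute_pair_weights(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    split: Split,
    traits=None,
    n_pcs: int = 30,
) -> dict[tuple[int, int], LocusWeights]:
    """Locus weights for every unordered trait pair, training rows only.

    SNP effects come from the per-SNP regression with genomic PCs fitted
    on the training individuals; allele frequencies likewise. Returns
    t(t+1)/2 weight vectors keyed by (k, k') positions within ``traits``.
    """
    traits = tuple(range(pheno.n_traits)) if traits is None else tuple(traits)
    idx = split.train_idx
    sub_geno = geno.subset_individuals(idx)
    Y = pheno.trait_values[np.ix_(idx, np.array(traits))]
    keep = ~np.isnan(Y).any(axis=1)
    sub_geno = sub_geno.subset_individuals(np.nonzero(keep)[0])
    Y = Y[keep]
    n_pcs = min(n_pcs, sub_geno.n_individuals - 2)
    pcs = top_genomic_pcs(compute_grm(sub_geno), n_pcs) if n_pcs > 0 else None
    effects = estimate_snp_effects(sub_geno, Y, pcs)
    t = len(traits)
    return {
        (k, kp): compute_locus_weights(effects, k, kp)
        for k in range(t)
        for kp in range(k, t)
    }


def _theta_matrix(theta, t: int) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 0:
        return np.full((t, t), float(theta))
    if theta.ndim == 1:  # upper triangle, row-major: th_11, th_12, ..., th_tt
        mat = np.zeros((t, t))
        iu = np.triu_indices(t)
        if len(theta) != len(iu[0]):
            raise ValueError(f"expected {len(iu[0])} bandwidths for t={t}")
        mat[iu] = theta
        return mat + np.triu(mat, 1).T
    return theta


def _rho_matrix(rho, t: int) -> np.ndarray:
    if rho is None:
        rho = 0.0
    rho = np.asarray(rho, dtype=float)
    if rho.ndim == 0:
        mat = np.full((t, t), float(rho))
        np.fill_diagonal(mat, 1.0)
        return mat
    if rho.ndim == 1:  # strict upper triangle, row-major
        mat = np.eye(t)
        iu = np.triu_indices(t, 1)
        if len(rho) != len(iu[0]):
            raise ValueError(f"expected {len(iu[0])} rho values for t={t}")
        mat[iu] = rho
        return mat + np.triu(mat, 1).T - np.diag(np.diag(np.triu(mat, 1).T))
    return rho


class QMTSVR:
    """(Quasi) multitask support vector regression on SNP kernels.

    Parameters
    ----------
    pheno, geno
        Phenotype table and genotype matrix over the same individuals.
    split
        Forward train/test partition (see :func:`qmtsvr.simdata.forward_split`).
    target_trait
        Trait to predict (index or name).
    design
        "ST", "CV1" or "CV2".
    traits
        Traits entering the stacked model (default: all for CV1/CV2,
        target only for ST).
    weighted
        Use SNP-(co)variance-weighted distances per trait pair. Weights
        are estimated from the training rows unless passed to ``fit``.
    kernel_kind
        "rbf" (default) or "grm" — the latter gives the linear-kernel SVR
        (ST design only), using the genomic relationship matrix directly.

    Examples
    --------
    >>> model = QMTSVR(pheno, geno, split, target_trait=0, design="CV2")
    >>> res = model.fit(C=1.0, eps=0.01, theta=[1.5, 2.0, 1.0], rho=[0.2])
    >>> res.predictions.head()
    """

    def __init__(
        self,
        pheno: PhenotypeTable,
        geno: GenotypeMatrix,
        split: Split,
        target_trait: int | str = 0,
        design: str = "CV2",
        traits=None,
        weighted: bool = False,
        kernel_kind: str = "rbf",
    ):
        if kernel_kind not in ("rbf", "grm"):
            raise ValueError("kernel_kind must be 'rbf' or 'grm'")
        self.pheno = pheno
        self.geno = geno
        self.split = split
        self.design = design
        self.target = pheno.trait_index(target_trait)
        if traits is None:
            traits = (self.target,) if design == "ST" else tuple(range(pheno.n_traits))
        self.traits = tuple(pheno.trait_index(t) for t in traits)
        self.weighted = weighted
        self.kernel_kind = kernel_kind
        if kernel_kind == "grm" and (design != "ST" or weighted):
            raise ValueError("the linear (GRM) kernel is supported for plain ST only")
        self._sq_edm: SquaredEDM | None = None
        self._grm = None
        self._pair_weights: dict | None = None

    # -- cached building blocks ------------------------------------------
    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def sq_edm(self) -> SquaredEDM:
        if self._sq_edm is None:
            self._sq_edm = compute_sq_edm(self.geno)
        return self._sq_edm

    def set_sq_edm(self, D: SquaredEDM) -> None:
        """Inject a precomputed distance matrix (e.g. shared across GA runs)."""
        self._sq_edm = D

    def pair_weights(self, n_pcs: int = 30) -> dict:
        if self._pair_weights is None:
            self._pair_weights = compute_pair_weights(
                self.geno, self.pheno, self.split, self.traits, n_pcs=n_pcs
            )
        return self._pair_weights

    def set_pair_weights(self, weights: dict) -> None:
        self._pair_weights = dict(weights)

    def build_kernel(self, theta, rho=None, weights=None) -> MTKernel:
        """Assemble (and PSD-stabilize) the block kernel for this model."""
        t = self.n_traits
        theta_m = _theta_matrix(theta, t)
        rho_m = _rho_matrix(rho, t)
        if self.weighted:
            weights = self.pair_weights() if weights is None else weights
            dist = {}
            for k in range(t):
                for kp in range(k, t):
                    w = weights[(k, kp)]
                    w = w.weights if isinstance(w, LocusWeights) else np.asarray(w)
                    dist[(k, kp)] = compute_weighted_sq_edm(self.geno, w)
            spec = MTKernelSpec(theta=theta_m, rho=rho_m, distances=dist)
        else:
            spec = MTKernelSpec.from_shared_distance(theta_m, rho_m, self.sq_edm())
        return stabilize_psd(build_mt_kernel(spec))

    # -- fitting ---------------------------------------------------------
    def fit(
        self,
        C: float = 1.0,
        eps: float = 0.01,
        theta=1.0,
        rho=None,
        weights: dict | None = None,
        tol: float = 1e-3,
        max_passes: int = 10_000,
    ) -> "QMTSVRResults":
        stacked = build_stacked_dataset(
            self.pheno, self.split, self.target, self.design, self.traits
        )
        if self.kernel_kind == "grm":
            if self._grm is None:
                self._grm = compute_grm(self.geno)
            Kfull = self._grm.values
            K_train = Kfull[np.ix_(stacked.train_ind, stacked.train_ind)]
            K_cross = Kfull[np.ix_(stacked.predict_ind, stacked.train_ind)]
            jitter = 0.0
        else:
            Q = self.build_kernel(theta, rho, weights)
            K_train, K_cross = assemble_q_submatrices(Q, stacked)
            jitter = Q.jitter_applied
        prob = _svr.SVRProblem(
            K=K_train, y=stacked.y_star, C=C, eps=eps, tol=tol, max_passes=max_passes
        )
        svr_model = _svr.fit_epsilon_svr(prob)
        pred_star = _svr.svr_predict(svr_model, K_cross)
        predictions = stacked.destandardize(pred_star)
        return QMTSVRResults(
            model=self,
            svr=svr_model,
            stacked=stacked,
            params={
                "C": C,
                "eps": eps,
                "theta": _theta_matrix(theta, self.n_traits),
                "rho": _rho_matrix(rho, self.n_traits),
            },
            jitter_applied=jitter,
            predicted_values=predictions,
        )


@dataclass
class QMTSVRResults:
    """Fitted QMTSVR: dual solution, diagnostics and test predictions."""

    model: QMTSVR
    svr: _svr.SVRModel
    stacked: StackedDataset
    params: dict
    jitter_applied: float
    predicted_values: np.ndarray
    _pred_df: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def predictions(self) -> pd.DataFrame:
        """Test-set predictions on the original trait scale."""
        if self._pred_df is None:
            P = self.model.pheno
            idx = self.stacked.predict_ind
            label = ("W" if self.model.weighted else "") + (
                "QMTSVR" if self.model.design != "ST" else "SVR"
            )
            if self.model.kernel_kind == "grm":
                label = "SVR_Lin"
            self._pred_df = pd.DataFrame(
                {
                    "id": P.ids[idx],
                    "generation": P.generation[idx],
                    "design": self.model.design,
                    "model": label,
                    "predicted": self.predicted_values,
                }
            )
        return self._pred_df

    def predict(self) -> pd.DataFrame:
        return self.predictions

    @property
    def n_support_vectors(self) -> int:
        return self.svr.n_support_vectors

    def summary(self) -> str:
        p = self.params
        t = self.model.n_traits
        lines = [
            "Quasi multitask SVR results",
            "===========================",
            f"design: {self.model.design}   traits: {t}   "
            f"target: {self.model.pheno.trait_names[self.model.target]}",
            f"kernel: {self.model.kernel_kind}"
            + (" (SNP-weighted)" if self.model.weighted else ""),
            f"train rows: {self.stacked.n_train}   "
            f"predict rows: {self.stacked.n_predict}",
            f"C = {p['C']:.4g}   eps = {p['eps']:.4g}",
            f"theta = {np.array2string(p['theta'], precision=3)}",
            f"rho = {np.array2string(p['rho'], precision=3)}",
            f"support vectors: {self.svr.n_support_vectors} / {self.stacked.n_train}",
            f"b0 = {self.svr.b0:.5g}   dual objective = "
            f"{self.svr.objective_value:.5g}",
            f"SMO pair updates: {self.svr.n_iterations}   "
            f"max KKT violation: {self.svr.max_kkt_violation:.2e}",
            f"PSD jitter applied: {self.jitter_applied:.2e}",
        ]
        return "\n".join(lines)


def fit_qmtsvr(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    split: Split,
    C: float,
    eps: float,
    theta,
    rho=None,
    design: str = "CV2",
    target_trait: int | str = 0,
    weighted: bool = False,
    weights: dict | None = None,
    **kwargs,
) -> QMTSVRResults:
    """Functional one-shot wrapper around :class:`QMTSVR`."""
    model = QMTSVR(
        pheno, geno, split, target_trait=target_trait, design=design, weighted=weighted
    )
    return model.fit(C=C, eps=eps, theta=theta, rho=rho, weights=weights, **kwargs)
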
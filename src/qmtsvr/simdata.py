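"""Synthetic multi-generation breeding populations for genomic prediction.

Emulates a closed population bred for several discrete mating generations
(MG), genotyped at biallelic SNPs coded 0/1/2, with two (or more) correlated
polygenic traits. The generator provides everything the downstream kernel /
SVR / mixed-model machinery needs to be exercised offline: genotypes with
optional missingness, phenotypes with known true breeding values (TBV),
per-trait reliabilities, and generation labels for forward-in-time
validation splits.

The quantitative-genetic model is additive (optionally with a pairwise
epistatic component): a set of QTL receives per-trait effects drawn from a
multivariate normal whose correlation matrix is the target genetic
correlation; genetic values are rescaled so the realized heritabilities
match the requested ones, and residuals are drawn with the requested
residual correlation. Phenotypic variance is 1 per trait by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "SimConfig",
    "Split",
    "QCReport",
    "simulate_population",
    "qc_filter_snps",
    "reliability_filter",
    "forward_split",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with codes {0, 1, 2}.

    ``values`` holds integer dosages; entries flagged in ``missing_mask``
    are undefined (stored as 0 but never read directly — use
    :meth:`dosages` which mean-imputes them).
    """

    values: np.ndarray
    missing_mask: np.ndarray
    ids: np.ndarray
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.ids = np.asarray(self.ids)
        self.snp_ids = np.asarray(self.snp_ids)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if self.values.shape[0] < 2 or self.values.shape[1] < 1:
            raise ValueError("need at least 2 individuals and 1 SNP")
        obs = self.values[~self.missing_mask]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("genotype codes must be in {0, 1, 2}")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("individual ids must be unique")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Observed second-allele frequency q_l per SNP (missing excluded)."""
        vals = np.where(self.missing_mask, np.nan, self.values.astype(float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            q = np.nanmean(vals, axis=0) / 2.0
        return np.where(np.isfinite(q), q, 0.0)

    def minor_allele_freqs(self) -> np.ndarray:
        q = self.allele_freqs()
        return np.minimum(q, 1.0 - q)

    def call_rates(self) -> np.ndarray:
        return 1.0 - self.missing_mask.mean(axis=0)

    def dosages(self) -> np.ndarray:
        """Float dosage matrix with missing entries mean-imputed per SNP."""
        X = self.values.astype(float)
        if self.missing_mask.any():
            q = self.allele_freqs()
            col_mean = 2.0 * q
            rows, cols = np.nonzero(self.missing_mask)
            X[rows, cols] = col_mean[cols]
        return X

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values[idx], self.missing_mask[idx], self.ids[idx], self.snp_ids
        )

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values[:, mask],
            self.missing_mask[:, mask],
            self.ids,
            self.snp_ids[mask],
        )


@dataclass
class PhenotypeTable:
    """Per-individual records: generation label, trait values, reliabilities.

    ``trait_values`` is N x t (NaN = missing); ``reliabilities`` is the
    per-trait reliability of the response (the analogue of a DRP
    reliability), used both as a QC filter and as the denominator of the
    corrected accuracy. ``true_breeding_values`` is only available for
    simulated data.
    """

    ids: np.ndarray
    generation: np.ndarray
    trait_values: np.ndarray
    trait_names: Sequence[str] = field(default_factory=list)
    reliabilities: np.ndarray | None = None
    true_breeding_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.generation = np.asarray(self.generation, dtype=int)
        self.trait_values = np.atleast_2d(np.asarray(self.trait_values, dtype=float))
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("one record per individual required")
        if (self.generation < 0).any():
            raise ValueError("generation labels must be nonnegative")
        if not self.trait_names:
            self.trait_names = [f"trait_{k + 1}" for k in range(self.n_traits)]
        self.trait_names = list(self.trait_names)
        if self.reliabilities is not None:
            self.reliabilities = np.asarray(self.reliabilities, dtype=float)
            if ((self.reliabilities < 0) | (self.reliabilities > 1)).any():
                raise ValueError("reliabilities must lie in [0, 1]")
        if self.true_breeding_values is not None:
            self.true_breeding_values = np.asarray(
                self.true_breeding_values, dtype=float
            )

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_traits(self) -> int:
        return self.trait_values.shape[1]

    def trait_index(self, trait: int | str) -> int:
        if isinstance(trait, str):
            return list(self.trait_names).index(trait)
        return int(trait)

    def subset(self, idx: np.ndarray) -> "PhenotypeTable":
        return PhenotypeTable(
            ids=self.ids[idx],
            generation=self.generation[idx],
            trait_values=self.trait_values[idx],
            trait_names=self.trait_names,
            reliabilities=None if self.reliabilities is None else self.reliabilities[idx],
            true_breeding_values=None
            if self.true_breeding_values is None
            else self.true_breeding_values[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {"id": self.ids, "generation": self.generation}
        for k, name in enumerate(self.trait_names):
            data[name] = self.trait_values[:, k]
        if self.reliabilities is not None:
            for k, name in enumerate(self.trait_names):
                data[f"rel_{name}"] = self.reliabilities[:, k]
        if self.true_breeding_values is not None:
            for k, name in enumerate(self.trait_names):
                data[f"tbv_{name}"] = self.true_breeding_values[:, k]
        return pd.DataFrame(data)


def _check_correlation(mat: np.ndarray, name: str, t: int) -> np.ndarray:
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    if mat.shape != (t, t):
        raise ValueError(f"{name} must be {t}x{t}")
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(mat), 1.0):
        raise ValueError(f"{name} must have unit diagonal")
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals.min() <= 1e-10:
        raise ValueError(
            f"{name} is not positive definite (min eigenvalue {eigvals.min():.3g})"
        )
    return mat


@dataclass
class SimConfig:
    """Study conditions for :func:`simulate_population`.

    Defaults mirror a broiler-type scenario: two traits with
    heritabilities 0.56 (carcass-type target) and 0.34 (growth-type
    indicator), genetic correlation 0.23 and residual correlation 0.47,
    genotyped at densely spaced biallelic SNPs, phenotyped over five
    discrete mating generations.
    """

    n_per_generation: int = 100
    n_generations: int = 5
    p_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int | None = None  # default: min(100, p_snps // 2) — polygenic
    h2: Sequence[float] = (0.56, 0.34)
    genetic_corr: np.ndarray | float = 0.23
    residual_corr: np.ndarray | float = 0.47
    epistasis_fraction: float = 0.0
    missing_rate: float = 0.0
    reliability_range: tuple[float, float] = (0.5, 0.95)
    selection_fraction: float = 1.0  # 1.0 = random mating, <1 truncation on trait 1
    trait_names: Sequence[str] | None = None
    seed: int = 0

    def corr_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        t = len(self.h2)

        def expand(c):
            c = np.asarray(c, dtype=float)
            if c.ndim == 0:
                m = np.full((t, t), float(c))
                np.fill_diagonal(m, 1.0)
                return m
            return c

        rg = _check_correlation(expand(self.genetic_corr), "genetic_corr", t)
        re = _check_correlation(expand(self.residual_corr), "residual_corr", t)
        return rg, re

    def validate(self) -> None:
        h2 = np.asarray(self.h2, dtype=float)
        if ((h2 <= 0) | (h2 >= 1)).any():
            raise ValueError("heritabilities must lie in (0, 1)")
        if not 0.0 <= self.epistasis_fraction <= 1.0:
            raise ValueError("epistasis_fraction must lie in [0, 1]")
        if not 0.0 < self.selection_fraction <= 1.0:
            raise ValueError("selection_fraction must lie in (0, 1]")
        if self.resolved_n_qtl() > self.p_snps:
            raise ValueError("n_qtl cannot exceed p_snps")
        self.corr_matrices()

    def resolved_n_qtl(self) -> int:
        if self.n_qtl is None:
            return max(min(100, self.p_snps // 2), 1)
        return int(self.n_qtl)


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

def simulate_population(config: SimConfig) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Simulate genotypes and correlated polygenic phenotypes.

    Generation 0 genotypes are drawn per SNP as binomial(2, q_l) with q_l
    uniform on ``maf_range``; later generations arise by Mendelian gamete
    sampling from randomly mated parents of the previous generation
    (optionally truncation-selected on trait 1), which induces drift.
    Genetic values from MVN-distributed QTL effects are rescaled so that
    var(TBV)/var(y) matches ``h2`` per trait; residuals carry the
    requested residual correlation. Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = len(config.h2)
    h2 = np.asarray(config.h2, dtype=float)
    rg, re = config.corr_matrices()
    n, G, p = config.n_per_generation, config.n_generations, config.p_snps

    q0 = rng.uniform(*config.maf_range, size=p)
    genos = [rng.binomial(2, q0, size=(n, p)).astype(np.int8)]

    # QTL architecture: shared loci, per-trait effects correlated across traits
    n_qtl = config.resolved_n_qtl()
    qtl_idx = rng.choice(p, size=n_qtl, replace=False)
    qtl_effects = rng.multivariate_normal(np.zeros(t), rg, size=n_qtl)

    def genetic_values(geno: np.ndarray) -> np.ndarray:
        Z = geno[:, qtl_idx].astype(float)
        g = (Z - Z.mean(axis=0)) @ qtl_effects
        if config.epistasis_fraction > 0.0:
            g_add = _standardize_cols(g)
            g_epi = _standardize_cols(_epistatic_values(Z, epi_pairs, epi_effects))
            g = (
                np.sqrt(1.0 - config.epistasis_fraction) * g_add
                + np.sqrt(config.epistasis_fraction) * g_epi
            )
        return g

    if config.epistasis_fraction > 0.0:
        n_pairs = max(n_qtl // 2, 1)
        epi_pairs = rng.choice(n_qtl, size=(n_pairs, 2))
        epi_effects = rng.multivariate_normal(np.zeros(t), rg, size=n_pairs)

    # breed forward; selection (if any) acts on a provisional trait-1 phenotype
    for _ in range(1, G):
        prev = genos[-1]
        if config.selection_fraction < 1.0:
            g_prev = genetic_values(prev)
            y1 = g_prev[:, 0] + rng.standard_normal(n) * np.std(g_prev[:, 0]) * np.sqrt(
                max(1.0 / h2[0] - 1.0, 1e-12)
            )
            n_parents = max(int(np.ceil(n * config.selection_fraction)), 2)
            pool = np.argsort(-y1)[:n_parents]
        else:
            pool = np.arange(n)
        sires = rng.choice(pool, size=n)
        dams = rng.choice(pool, size=n)
        same = sires == dams
        while same.any():  # avoid selfing
            dams[same] = rng.choice(pool, size=same.sum())
            same = sires == dams
        gam1 = rng.binomial(1, prev[sires].astype(float) / 2.0)
        gam2 = rng.binomial(1, prev[dams].astype(float) / 2.0)
        genos.append((gam1 + gam2).astype(np.int8))

    values = np.vstack(genos)
    N = values.shape[0]
    generation = np.repeat(np.arange(G), n)
    ids = np.array([f"G{g}_I{i:04d}" for g, i in zip(generation, range(N))])
    snp_ids = np.array([f"SNP{j + 1:05d}" for j in range(p)])

    # genetic values scaled so realized h2 matches targets (phenotypic var 1)
    g_raw = genetic_values(values)
    tbv = _standardize_cols(g_raw) * np.sqrt(h2)
    sd_e = np.sqrt(1.0 - h2)
    E = rng.multivariate_normal(np.zeros(t), re, size=N) * sd_e
    y = tbv + E

    rel = rng.uniform(*config.reliability_range, size=(N, t))

    missing = np.zeros_like(values, dtype=bool)
    if config.missing_rate > 0.0:
        missing = rng.random(values.shape) < config.missing_rate

    trait_names = (
        list(config.trait_names)
        if config.trait_names is not None
        else [f"trait_{k + 1}" for k in range(t)]
    )
    geno = GenotypeMatrix(values, missing, ids, snp_ids)
    pheno = PhenotypeTable(
        ids=ids,
        generation=generation,
        trait_values=y,
        trait_names=trait_names,
        reliabilities=rel,
        true_breeding_values=tbv,
    )
    return geno, pheno


def _standardize_cols(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - x.mean(axis=0)) / sd


def _epistatic_values(Z, pairs, effects) -> np.ndarray:
    Zc = Z - Z.mean(axis=0)
    prod = Zc[:, pairs[:, 0]] * Zc[:, pairs[:, 1]]
    return prod @ effects


# ---------------------------------------------------------------------------
# quality control & splitting
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_input: int
    n_retained: int
    n_removed_maf: int
    n_removed_call_rate: int
    kept_mask: np.ndarray


def qc_filter_snps(
    G: GenotypeMatrix, maf_min: float = 0.05, call_rate_min: float = 0.95
) -> tuple[GenotypeMatrix, QCReport]:
    """Retain SNPs with MAF > ``maf_min`` and call rate > ``call_rate_min``.

    Both criteria are strict inequalities. Returns the filtered matrix and
    a report with counts removed per criterion (a SNP failing both is
    counted under each).
    """
    if not 0.0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    if not 0.0 < call_rate_min <= 1.0:
        raise ValueError("call_rate_min must lie in (0, 1]")
    maf_ok = G.minor_allele_freqs() > maf_min
    cr_ok = G.call_rates() > call_rate_min
    kept = maf_ok & cr_ok
    if not kept.any():
        raise ValueError("QC removed all SNPs")
    report = QCReport(
        n_input=G.n_snps,
        n_retained=int(kept.sum()),
        n_removed_maf=int((~maf_ok).sum()),
        n_removed_call_rate=int((~cr_ok).sum()),
        kept_mask=kept,
    )
    return G.subset_snps(kept), report


def reliability_filter(P: PhenotypeTable, r_min: float = 0.4) -> PhenotypeTable:
    """Keep individuals whose reliability exceeds ``r_min`` in every trait."""
    if P.reliabilities is None:
        raise ValueError("phenotype table has no reliabilities")
    keep = (P.reliabilities > r_min).all(axis=1)
    if not keep.any():
        warnings.warn("reliability filter removed every individual")
    return P.subset(np.nonzero(keep)[0])


@dataclass
class Split:
    """Forward-in-time train/test partition by mating generation."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    train_generations: frozenset
    test_generations: frozenset

    def inner(self, P: PhenotypeTable, validation_generations) -> "Split":
        """Nested split of the training set for hyperparameter fitness.

        The validation generations are carved out of this split's training
        generations (they are withheld during tuning and restored when the
        final model is retrained on the full training set).
        """
        val = frozenset(int(g) for g in validation_generations)
        if not val <= self.train_generations:
            raise ValueError("inner validation generations must be training generations")
        inner_train = self.train_generations - val
        return forward_split(P, sorted(inner_train), sorted(val))


def forward_split(
    P: PhenotypeTable, train_generations, test_generations
) -> Split:
    """Partition individuals by generation label into train and test sets."""
    train_g = frozenset(int(g) for g in train_generations)
    test_g = frozenset(int(g) for g in test_generations)
    if train_g & test_g:
        raise ValueError(f"overlapping generation sets: {sorted(train_g & test_g)}")
    train_idx = np.nonzero(np.isin(P.generation, sorted(train_g)))[0]
    test_idx = np.nonzero(np.isin(P.generation, sorted(test_g)))[0]
    return Split(train_idx, test_idx, train_g, test_g)
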
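"""Simulator bookkeeping, moment recovery, QC filters, forward splits."""

import numpy as np
import pytest

from qmtsvr.simdata import (
    GenotypeMatrix,
    PhenotypeTable,
    SimConfig,
    forward_split,
    qc_filter_snps,
    reliability_filter,
    simulate_population,
)


class TestSimulatePopulation:
    def test_bookkeeping(self):
        cfg = SimConfig(n_per_generation=100, n_generations=5, p_snps=120, seed=1)
        geno, pheno = simulate_population(cfg)
        assert geno.n_individuals == 500
        assert pheno.n_individuals == 500
        assert sorted(np.unique(pheno.generation)) == [0, 1, 2, 3, 4]
        assert np.bincount(pheno.generation).tolist() == [100] * 5

    def test_reproducible_from_seed(self):
        cfg = SimConfig(n_per_generation=30, n_generations=3, p_snps=80, seed=9)
        g1, p1 = simulate_population(cfg)
        g2, p2 = simulate_population(cfg)
        np.testing.assert_array_equal(g1.values, g2.values)
        np.testing.assert_allclose(p1.trait_values, p2.trait_values)

    def test_independent_traits_have_near_zero_tbv_correlation(self):
        cfg = SimConfig(
            n_per_generation=1000,
            n_generations=2,
            p_snps=400,
            n_qtl=150,
            h2=(0.5, 0.5),
            genetic_corr=0.0,
            residual_corr=0.0,
            seed=3,
        )
        _, pheno = simulate_population(cfg)
        r = np.corrcoef(pheno.true_breeding_values.T)[0, 1]
        assert abs(r) < 0.1

    def test_realized_heritabilities_match_targets(self):
        cfg = SimConfig(
            n_per_generation=1000,
            n_generations=5,
            p_snps=500,
            n_qtl=150,
            h2=(0.56, 0.34),
            genetic_corr=0.23,
            residual_corr=0.47,
            seed=5,
        )
        _, pheno = simulate_population(cfg)
        h2_real = pheno.true_breeding_values.var(axis=0) / pheno.trait_values.var(
            axis=0
        )
        np.testing.assert_allclose(h2_real, [0.56, 0.34], atol=0.05)
        rg_real = np.corrcoef(pheno.true_breeding_values.T)[0, 1]
        assert abs(rg_real - 0.23) < 0.1

    def test_moment_recovery_across_seeds(self):
        """Mean realized h2 / r_g over many replicates stays on target."""
        h2s, rgs = [], []
        for seed in range(20):
            cfg = SimConfig(
                n_per_generation=400,
                n_generations=5,
                p_snps=300,
                n_qtl=100,
                h2=(0.5, 0.4),
                genetic_corr=0.3,
                residual_corr=0.2,
                seed=seed,
            )
            _, pheno = simulate_population(cfg)
            h2s.append(
                pheno.true_breeding_values.var(axis=0)
                / pheno.trait_values.var(axis=0)
            )
            rgs.append(np.corrcoef(pheno.true_breeding_values.T)[0, 1])
        np.testing.assert_allclose(np.mean(h2s, axis=0), [0.5, 0.4], atol=0.05)
        assert abs(np.mean(rgs) - 0.3) < 0.05

    def test_non_pd_correlation_rejected(self):
        cfg = SimConfig(h2=(0.5, 0.5, 0.5), genetic_corr=np.array(
            [[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]]
        ), residual_corr=0.0)
        with pytest.raises(ValueError, match="positive definite"):
            simulate_population(cfg)

    def test_missing_rate(self):
        cfg = SimConfig(n_per_generation=100, n_generations=2, p_snps=200,
                        missing_rate=0.05, seed=2)
        geno, _ = simulate_population(cfg)
        assert 0.03 < geno.missing_mask.mean() < 0.07

    def test_selection_shifts_trait_one(self):
        base = dict(n_per_generation=300, n_generations=5, p_snps=300,
                    h2=(0.5, 0.4), genetic_corr=0.3, residual_corr=0.2, seed=8)
        _, sel = simulate_population(SimConfig(selection_fraction=0.3, **base))
        gen = sel.generation
        tbv1 = sel.true_breeding_values[:, 0]
        assert tbv1[gen == 4].mean() > tbv1[gen == 0].mean() + 0.2


class TestQCFilters:
    def test_maf_threshold(self):
        # 3 SNPs with MAF 0.02, 0.10, 0.50 over 50 individuals, no missing
        n = 50
        vals = np.zeros((n, 3), dtype=int)
        vals[:2, 0] = 1      # q = 0.02
        vals[:10, 1] = 1     # q = 0.10
        vals[:25, 2] = 2     # q = 0.50
        G = GenotypeMatrix(vals, np.zeros_like(vals, bool),
                           np.arange(n).astype(str), np.array(["a", "b", "c"]))
        filt, report = qc_filter_snps(G, maf_min=0.05, call_rate_min=0.95)
        assert list(filt.snp_ids) == ["b", "c"]
        assert report.n_removed_maf == 1

    def test_call_rate_threshold(self):
        n = 100
        vals = np.ones((n, 2), dtype=int)
        vals[::2, :] = 2  # polymorphic so MAF passes
        miss = np.zeros_like(vals, bool)
        miss[:10, 0] = True  # 10% missing -> call rate 0.9
        G = GenotypeMatrix(vals, miss, np.arange(n).astype(str),
                           np.array(["drop", "keep"]))
        filt, report = qc_filter_snps(G, maf_min=0.05, call_rate_min=0.95)
        assert filt.snp_ids.tolist() == ["keep"]
        assert report.n_removed_call_rate == 1

    def test_matches_bruteforce(self, rng):
        vals = rng.integers(0, 3, size=(100, 200))
        miss = rng.random((100, 200)) < 0.04
        G = GenotypeMatrix(vals, miss, np.arange(100).astype(str),
                           np.array([f"s{j}" for j in range(200)]))
        filt, _ = qc_filter_snps(G, 0.05, 0.97)
        expected = []
        for j in range(200):
            obs = vals[~miss[:, j], j]
            q = obs.mean() / 2.0
            maf = min(q, 1 - q)
            call = len(obs) / 100
            if maf > 0.05 and call > 0.97:
                expected.append(f"s{j}")
        assert filt.snp_ids.tolist() == expected

    def test_idempotent(self, small_pop):
        geno, _ = small_pop
        once, _ = qc_filter_snps(geno, 0.1, 0.95)
        twice, rep = qc_filter_snps(once, 0.1, 0.95)
        assert rep.n_retained == once.n_snps
        np.testing.assert_array_equal(once.values, twice.values)

    def test_all_removed_errors(self):
        vals = np.zeros((10, 2), dtype=int)  # monomorphic: MAF = 0
        G = GenotypeMatrix(vals, np.zeros_like(vals, bool),
                           np.arange(10).astype(str), np.array(["a", "b"]))
        with pytest.raises(ValueError, match="all SNPs"):
            qc_filter_snps(G)


class TestReliabilityFilter:
    def _table(self, rel):
        n = rel.shape[0]
        return PhenotypeTable(
            ids=np.arange(n).astype(str),
            generation=np.zeros(n, int),
            trait_values=np.zeros((n, rel.shape[1])),
            reliabilities=rel,
        )

    def test_fails_one_trait_removed(self):
        P = self._table(np.array([[0.5, 0.3], [0.9, 0.9]]))
        out = reliability_filter(P, 0.4)
        assert out.ids.tolist() == ["1"]

    def test_all_reliable_is_identity(self):
        P = self._table(np.ones((5, 2)))
        out = reliability_filter(P, 0.4)
        assert out.n_individuals == 5

    def test_matches_bruteforce(self, rng):
        rel = rng.random((50, 3))
        P = self._table(rel)
        out = reliability_filter(P, 0.4)
        expected = sum(1 for row in rel if row.min() > 0.4)
        assert out.n_individuals == expected


class TestForwardSplit:
    def test_partition(self, small_pop):
        _, pheno = small_pop
        s = forward_split(pheno, [0, 1, 2], [3, 4])
        assert len(s.train_idx) + len(s.test_idx) == pheno.n_individuals
        assert not set(s.train_idx) & set(s.test_idx)

    def test_empty_test_set(self, small_pop):
        _, pheno = small_pop
        s = forward_split(pheno, [0, 1, 2, 3, 4], [])
        assert len(s.train_idx) == pheno.n_individuals
        assert len(s.test_idx) == 0

    def test_overlap_rejected(self, small_pop):
        _, pheno = small_pop
        with pytest.raises(ValueError, match="overlap"):
            forward_split(pheno, [0, 1, 2], [2, 3])

    def test_nested_inner_split(self, small_pop):
        """Tuning withholds late training generations as inner validation."""
        _, pheno = small_pop
        outer = forward_split(pheno, [0, 1, 2, 3], [4])
        inner = outer.inner(pheno, [3])
        assert inner.train_generations == frozenset({0, 1, 2})
        assert inner.test_generations == frozenset({3})
        assert set(inner.train_idx) | set(inner.test_idx) == set(outer.train_idx)
        with pytest.raises(ValueError):
            outer.inner(pheno, [4])
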
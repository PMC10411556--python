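"""Data expansion, Q-submatrix assembly, and QMTSVR fit/predict."""

import numpy as np
import pytest

from qmtsvr.kernels import MTKernelSpec, build_mt_kernel, compute_sq_edm
from qmtsvr.model import (
    QMTSVR,
    assemble_q_submatrices,
    build_stacked_dataset,
)
from qmtsvr.simdata import forward_split
from qmtsvr.svr import SVRProblem, fit_epsilon_svr


class TestStackedDataset:
    def test_row_counts_by_design(self, small_pop, small_split):
        _, pheno = small_pop
        n_train, n_test = len(small_split.train_idx), len(small_split.test_idx)
        st = build_stacked_dataset(pheno, small_split, 0, "ST")
        cv1 = build_stacked_dataset(pheno, small_split, 0, "CV1")
        cv2 = build_stacked_dataset(pheno, small_split, 0, "CV2")
        assert st.n_train == n_train
        assert cv1.n_train == 2 * n_train
        assert cv2.n_train == 2 * n_train + n_test
        for d in (st, cv1, cv2):
            assert d.n_predict == n_test

    def test_standardize_round_trip(self, small_pop, small_split):
        _, pheno = small_pop
        d = build_stacked_dataset(pheno, small_split, 0, "CV1")
        target_rows = d.train_trait == d.target_pos
        raw = pheno.trait_values[d.train_ind[target_rows], d.traits[d.target_pos]]
        np.testing.assert_allclose(
            d.destandardize(d.y_star[target_rows]), raw, atol=1e-12
        )

    def test_trait_major_ordering(self, small_pop, small_split):
        _, pheno = small_pop
        d = build_stacked_dataset(pheno, small_split, 0, "CV2")
        # trait blocks must be contiguous and ordered
        changes = np.nonzero(np.diff(d.train_trait))[0]
        assert len(changes) == 1

    def test_cv2_missing_secondary_errors(self, small_pop, small_split):
        _, pheno = small_pop
        pheno2 = pheno.subset(np.arange(pheno.n_individuals))
        pheno2.trait_values[small_split.test_idx[0], 1] = np.nan
        with pytest.raises(ValueError, match="CV2"):
            build_stacked_dataset(pheno2, small_split, 0, "CV2")

    def test_missing_target_in_training_errors(self, small_pop, small_split):
        _, pheno = small_pop
        pheno2 = pheno.subset(np.arange(pheno.n_individuals))
        pheno2.trait_values[small_split.train_idx[0], 0] = np.nan
        with pytest.raises(ValueError, match="target trait"):
            build_stacked_dataset(pheno2, small_split, 0, "CV1")


class TestAssembly:
    def test_hand_indexed_toy(self, small_pop, small_split):
        geno, pheno = small_pop
        D = compute_sq_edm(geno)
        theta = np.array([[1.0, 2.0], [2.0, 1.5]])
        rho = np.array([[1.0, 0.3], [0.3, 1.0]])
        Q = build_mt_kernel(MTKernelSpec.from_shared_distance(theta, rho, D))
        d = build_stacked_dataset(pheno, small_split, 0, "CV2")
        K_train, K_cross = assemble_q_submatrices(Q, d)
        n = geno.n_individuals
        p = geno.n_snps
        # spot-check entries against direct elementwise evaluation
        rng = np.random.default_rng(0)
        for _ in range(40):
            a, b = rng.integers(0, d.n_train, size=2)
            i, k = d.train_ind[a], d.train_trait[a]
            j, kp = d.train_ind[b], d.train_trait[b]
            d2 = D.values[i, j]
            expected = np.exp(-theta[k, kp] * d2 / p)
            if k != kp:
                expected *= rho[k, kp]
            elif i == j:
                expected = 1.0
            assert K_train[a, b] == pytest.approx(expected, rel=1e-12)
        for _ in range(20):
            a = rng.integers(0, d.n_predict)
            b = rng.integers(0, d.n_train)
            i = d.predict_ind[a]
            j, kp = d.train_ind[b], d.train_trait[b]
            expected = np.exp(-theta[0, kp] * D.values[i, j] / p)
            if kp != 0:
                expected *= rho[0, kp]
            elif i == j:
                expected = 1.0
            assert K_cross[a, b] == pytest.approx(expected, rel=1e-12)

    def test_train_kernel_symmetric_unit_diag(self, small_pop, small_split):
        geno, pheno = small_pop
        D = compute_sq_edm(geno)
        Q = build_mt_kernel(
            MTKernelSpec.from_shared_distance(np.full((2, 2), 1.0),
                                              np.eye(2), D)
        )
        d = build_stacked_dataset(pheno, small_split, 0, "CV1")
        K_train, _ = assemble_q_submatrices(Q, d)
        np.testing.assert_allclose(K_train, K_train.T)
        np.testing.assert_allclose(np.diag(K_train), 1.0)


class TestQMTSVRModel:
    def test_single_trait_path_identical_to_plain_svr(self, small_pop, small_split):
        geno, pheno = small_pop
        res = QMTSVR(pheno, geno, small_split, 0, "ST").fit(
            C=1.5, eps=0.05, theta=2.0
        )
        # manual pipeline with the bare solver
        from qmtsvr.kernels import rbf_from_sq_edm

        D = compute_sq_edm(geno)
        K = rbf_from_sq_edm(D, 2.0).values
        tr, te = small_split.train_idx, small_split.test_idx
        y = pheno.trait_values[tr, 0]
        y_star = (y - y.mean()) / y.std()
        m = fit_epsilon_svr(SVRProblem(K[np.ix_(tr, tr)], y_star, 1.5, 0.05))
        np.testing.assert_array_equal(res.svr.beta_dual, m.beta_dual)
        pred = (K[np.ix_(te, tr)] @ m.beta_dual + m.b0) * y.std() + y.mean()
        np.testing.assert_allclose(res.predicted_values, pred)

    def test_uniform_weights_match_unweighted(self, small_pop, small_split):
        geno, pheno = small_pop
        theta = [1.0, 1.5, 2.0]
        rho = [0.2]
        plain = QMTSVR(pheno, geno, small_split, 0, "CV2").fit(
            C=1.0, eps=0.02, theta=theta, rho=rho
        )
        uniform = {
            pair: np.ones(geno.n_snps) for pair in [(0, 0), (0, 1), (1, 1)]
        }
        weighted = QMTSVR(
            pheno, geno, small_split, 0, "CV2", weighted=True
        ).fit(C=1.0, eps=0.02, theta=theta, rho=rho, weights=uniform)
        np.testing.assert_allclose(
            weighted.predicted_values, plain.predicted_values, atol=1e-8
        )

    def test_cv1_predictions_ignore_test_phenotypes(self, small_pop, small_split):
        """No leakage: perturbing test records leaves CV1 output unchanged."""
        geno, pheno = small_pop
        res1 = QMTSVR(pheno, geno, small_split, 0, "CV1").fit(
            C=1.0, eps=0.02, theta=[1.0, 1.0, 1.0], rho=[0.2]
        )
        pheno2 = pheno.subset(np.arange(pheno.n_individuals))
        pheno2.trait_values[small_split.test_idx] += 100.0
        res2 = QMTSVR(pheno2, geno, small_split, 0, "CV1").fit(
            C=1.0, eps=0.02, theta=[1.0, 1.0, 1.0], rho=[0.2]
        )
        np.testing.assert_array_equal(res1.predicted_values, res2.predicted_values)

    def test_cv2_predictions_use_test_secondary(self, small_pop, small_split):
        geno, pheno = small_pop
        kw = dict(C=1.0, eps=0.02, theta=[1.0, 1.0, 1.0], rho=[0.25])
        res1 = QMTSVR(pheno, geno, small_split, 0, "CV2").fit(**kw)
        pheno2 = pheno.subset(np.arange(pheno.n_individuals))
        rng = np.random.default_rng(0)
        pheno2.trait_values[small_split.test_idx, 1] = rng.permutation(
            pheno2.trait_values[small_split.test_idx, 1]
        )
        res2 = QMTSVR(pheno2, geno, small_split, 0, "CV2").fit(**kw)
        assert not np.allclose(res1.predicted_values, res2.predicted_values)

    def test_prediction_order_invariance(self, small_pop):
        geno, pheno = small_pop
        split = forward_split(pheno, [0, 1, 2, 3], [4])
        res = QMTSVR(pheno, geno, split, 0, "CV2").fit(
            C=1.0, eps=0.02, theta=[1.0, 1.0, 1.0], rho=[0.2]
        )
        perm = np.random.default_rng(1).permutation(len(split.test_idx))
        split2 = forward_split(pheno, [0, 1, 2, 3], [4])
        split2.test_idx = split2.test_idx[perm]
        res2 = QMTSVR(pheno, geno, split2, 0, "CV2").fit(
            C=1.0, eps=0.02, theta=[1.0, 1.0, 1.0], rho=[0.2]
        )
        np.testing.assert_allclose(res2.predicted_values,
                                   res.predicted_values[perm], atol=1e-10)

    def test_constant_target_rejected(self, small_pop, small_split):
        geno, pheno = small_pop
        pheno2 = pheno.subset(np.arange(pheno.n_individuals))
        pheno2.trait_values[:, 0] = 1.0
        with pytest.raises(ValueError, match="constant"):
            QMTSVR(pheno2, geno, small_split, 0, "ST").fit()

    def test_linear_kernel_svr(self, small_pop, small_split):
        geno, pheno = small_pop
        res = QMTSVR(pheno, geno, small_split, 0, "ST",
                     kernel_kind="grm").fit(C=1.0, eps=0.05)
        assert res.predictions["model"].iloc[0] == "SVR_Lin"
        assert np.isfinite(res.predicted_values).all()

    def test_summary_mentions_design_and_svs(self, small_pop, small_split):
        geno, pheno = small_pop
        res = QMTSVR(pheno, geno, small_split, 0, "CV2").fit(
            C=1.0, eps=0.02, theta=[1.0, 1.0, 1.0], rho=[0.2]
        )
        s = res.summary()
        assert "CV2" in s and "support vectors" in s
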
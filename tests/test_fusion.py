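"""Multiblock fusion: kernels, RV weights, kernel-OPLS, CV, permutations."""

import numpy as np
import pandas as pd
import pytest

from glycofuse import fusion
from glycofuse._exceptions import DataError
from reference import opls_nipals


def _df(arr, groups=None, cols=None):
    arr = np.asarray(arr, dtype=float)
    groups = groups or [f"g{i+1}" for i in range(arr.shape[0])]
    cols = cols or [f"M{j+1}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=groups, columns=cols)


class TestBuildKernels:
    def test_kernel_is_normalized_psd_and_symmetric(self):
        rng = np.random.default_rng(0)
        K = fusion.build_kernels({"b": _df(rng.standard_normal((6, 4)))})["b"]
        assert np.linalg.norm(K, "fro") == pytest.approx(1.0)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_matches_direct_product(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 4))
        K = fusion.build_kernels({"b": _df(X)})["b"]
        Xc = X - X.mean(axis=0)
        expected = Xc @ Xc.T
        expected /= np.linalg.norm(expected, "fro")
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_duplicating_columns_leaves_normalized_kernel_unchanged(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((6, 4))
        K1 = fusion.build_kernels({"b": _df(X)})["b"]
        K2 = fusion.build_kernels({"b": _df(np.hstack([X, X]), cols=None)})["b"]
        np.testing.assert_allclose(K1, K2, atol=1e-12)

    def test_all_zero_block_is_rejected(self):
        with pytest.raises(DataError):
            fusion.build_kernels({"b": _df(np.zeros((5, 3)))})


class TestRvModified:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((5, 3))
        K = X @ X.T
        assert fusion.rv_modified(K, K) == pytest.approx(1.0)

    def test_positive_scaling_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((5, 3))
        K = X @ X.T
        assert fusion.rv_modified(K, 7.3 * K) == pytest.approx(1.0)

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((5, 5))
        B = rng.standard_normal((5, 5))
        K1, K2 = A @ A.T, B @ B.T
        t1 = K1 - np.diag(np.diag(K1))
        t2 = K2 - np.diag(np.diag(K2))
        expected = np.trace(t1 @ t2) / np.sqrt(np.trace(t1 @ t1) * np.trace(t2 @ t2))
        assert fusion.rv_modified(K1, K2) == pytest.approx(expected, abs=1e-12)

    def test_zero_off_diagonal_is_rejected(self):
        with pytest.raises(DataError):
            fusion.rv_modified(np.eye(4), np.eye(4))


class TestConsensusWeights:
    def test_outcome_derived_block_dominates_noise(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(18)
            signal = _df(np.column_stack([y, y + 0.01 * rng.standard_normal(18)]))
            noise = _df(rng.standard_normal((18, 5)))
            kernels = fusion.build_kernels({"signal": signal, "noise": noise})
            w = fusion.consensus_weights(kernels, y)
            assert w["signal"] > 0.6
            assert w.idxmax() == "signal"

    def test_identical_blocks_split_the_weight_evenly(self):
        rng = np.random.default_rng(6)
        X = _df(rng.standard_normal((10, 3)))
        y = X.iloc[:, 0].to_numpy() + 0.1 * rng.standard_normal(10)
        kernels = fusion.build_kernels({"a": X, "b": X.copy()})
        w = fusion.consensus_weights(kernels, y)
        assert w["a"] == pytest.approx(0.5)
        assert w["b"] == pytest.approx(0.5)

    def test_single_block_takes_all_weight(self):
        rng = np.random.default_rng(7)
        X = _df(rng.standard_normal((8, 3)))
        kernels = fusion.build_kernels({"only": X})
        y = X.iloc[:, 1].to_numpy() + 0.1 * rng.standard_normal(8)
        assert fusion.consensus_weights(kernels, y)["only"] == pytest.approx(1.0)

    def test_weights_invariant_to_block_scaling(self):
        rng = np.random.default_rng(8)
        X1 = _df(rng.standard_normal((12, 3)))
        X2 = _df(rng.standard_normal((12, 4)))
        y = X1.iloc[:, 0].to_numpy() + X2.iloc[:, 0].to_numpy()
        w1 = fusion.consensus_weights(fusion.build_kernels({"a": X1, "b": X2}), y)
        w2 = fusion.consensus_weights(
            fusion.build_kernels({"a": 13.0 * X1, "b": 0.25 * X2}), y
        )
        np.testing.assert_allclose(w1.to_numpy(), w2.to_numpy(), atol=1e-12)

    def test_no_predictive_block_raises_or_falls_back(self):
        # anti-correlated structure: RV with yyT can be forced <= 0 by a
        # single 2-group kernel whose off-diagonal opposes y's outer product
        K = np.array([[1.0, -0.5], [-0.5, 1.0]])
        y = np.array([1.0, -1.0])  # yyT off-diagonal = -1, RV = +... construct opposite
        K_pos = np.array([[1.0, 0.5], [0.5, 1.0]])
        with pytest.raises(DataError):
            fusion.consensus_weights({"b": K_pos}, y)
        w = fusion.consensus_weights({"b": K_pos}, y, on_degenerate="uniform")
        assert w["b"] == pytest.approx(1.0)
        # sanity: the negated kernel is predictive, no error
        assert fusion.consensus_weights({"b": K}, y)["b"] == pytest.approx(1.0)


class TestKoplsFit:
    def test_rank_one_predictor_fits_its_own_score_exactly(self):
        rng = np.random.default_rng(9)
        t = rng.standard_normal(12)
        p = rng.standard_normal(6)
        X = np.outer(t, p)
        y = 2.0 * (t - t.mean()) + 0.3
        res = fusion.kopls_fit(X @ X.T, y, n_ortho=0)
        assert res["r2y"] == pytest.approx(1.0, abs=1e-8)

    def test_matches_direct_nipals_opls(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((18, 10))
        y = rng.standard_normal(18)
        for n_ortho in range(4):
            res = fusion.kopls_fit(X @ X.T, y, n_ortho=n_ortho)
            oracle = opls_nipals(X, y, n_ortho)
            np.testing.assert_allclose(res["fitted"], oracle, atol=1e-8)

    def test_predictive_score_is_equivariant_under_group_permutation(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((10, 4))
        y = rng.standard_normal(10)
        K = X @ X.T
        perm = rng.permutation(10)
        res = fusion.kopls_fit(K, y, n_ortho=1)
        res_p = fusion.kopls_fit(K[np.ix_(perm, perm)], y[perm], n_ortho=1)
        np.testing.assert_allclose(res_p["t_p"], res["t_p"][perm], atol=1e-10)

    def test_predictive_score_orthogonal_to_orthogonal_scores(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((15, 8))
        y = rng.standard_normal(15)
        res = fusion.kopls_fit(X @ X.T, y, n_ortho=3)
        if res["T_o"].shape[1]:
            overlap = np.abs(res["T_o"].T @ res["t_p"]).max()
            assert overlap / np.linalg.norm(res["t_p"]) < 1e-8

    def test_non_psd_kernel_is_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(DataError):
            fusion.kopls_fit(K, np.array([1.0, -1.0]))

    def test_asymmetric_kernel_is_rejected(self):
        K = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(DataError):
            fusion.kopls_fit(K, np.array([1.0, -1.0]))


class TestCrossValidation:
    def test_noise_free_outcome_block_predicts_almost_perfectly(self):
        rng = np.random.default_rng(13)
        y = pd.Series(rng.standard_normal(18), index=[f"g{i}" for i in range(18)])
        blocks = {"b": _df(np.column_stack([y, rng.standard_normal(18)]), groups=list(y.index))}
        q2 = fusion.cross_validate_q2(blocks, y, folds=14, n_ortho=0, seed=0)
        assert q2 >= 0.95

    def test_null_outcome_rarely_reaches_high_q2(self):
        high = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = pd.Series(rng.standard_normal(18), index=[f"g{i}" for i in range(18)])
            blocks = {"b": _df(rng.standard_normal((18, 5)), groups=list(y.index))}
            q2 = fusion.cross_validate_q2(blocks, y, folds=14, n_ortho=0, seed=seed)
            high += q2 > 0.2
        assert high <= 2  # <= 5% of 50 seeds

    def test_leave_one_out_returns_finite_q2(self):
        rng = np.random.default_rng(14)
        y = pd.Series(rng.standard_normal(12), index=[f"g{i}" for i in range(12)])
        blocks = {"b": _df(rng.standard_normal((12, 3)), groups=list(y.index))}
        q2 = fusion.cross_validate_q2(blocks, y, folds=12, n_ortho=1, seed=1)
        assert np.isfinite(q2)

    def test_too_many_folds_are_rejected(self):
        rng = np.random.default_rng(15)
        y = pd.Series(rng.standard_normal(8), index=[f"g{i}" for i in range(8)])
        blocks = {"b": _df(rng.standard_normal((8, 3)), groups=list(y.index))}
        with pytest.raises(DataError):
            fusion.cross_validate_q2(blocks, y, folds=9, n_ortho=0)


class TestConsensusOPLS:
    def _signal_model(self, seed=0, folds=14):
        rng = np.random.default_rng(seed)
        groups = [f"g{i:02d}" for i in range(18)]
        y = pd.Series(rng.standard_normal(18), index=groups)
        signal = np.column_stack(
            [y + 0.15 * rng.standard_normal(18) for _ in range(3)]
        )
        blocks = {
            "signal": _df(signal, groups=groups),
            "noise": _df(rng.standard_normal((18, 4)), groups=groups),
        }
        return fusion.ConsensusOPLS(blocks, y, folds=folds), y

    def test_weights_sum_to_one_and_fit_is_strong(self):
        model, _ = self._signal_model()
        res = model.fit(seed=0)
        assert res.weights.sum() == pytest.approx(1.0)
        assert res.q2 > 0.8
        assert res.r2y >= res.q2

    def test_vip_table_covers_every_block_module(self, random_blocks):
        blocks, y = random_blocks
        res = fusion.ConsensusOPLS(blocks, y, folds=6).fit(seed=0)
        counts = res.vip_table.groupby("block")["module"].count()
        assert counts["alpha"] == 4 and counts["beta"] == 7

    def test_vip_squares_sum_to_module_count_per_block(self, random_blocks):
        blocks, y = random_blocks
        res = fusion.ConsensusOPLS(blocks, y, folds=6).fit(seed=0)
        ssq = res.vip_table.groupby("block")["vip"].apply(lambda v: np.sum(v**2))
        assert ssq["alpha"] == pytest.approx(4.0, abs=1e-8)
        assert ssq["beta"] == pytest.approx(7.0, abs=1e-8)

    def test_single_module_block_has_vip_one_signed_by_loading(self):
        rng = np.random.default_rng(16)
        groups = [f"g{i}" for i in range(10)]
        y = pd.Series(rng.standard_normal(10), index=groups)
        blocks = {
            "one": _df((-y.to_numpy()).reshape(-1, 1), groups=groups, cols=["M1"]),
            "pad": _df(rng.standard_normal((10, 2)), groups=groups),
        }
        res = fusion.ConsensusOPLS(blocks, y, n_ortho=0, folds=5).fit(seed=0)
        row = res.vip_table.set_index(["block", "module"]).loc[("one", "M1")]
        assert row["vip"] == pytest.approx(1.0)
        assert row["svip"] == pytest.approx(-1.0)

    def test_equal_magnitude_loadings_share_vip_one(self):
        rng = np.random.default_rng(17)
        groups = [f"g{i}" for i in range(12)]
        y = pd.Series(rng.standard_normal(12), index=groups)
        X = np.column_stack([y, -y])
        blocks = {"b": _df(X, groups=groups)}
        res = fusion.ConsensusOPLS(blocks, y, n_ortho=0, folds=6).fit(seed=0)
        np.testing.assert_allclose(res.vip_table["vip"].to_numpy(), 1.0, atol=1e-8)

    def test_mismatched_group_order_is_rejected(self, random_blocks):
        blocks, y = random_blocks
        bad = dict(blocks)
        bad["beta"] = bad["beta"].iloc[::-1]
        with pytest.raises(DataError):
            fusion.ConsensusOPLS(bad, y)

    def test_auto_selection_prefers_fewer_components_on_ties(self, random_blocks):
        blocks, y = random_blocks
        res = fusion.ConsensusOPLS(blocks, y, n_ortho="auto", folds=6).fit(seed=0)
        assert 0 <= res.n_ortho_ <= 3

    def test_summary_reports_the_headline_numbers(self):
        model, _ = self._signal_model()
        res = model.fit(seed=0)
        res.permutation_test(n_perm=9, seed=1)
        text = res.summary()
        assert "Q2" in text and "permutation" in text and "signal" in text


class TestPermutationTest:
    def test_single_permutation_p_is_half_or_one(self, random_blocks):
        blocks, y = random_blocks
        res = fusion.ConsensusOPLS(blocks, y, folds=6).fit(seed=0)
        perm = res.permutation_test(n_perm=1, seed=0)
        assert perm.p_q2 in (0.5, 1.0)

    def test_p_value_never_below_its_floor(self, random_blocks):
        blocks, y = random_blocks
        res = fusion.ConsensusOPLS(blocks, y, folds=6).fit(seed=0)
        perm = res.permutation_test(n_perm=19, seed=0)
        assert perm.p_q2 >= 1.0 / 20.0

    def test_same_seed_reproduces_the_archive_bitwise(self, random_blocks):
        blocks, y = random_blocks
        res = fusion.ConsensusOPLS(blocks, y, folds=6).fit(seed=0)
        a = res.permutation_test(n_perm=11, seed=3)
        b = res.permutation_test(n_perm=11, seed=3)
        np.testing.assert_array_equal(a.q2_perm, b.q2_perm)
        pd.testing.assert_frame_equal(a.svip_perm, b.svip_perm)

    def test_planted_signal_reaches_the_p_floor(self):
        rng = np.random.default_rng(18)
        groups = [f"g{i:02d}" for i in range(18)]
        y = pd.Series(rng.standard_normal(18), index=groups)
        signal = np.column_stack([y + 0.1 * rng.standard_normal(18) for _ in range(3)])
        blocks = {"signal": _df(signal, groups=groups)}
        res = fusion.ConsensusOPLS(blocks, y, folds=14).fit(seed=0)
        perm = res.permutation_test(n_perm=99, seed=1)
        assert perm.p_q2 == pytest.approx(0.01)

    def test_permuted_svip_archive_respects_vip_normalization(self, random_blocks):
        blocks, y = random_blocks
        res = fusion.ConsensusOPLS(blocks, y, folds=6).fit(seed=0)
        perm = res.permutation_test(n_perm=7, seed=2)
        for block, n_modules in (("alpha", 4), ("beta", 7)):
            ssq = (perm.svip_perm[block] ** 2).sum(axis=1)
            np.testing.assert_allclose(ssq.to_numpy(), n_modules, atol=1e-8)


class TestCcswa:
    def test_single_kernel_recovers_its_leading_eigenvector(self):
        rng = np.random.default_rng(19)
        X = _df(rng.standard_normal((10, 4)))
        res = fusion.CCSWA({"b": X}).fit(n_dims=1)
        K = fusion.build_kernels({"b": X})["b"]
        vals, vecs = np.linalg.eigh(K)
        lead = vecs[:, -1]
        score = res.scores["dim1"].to_numpy()
        assert abs(abs(lead @ score)) == pytest.approx(1.0, abs=1e-8)

    def test_identical_kernels_share_the_salience(self):
        rng = np.random.default_rng(20)
        X = _df(rng.standard_normal((10, 4)))
        res = fusion.CCSWA({"a": X, "b": X.copy()}).fit(n_dims=1)
        s = res.saliences["dim1"]
        assert s["a"] == pytest.approx(s["b"], rel=1e-8)

    def test_orthogonal_dominant_structures_separate_by_salience(self):
        rng = np.random.default_rng(21)
        # structures chosen orthogonal *after* centering, so the blocks share
        # no common direction
        u = np.tile([1.0, -1.0], 6)
        v = np.repeat([1.0, -1.0], 6)
        A = _df(np.outer(u, [3.0, -2.0, 1.0]) + 0.01 * rng.standard_normal((12, 3)))
        B = _df(np.outer(v, [1.0, 1.0]) + 0.01 * rng.standard_normal((12, 2)))
        res = fusion.CCSWA({"a": A, "b": B}).fit(n_dims=1)
        s = res.saliences["dim1"]
        assert s.max() / s.sum() > 0.9

    def test_common_scores_are_orthonormal(self):
        rng = np.random.default_rng(22)
        blocks = {
            "a": _df(rng.standard_normal((10, 4))),
            "b": _df(rng.standard_normal((10, 3))),
        }
        res = fusion.CCSWA(blocks).fit(n_dims=3)
        S = res.scores.to_numpy()
        np.testing.assert_allclose(S.T @ S, np.eye(3), atol=1e-8)

    def test_saliences_are_non_negative(self):
        rng = np.random.default_rng(23)
        blocks = {
            "a": _df(rng.standard_normal((10, 4))),
            "b": _df(rng.standard_normal((10, 3))),
        }
        res = fusion.CCSWA(blocks).fit(n_dims=2)
        assert (res.saliences.to_numpy() >= -1e-12).all()
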
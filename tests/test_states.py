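"""Label transfer, signature scoring, decomposition, DEG filter, chi-square."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData
from hypothesis import given, settings
from hypothesis import strategies as hst

from pctrace import simulate as sim
from pctrace import states as st


def _adata(X, barcodes=None, genes=None):
    X = np.asarray(X)
    return AnnData(
        X=sp.csr_matrix(X.astype(np.int64)),
        obs=pd.DataFrame(index=barcodes or [f"BC{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=genes or [f"G{i}" for i in range(X.shape[1])]),
    )


class TestCentroids:
    def test_identical_cells_give_member_vector(self):
        row = np.array([4, 0, 2, 8])
        adata = _adata(np.vstack([row, row, row]))
        labels = pd.Series(["s1"] * 3, index=adata.obs_names)
        ref = st.build_centroids(adata, labels, list(adata.var_names))
        from pctrace.io import log_normalize

        expected = log_normalize(adata)[0]
        np.testing.assert_allclose(ref.centroids.loc["s1"].to_numpy(), expected)

    def test_invariant_to_uniform_library_scaling(self):
        # exact invariance requires a fixed normalization target
        rng = np.random.default_rng(3)
        X = rng.poisson(5.0, size=(10, 6))
        labels = pd.Series(["a"] * 5 + ["b"] * 5)
        a1 = _adata(X)
        a2 = _adata(2 * X)
        labels.index = a1.obs_names
        r1 = st.build_centroids(a1, labels, list(a1.var_names), norm_target=1e4)
        r2 = st.build_centroids(a2, labels, list(a2.var_names), norm_target=1e4)
        np.testing.assert_allclose(r1.centroids.to_numpy(), r2.centroids.to_numpy())

    def test_state_with_one_cell_rejected(self):
        adata = _adata(np.ones((3, 4)))
        labels = pd.Series(["a", "a", "b"], index=adata.obs_names)
        with pytest.raises(ValueError, match="'b'"):
            st.build_centroids(adata, labels, list(adata.var_names))

    def test_centroids_elevated_at_planted_markers(self, expression_sim):
        _, truth, adata, marker_map = expression_sim
        labels = truth.set_index("barcode")["state"]
        markers = [g for gs in marker_map.values() for g in gs]
        ref = st.build_centroids(adata, labels, markers)
        for state, genes in marker_map.items():
            own = ref.centroids.loc[state, genes].mean()
            other_states = [s for s in marker_map if s != state]
            others = ref.centroids.loc[other_states, genes].to_numpy().mean()
            assert own > others


class TestClassify:
    def test_centroid_cell_maps_to_its_state_with_r_one(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(10.0, size=(6, 8))
        adata = _adata(X)
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=adata.obs_names)
        ref = st.build_centroids(adata, labels, list(adata.var_names), norm_target=1e4)
        # craft a query whose log profile equals the centroid exactly
        centroid_counts = 2 ** ref.centroids.loc["a"].to_numpy() - 1.0
        q = centroid_counts / centroid_counts.sum() * 1e4
        query = AnnData(X=sp.csr_matrix(np.round(q[None, :] * 1000).astype(np.int64)))
        query.var_names = adata.var_names
        res = st.classify_cells(query, ref)
        assert res.iloc[0]["label"] == "a"
        assert res.iloc[0]["best_r"] > 0.999

    def test_noise_cells_are_unassigned(self, expression_sim):
        _, truth, adata, marker_map = expression_sim
        labels = truth.set_index("barcode")["state"]
        markers = [g for gs in marker_map.values() for g in gs]
        ref = st.build_centroids(adata, labels, markers)
        rng = np.random.default_rng(1)
        noise = _adata(rng.poisson(1.0, size=(50, adata.n_vars)), genes=list(adata.var_names))
        res = st.classify_cells(noise, ref)
        assert (res["label"] == "unassigned").mean() == 1.0

    def test_zero_variance_cell_unassigned(self):
        rng = np.random.default_rng(2)
        adata = _adata(rng.poisson(8.0, size=(4, 5)))
        labels = pd.Series(["a", "a", "b", "b"], index=adata.obs_names)
        ref = st.build_centroids(adata, labels, list(adata.var_names))
        flat = _adata(np.full((1, 5), 7), genes=list(adata.var_names))
        res = st.classify_cells(flat, ref)
        assert res.iloc[0]["label"] == "unassigned"
        assert np.isnan(res.iloc[0]["best_r"])


class TestSignatureScore:
    def test_random_signature_scores_near_zero(self, expression_sim):
        _, _, adata, _ = expression_sim
        rng = np.random.default_rng(4)
        genes = list(rng.choice(adata.var_names, size=30, replace=False))
        score = st.signature_score(adata, st.SignatureSpec("null", genes, seed=5))
        assert abs(score.mean()) < 0.05

    def test_boosting_signature_counts_increases_score(self):
        rng = np.random.default_rng(6)
        X = rng.poisson(5.0, size=(20, 200)) + 1
        adata = _adata(X)
        genes = list(adata.var_names[:10])
        spec = st.SignatureSpec("sig", genes, n_background_bins=5, seed=0)
        base_score = st.signature_score(adata, spec)
        X2 = X.copy()
        X2[0, :10] *= 10
        boosted = st.signature_score(_adata(X2), spec)
        assert boosted.iloc[0] > base_score.iloc[0]

    def test_pc_state_cells_score_higher_on_pc_signature(self, expression_sim):
        from scipy import stats

        _, truth, adata, marker_map = expression_sim
        score = st.signature_score(
            adata, st.SignatureSpec("PC", marker_map["PC-Tigit"], seed=1)
        )
        states = truth.set_index("barcode")["state"]
        pc = score[states == "PC-Tigit"]
        bcell = score[states == "B cells-C1"]
        res = stats.mannwhitneyu(pc, bcell, alternative="greater")
        assert res.pvalue < 0.01

    def test_deterministic_for_fixed_seed(self, expression_sim):
        _, _, adata, marker_map = expression_sim
        spec = st.SignatureSpec("PC", marker_map["PC-Slpi"], seed=3)
        s1 = st.signature_score(adata, spec)
        s2 = st.signature_score(adata, spec)
        pd.testing.assert_series_equal(s1, s2)


class TestDecomposition:
    def test_alpha_zero_is_identity(self):
        fm = pd.Series({"a": 0.6, "b": 0.4})
        fp = pd.Series({"a": 1.0, "b": 0.0})
        out = st.subset_frequency_decomposition(fm, fp, alpha=0.0)
        pd.testing.assert_series_equal(out, fm)

    def test_forced_arithmetic(self):
        fm = pd.Series({"a": 0.6, "b": 0.4})
        fp = pd.Series({"a": 1.0, "b": 0.0})
        out = st.subset_frequency_decomposition(fm, fp, alpha=0.5)
        np.testing.assert_allclose(out.to_numpy(), [0.2, 0.8])

    def test_degenerate_decomposition_rejected(self):
        fm = pd.Series({"a": 1.0, "b": 0.0})
        with pytest.raises(ValueError, match="degenerate"):
            st.subset_frequency_decomposition(fm, fm, alpha=1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    def test_exact_recovery_on_exact_mixtures(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 8))
        f_target = rng.dirichlet(np.ones(k))
        f_pure = rng.dirichlet(np.ones(k))
        a = float(rng.uniform(0.0, 0.95))
        f_mixed = (1 - a) * f_target + a * f_pure
        out = st.subset_frequency_decomposition(pd.Series(f_mixed), pd.Series(f_pure), alpha=a)
        assert np.abs(out.to_numpy() - f_target).max() < 1e-12


class TestDifferentialExpression:
    def test_duplicated_groups_yield_zero_degs(self):
        A, _, _ = sim.simulate_deg_groups(seed=8, n_planted=0, n_cells_per_group=50, n_genes=500)
        table = st.differential_expression(A, A.copy())
        assert table["is_deg"].sum() == 0

    def test_fold_below_threshold_never_deg(self):
        # strongly significant but only 1.1-fold: the fold filter must veto it
        rng = np.random.default_rng(9)
        n = 200
        base = np.full(300, 50.0)
        Xa = rng.poisson(base, size=(n, 300))
        Xb = rng.poisson(base, size=(n, 300))
        Xa[:, 0] = rng.poisson(55.0, size=n)  # 1.1-fold
        table = st.differential_expression(_adata(Xa), _adata(Xb))
        row = table.iloc[0]
        assert row["abs_fold"] < 1.2
        assert not row["is_deg"]

    def test_unshrunk_t_matches_scipy_pooled_t(self):
        from scipy import stats as sps

        A, B, _ = sim.simulate_deg_groups(seed=10, n_planted=0, n_cells_per_group=30, n_genes=200)
        table = st.differential_expression(A, B, shrink=False)
        import scipy.sparse as ssp
        from pctrace.io import log_normalize

        # replicate the internal normalization, then compare to scipy
        Xa = np.asarray(A.X.todense(), dtype=float)
        Xb = np.asarray(B.X.todense(), dtype=float)
        lib = np.concatenate([Xa.sum(axis=1), Xb.sum(axis=1)])
        target = float(np.median(lib))
        La = np.log2(1 + Xa / Xa.sum(axis=1, keepdims=True) * target)
        Lb = np.log2(1 + Xb / Xb.sum(axis=1, keepdims=True) * target)
        t_ref, p_ref = sps.ttest_ind(La, Lb, axis=0, equal_var=True)
        np.testing.assert_allclose(table["t"].to_numpy(), t_ref, rtol=1e-10)
        np.testing.assert_allclose(table["raw_p"].to_numpy(), p_ref, rtol=1e-8)

    def test_tiny_group_rejected(self):
        A, B, _ = sim.simulate_deg_groups(seed=11, n_planted=0, n_cells_per_group=10, n_genes=50)
        with pytest.raises(ValueError, match="at least 3"):
            st.differential_expression(A[:2].copy(), B)

    def test_invalid_config(self):
        with pytest.raises(ValueError, match="fold_threshold"):
            st.DEGConfig(fold_threshold=1.0)


class TestStateFrequencyTest:
    def test_proportional_counts_give_null(self):
        chi2, df, p = st.state_frequency_test({"a": 50, "b": 50}, {"a": 100, "b": 100})
        assert chi2 == pytest.approx(0.0)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_pinned_value_against_brute_force(self):
        counts_a, counts_b = {"a": 90, "b": 10}, {"a": 10, "b": 90}
        chi2, df, _ = st.state_frequency_test(counts_a, counts_b)
        # independent brute force: sum (O-E)^2 / E over the 2x2 table
        O = np.array([[90, 10], [10, 90]], dtype=float)
        E = O.sum(axis=1, keepdims=True) * O.sum(axis=0, keepdims=True) / O.sum()
        assert chi2 == pytest.approx(((O - E) ** 2 / E).sum())
        assert chi2 == pytest.approx(128.0)
        assert df == 1

    def test_symmetry_under_group_swap(self):
        a, b = {"a": 30, "b": 12, "c": 5}, {"a": 8, "b": 22, "c": 9}
        assert st.state_frequency_test(a, b)[0] == pytest.approx(st.state_frequency_test(b, a)[0])

    def test_zero_count_state_dropped_with_reduced_df(self):
        chi2, df, _ = st.state_frequency_test({"a": 10, "b": 10, "c": 0}, {"a": 12, "b": 9, "c": 0})
        assert df == 1
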
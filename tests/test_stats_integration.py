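"""PCA, Hotelling T^2, Pearson correlation, rCCA, and clustering."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla
from scipy import stats

from glycotraits.stats_integration import (
    cluster_order,
    correlate_traits_genes,
    fit_pca,
    fit_rcca,
    hotelling_t2,
    hotelling_t2_limit,
)


def _random_df(rng, n, p, prefix="f"):
    return pd.DataFrame(rng.normal(size=(n, p)), columns=[f"{prefix}{i}" for i in range(p)])


class TestPca:
    def test_duplicated_samples_share_scores(self):
        rng = np.random.default_rng(0)
        X = _random_df(rng, 6, 4)
        X.iloc[5] = X.iloc[0]
        m = fit_pca(X, n_components=2)
        assert np.allclose(m.scores.iloc[0], m.scores.iloc[5])

    def test_rank_one_data_has_single_component(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=8)
        v = rng.normal(size=5)
        X = pd.DataFrame(np.outer(u, v))
        m = fit_pca(X, n_components=2, scaling="none")
        assert m.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)
        assert m.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-10)

    def test_loadings_orthonormal_and_reconstruction(self):
        rng = np.random.default_rng(2)
        X = _random_df(rng, 12, 7)
        k = min(11, 7)
        m = fit_pca(X, n_components=k)
        gram = m.loadings.to_numpy().T @ m.loadings.to_numpy()
        assert np.allclose(gram, np.eye(k), atol=1e-8)
        scaled = (X - m.mean) / m.scale
        recon = m.scores.to_numpy() @ m.loadings.to_numpy().T
        assert np.allclose(recon, scaled.to_numpy(), atol=1e-8)

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(3)
        m = fit_pca(_random_df(rng, 20, 10), n_components=9)
        assert np.all(np.diff(m.explained_variance) <= 1e-12)

    def test_hotelling_flags_match_direct_t2(self):
        rng = np.random.default_rng(4)
        X = _random_df(rng, 21, 8)
        m = fit_pca(X, n_components=2)
        flags = hotelling_t2(m)
        t2_direct = (m.scores.to_numpy() ** 2 / m.explained_variance).sum(axis=1)
        limit = 2 * 20 * 22 / (21 * 19) * stats.f.ppf(0.95, 2, 19)
        assert m.t2_limit == pytest.approx(limit)
        assert np.allclose(flags["t2"], t2_direct)
        assert (flags["inside"] == (t2_direct <= limit)).all()

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="n_components"):
            fit_pca(_random_df(rng, 5, 10), n_components=5)

    def test_incomplete_input_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="complete"):
            fit_pca(X, n_components=1)


class TestCorrelation:
    def test_perfect_linearity(self):
        x = pd.DataFrame({"t": [1.0, 2.0, 3.0, 4.0]})
        y = pd.DataFrame({"g": [3.0, 5.0, 7.0, 9.0]})  # y = 2x + 1
        out = correlate_traits_genes(x, y)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "tier"] == "***"

    def test_null_rarely_significant(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = pd.DataFrame({"t": rng.normal(size=21)})
            y = pd.DataFrame({"g": rng.normal(size=21)})
            out = correlate_traits_genes(x, y)
            assert abs(out.loc[0, "r"]) <= 1
            hits += out.loc[0, "p"] <= 0.05
        assert hits <= 20  # >=90% of null repeats non-significant

    def test_tiers_and_pvalue_from_t_transform(self):
        rng = np.random.default_rng(6)
        n = 15
        x = pd.Series(rng.normal(size=n))
        y = 0.8 * x + rng.normal(scale=0.5, size=n)
        out = correlate_traits_genes(x.to_frame("t"), y.to_frame("g"))
        r = out.loc[0, "r"]
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p_expected = 2 * stats.t.sf(abs(t), n - 2)
        assert out.loc[0, "p"] == pytest.approx(p_expected, rel=1e-10)

    def test_zero_variance_gives_nan(self):
        x = pd.DataFrame({"t": [1.0, 1.0, 1.0]})
        y = pd.DataFrame({"g": [1.0, 2.0, 3.0]})
        out = correlate_traits_genes(x, y)
        assert np.isnan(out.loc[0, "r"])

    def test_insufficient_overlap_skipped(self):
        x = pd.DataFrame({"t": [1.0, 2.0]}, index=["a", "b"])
        y = pd.DataFrame({"g": [1.0, 2.0]}, index=["a", "c"])
        out = correlate_traits_genes(x, y)
        assert out.empty


def classical_cca_rhos(X, Y):
    """Independent classical-CCA oracle via the generalized eigenproblem."""
    n = len(X)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Cxx = Xc.T @ Xc / (n - 1)
    Cyy = Yc.T @ Yc / (n - 1)
    Cxy = Xc.T @ Yc / (n - 1)
    M = sla.solve(Cxx, Cxy) @ sla.solve(Cyy, Cxy.T)
    vals = np.sort(np.real(sla.eigvals(M)))[::-1]
    return np.sqrt(np.clip(vals, 0, 1))


class TestRcca:
    def test_identical_blocks_give_unit_correlations(self):
        rng = np.random.default_rng(7)
        X = _random_df(rng, 30, 4)
        m = fit_rcca(X, X.copy(), 0.0, 0.0, n_components=3)
        assert np.allclose(m.canonical_correlations, 1.0, atol=1e-8)

    def test_lambda_zero_matches_classical_cca(self):
        rng = np.random.default_rng(8)
        X = _random_df(rng, 40, 4, "x")
        Y = pd.DataFrame(
            X.to_numpy()[:, :3] @ rng.normal(size=(3, 3)) + rng.normal(size=(40, 3)),
            columns=list("abc"))
        m = fit_rcca(X, Y, 0.0, 0.0, n_components=3)
        oracle = classical_cca_rhos(X.to_numpy(), Y.to_numpy())[:3]
        assert np.allclose(m.canonical_correlations, oracle, atol=1e-6)

    def test_affine_rescaling_invariance_at_lambda_zero(self):
        rng = np.random.default_rng(9)
        X = _random_df(rng, 35, 3, "x")
        Y = _random_df(rng, 35, 3, "y")
        m1 = fit_rcca(X, Y, 0.0, 0.0, 2)
        X2 = X * np.array([10.0, 0.2, 3.0]) + np.array([5.0, -1.0, 0.0])
        m2 = fit_rcca(X2, Y, 0.0, 0.0, 2)
        assert np.allclose(m1.canonical_correlations, m2.canonical_correlations, atol=1e-8)

    def test_correlations_non_increasing_and_shrinking_with_lambda(self):
        rng = np.random.default_rng(10)
        X = _random_df(rng, 25, 6, "x")
        Y = _random_df(rng, 25, 5, "y")
        prev_rho1 = None
        for lam in (0.0, 0.05, 0.5, 5.0):
            m = fit_rcca(X, Y, lam, lam, 3)
            assert np.all(np.diff(m.canonical_correlations) <= 1e-10)
            if prev_rho1 is not None:
                assert m.canonical_correlations[0] <= prev_rho1 + 1e-10
            prev_rho1 = m.canonical_correlations[0]

    def test_variates_unit_variance_under_regularized_metric(self):
        rng = np.random.default_rng(11)
        X = _random_df(rng, 30, 4, "x")
        Y = _random_df(rng, 30, 4, "y")
        lam = 0.3
        m = fit_rcca(X, Y, lam, lam, 2)
        n = len(X)
        Xc = (X - X.mean()).to_numpy()
        Cxx = Xc.T @ Xc / (n - 1) + lam * np.eye(4)
        A = m.x_weights.to_numpy()
        assert np.allclose(A.T @ Cxx @ A, np.eye(2), atol=1e-8)

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(12)
        X = _random_df(rng, 10, 3)
        with pytest.raises(ValueError):
            fit_rcca(X, X, -0.1, 0.0, 1)
        with pytest.raises(ValueError):
            fit_rcca(X, X, 0.1, 0.1, 9)
        bad = X.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_rcca(bad, X, 0.1, 0.1, 1)


class TestClusterOrder:
    def test_identical_rows_adjacent(self):
        m = pd.DataFrame(
            [[1.0, 0.0], [0.0, 5.0], [1.0, 0.0]], index=["a", "b", "c"])
        row_order, _, _, _ = cluster_order(m)
        ia, ic = row_order.index("a"), row_order.index("c")
        assert abs(ia - ic) == 1

    def test_block_sign_structure_contiguous(self):
        rng = np.random.default_rng(13)
        pos = rng.uniform(0.5, 1.0, size=(4, 6))
        neg = -rng.uniform(0.5, 1.0, size=(4, 6))
        m = pd.DataFrame(np.vstack([pos, neg]),
                         index=[f"p{i}" for i in range(4)] + [f"n{i}" for i in range(4)])
        row_order, _, _, _ = cluster_order(m)
        first_half = set(row_order[:4])
        assert first_half == {f"p{i}" for i in range(4)} or first_half == {f"n{i}" for i in range(4)}

    def test_permutation_invariance(self):
        rng = np.random.default_rng(14)
        m = pd.DataFrame(rng.normal(size=(6, 4)), index=list("abcdef"))
        shuffled = m.loc[list("dafcbe")]
        o1 = cluster_order(m)
        o2 = cluster_order(shuffled)
        assert o1[0] == o2[0] and o1[1] == o2[1]

    def test_single_row_identity(self):
        m = pd.DataFrame([[1.0, 2.0]], index=["only"])
        row_order, col_order, row_link, _ = cluster_order(m)
        assert row_order == ["only"] and row_link is None


def test_null_pvalues_uniform_ks():
    """Our reported p-values under independence are Uniform(0,1)."""
    rng = np.random.default_rng(99)
    ps = []
    for _ in range(1000):
        x = pd.DataFrame({"t": rng.normal(size=20)})
        y = pd.DataFrame({"g": rng.normal(size=20)})
        ps.append(correlate_traits_genes(x, y, bh_column=False).loc[0, "p"])
    stat, p = stats.kstest(ps, "uniform")
    assert p > 0.01
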
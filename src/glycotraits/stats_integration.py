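"""Multivariate statistics: PCA, trait-gene correlation, regularized CCA.

PCA is computed by singular value decomposition after mean-centering and
(by default) unit-variance scaling of each feature, with Hotelling's T^2
95% limit defining the score-plot confidence ellipse. Trait-gene
associations use Pearson correlation with the exact t-transform p-value.
Cross-block integration of glycan traits with transcription-factor
expression uses ridge-regularized canonical correlation analysis (rCCA):
the within-block covariances Cxx, Cyy are shrunk by lambda*I so the
canonical eigenproblem stays well-posed when features rival samples. The
cross-block similarity map projects each original variable onto the
averaged canonical variates, giving the signed association matrix that is
then ordered by hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.linalg as sla
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PCAModel",
    "RCCAModel",
    "fit_pca",
    "hotelling_t2",
    "correlate_traits_genes",
    "fit_rcca",
    "cluster_order",
]


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    """Fitted PCA with the preprocessing needed to reproject new data."""

    mean: pd.Series
    scale: pd.Series
    loadings: pd.DataFrame          # features x components, orthonormal
    scores: pd.DataFrame            # samples x components
    explained_variance: np.ndarray  # per component (score variance, ddof=1)
    explained_variance_ratio: np.ndarray
    scaling: str
    alpha: float
    t2_limit: float                 # Hotelling limit for all fitted components

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _scale_matrix(X: pd.DataFrame, scaling: str) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scaling == "unit_variance":
        scale = sd.mask(sd <= 0, 1.0)
    elif scaling == "pareto":
        scale = np.sqrt(sd).mask(sd <= 0, 1.0)
    elif scaling == "none":
        scale = pd.Series(1.0, index=X.columns)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return (X - mean) / scale, mean, scale


def hotelling_t2_limit(n_samples: int, n_components: int, alpha: float = 0.05) -> float:
    """Hotelling T^2 limit: A(n-1)(n+1)/(n(n-A)) * F(1-alpha; A, n-A)."""
    n, A = n_samples, n_components
    if n <= A:
        raise ValueError("need more samples than components for a T2 limit")
    f_crit = stats.f.ppf(1 - alpha, A, n - A)
    return A * (n - 1) * (n + 1) / (n * (n - A)) * f_crit


def fit_pca(
    matrix: pd.DataFrame,
    n_components: int = 2,
    scaling: str = "unit_variance",
    alpha: float = 0.05,
) -> PCAModel:
    """PCA by SVD on the centered/scaled matrix.

    Sign convention: each loading vector's largest-magnitude element is
    positive, making score plots reproducible across SVD implementations.
    The model carries the Hotelling T^2 limit at ``alpha`` for the fitted
    component count.
    """
    n, p = matrix.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 samples")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("PCA input must be complete (impute missing values first)")
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}")
    Xs, mean, scale = _scale_matrix(matrix.astype(float), scaling)
    U, s, Vt = np.linalg.svd(Xs.to_numpy(), full_matrices=False)
    # deterministic sign: largest-|.| loading element positive
    V = Vt.T
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] *= -1
            U[:, j] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    loadings = pd.DataFrame(V[:, :n_components], index=matrix.columns, columns=comp_names)
    scores = pd.DataFrame((U * s)[:, :n_components], index=matrix.index, columns=comp_names)
    ev_all = s**2 / (n - 1)
    return PCAModel(
        mean=mean, scale=scale, loadings=loadings, scores=scores,
        explained_variance=ev_all[:n_components],
        explained_variance_ratio=ev_all[:n_components] / ev_all.sum(),
        scaling=scaling, alpha=alpha,
        t2_limit=hotelling_t2_limit(n, n_components, alpha),
    )


def hotelling_t2(model: PCAModel) -> pd.DataFrame:
    """Per-sample Hotelling T^2 over the fitted components, with in/out flags.

    T^2_i = sum_a t_ia^2 / var_a, compared against the model's limit.
    """
    ev = model.explained_variance
    t2 = (model.scores.to_numpy() ** 2 / ev).sum(axis=1)
    return pd.DataFrame(
        {"t2": t2, "inside": t2 <= model.t2_limit}, index=model.scores.index
    )


# ---------------------------------------------------------------------------
# Pearson correlation with significance tiers

def significance_tier(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.05:
        return "*"
    return ""


def correlate_traits_genes(
    traits: pd.DataFrame,
    expr: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    bh_column: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of trait values with gene expression.

    ``pairs`` is a list of (trait, gene); by default every trait is tested
    against every gene. Samples are matched on the shared index; pairs with
    fewer than 3 complete observations are skipped, zero-variance vectors
    yield NaN correlations. p-values come from the exact t-transform with
    n-2 degrees of freedom (two-sided); tiers: * p<=0.05, *** p<=0.001.
    A Benjamini-Hochberg q column is appended for convenience but the tier
    column is always based on the raw p.
    """
    shared = traits.index.intersection(expr.index)
    if pairs is None:
        pairs = [(t, g) for t in traits.columns for g in expr.columns]
    rows = []
    for trait_name, gene in pairs:
        if trait_name not in traits.columns or gene not in expr.columns:
            continue
        x = traits.loc[shared, trait_name].astype(float)
        y = expr.loc[shared, gene].astype(float)
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < 3:
            continue
        xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
        if np.std(xv) == 0 or np.std(yv) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(xv, yv)
        rows.append({
            "trait": trait_name, "gene": gene, "r": r, "p": p, "n": n,
            "tier": significance_tier(p) if np.isfinite(p) else "",
        })
    out = pd.DataFrame(rows, columns=["trait", "gene", "r", "p", "n", "tier"])
    if bh_column and len(out):
        finite = out["p"].notna()
        q = np.full(len(out), np.nan)
        if finite.any():
            q[finite.to_numpy()] = multipletests(out.loc[finite, "p"], method="fdr_bh")[1]
        out["q_bh"] = q
    return out


# ---------------------------------------------------------------------------
# Regularized CCA

@dataclass
class RCCAModel:
    """Fitted ridge-regularized CCA between two sample-matched blocks."""

    lambda1: float
    lambda2: float
    n_components: int
    canonical_correlations: np.ndarray           # rho_1 >= ... >= rho_K
    x_weights: pd.DataFrame                      # X-features x components
    y_weights: pd.DataFrame
    x_variates: pd.DataFrame                     # samples x components
    y_variates: pd.DataFrame
    similarity: pd.DataFrame = field(default=None)  # X-features x Y-features


def _inv_sqrt(M: np.ndarray) -> np.ndarray:
    vals, vecs = sla.eigh(M)
    vals = np.clip(vals, 1e-12, None)
    return vecs @ np.diag(vals**-0.5) @ vecs.T


def _corr_with(block: pd.DataFrame, variates: np.ndarray) -> np.ndarray:
    Xc = block - block.mean(axis=0)
    Zc = variates - variates.mean(axis=0)
    xs = Xc.std(axis=0, ddof=1).to_numpy()
    zs = Zc.std(axis=0, ddof=1)
    xs = np.where(xs > 0, xs, np.inf)
    zs = np.where(zs > 0, zs, np.inf)
    n = len(block)
    return (Xc.to_numpy().T @ Zc) / (n - 1) / np.outer(xs, zs)


def _cross_block_similarity(model: RCCAModel) -> pd.DataFrame:
    """similarity(i, j) = sum_d cor(X_i, Z_d) * cor(Y_j, Z_d), where Z_d is
    the average of the d-th X- and Y-variates.

    Entries can exceed [-1, 1] in magnitude when K > 1; heatmap color
    scales should saturate at +-1.
    """
    Z = (model.x_variates.to_numpy() + model.y_variates.to_numpy()) / 2.0
    cx = _corr_with(model._X, Z)
    cy = _corr_with(model._Y, Z)
    sim = cx @ cy.T
    return pd.DataFrame(sim, index=model.x_weights.index, columns=model.y_weights.index)


def fit_rcca(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    lambda1: float = 0.1,
    lambda2: float = 0.1,
    n_components: int = 2,
) -> RCCAModel:
    """Ridge-regularized canonical correlation analysis.

    Solves the CCA problem with Cxx + lambda1*I and Cyy + lambda2*I in
    place of the within-block covariances, via whitening and SVD of the
    cross-covariance. Canonical variates have unit variance under the
    regularized metric (a' (Cxx + lambda1 I) a = 1). With lambda = 0 on
    well-conditioned blocks this reduces to classical CCA.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("regularization parameters must be >= 0")
    if not X.index.equals(Y.index):
        shared = X.index.intersection(Y.index)
        if len(shared) < 3:
            raise ValueError("X and Y share fewer than 3 samples")
        X, Y = X.loc[shared], Y.loc[shared]
    Xa, Ya = X.to_numpy(dtype=float), Y.to_numpy(dtype=float)
    if not (np.isfinite(Xa).all() and np.isfinite(Ya).all()):
        raise ValueError("rCCA input must be finite and complete")
    K = n_components
    if K < 1 or K > min(X.shape[1], Y.shape[1]):
        raise ValueError(f"n_components={K} out of range for block widths {X.shape[1]}, {Y.shape[1]}")

    n = len(X)
    Xc = Xa - Xa.mean(axis=0)
    Yc = Ya - Ya.mean(axis=0)
    Cxx = Xc.T @ Xc / (n - 1) + lambda1 * np.eye(X.shape[1])
    Cyy = Yc.T @ Yc / (n - 1) + lambda2 * np.eye(Y.shape[1])
    Cxy = Xc.T @ Yc / (n - 1)
    Wx, Wy = _inv_sqrt(Cxx), _inv_sqrt(Cyy)
    U, s, Vt = np.linalg.svd(Wx @ Cxy @ Wy)
    rho = np.clip(s[:K], 0.0, 1.0)
    A = Wx @ U[:, :K]   # a' Cxx_reg a = I by construction
    B = Wy @ Vt.T[:, :K]
    # deterministic sign: largest-|.| X-weight element positive
    for j in range(K):
        i = np.argmax(np.abs(A[:, j]))
        if A[i, j] < 0:
            A[:, j] *= -1
            B[:, j] *= -1
    comp = [f"CC{i + 1}" for i in range(K)]
    model = RCCAModel(
        lambda1=lambda1, lambda2=lambda2, n_components=K,
        canonical_correlations=rho,
        x_weights=pd.DataFrame(A, index=X.columns, columns=comp),
        y_weights=pd.DataFrame(B, index=Y.columns, columns=comp),
        x_variates=pd.DataFrame(Xc @ A, index=X.index, columns=comp),
        y_variates=pd.DataFrame(Yc @ B, index=Y.index, columns=comp),
        similarity=pd.DataFrame(),  # filled below, needs block refs
    )
    model._X, model._Y = X, Y
    model.similarity = _cross_block_similarity(model)
    return model


# ---------------------------------------------------------------------------
# Hierarchical ordering of similarity maps

def cluster_order(matrix: pd.DataFrame):
    """Row/column leaf orders from agglomerative clustering.

    Complete linkage on Euclidean distances, applied to rows and to
    columns. Rows (columns) are pre-sorted by label so the dendrogram and
    leaf order are deterministic and invariant to input permutation.
    Returns ``(row_order, col_order, row_linkage, col_linkage)`` with the
    orders as label lists; a single row or column yields the identity.
    """
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("clustering input must be finite")

    def one_axis(df: pd.DataFrame):
        labels = sorted(df.index, key=str)
        data = df.loc[labels].to_numpy(dtype=float)
        if len(labels) < 2:
            return list(labels), None
        link = sch.linkage(data, method="complete", metric="euclidean")
        order = [labels[i] for i in sch.leaves_list(link)]
        return order, link

    row_order, row_link = one_axis(matrix)
    col_order, col_link = one_axis(matrix.T)
    return row_order, col_order, row_link, col_link
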
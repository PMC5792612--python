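"""Phylogenetic principal component analysis of species trait tables.

Ordinary PCA of species means ignores shared ancestry; the phylogenetic
variant replaces the sample mean and covariance with their GLS analogues
under a Brownian-motion covariance ``V`` built from the tree:

    a = (1' V^-1 1)^-1 1' V^-1 X          (ancestral / phylogenetic mean)
    R = (X - 1a)' V^-1 (X - 1a) / (n - 1) (evolutionary covariance)

The eigen-decomposition of ``R`` (or of its correlation rescaling) gives
loadings and eigenvalues; scores are the centered traits projected on the
eigenvectors.  On a star phylogeny with equal branch lengths the procedure
reduces exactly to ordinary centered PCA.

Components with eigenvalue above 1 are flagged as retained (Kaiser
criterion); eigenvectors are sign-oriented so the largest-|loading|
variable loads positively.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .phylo import Phylogeny


def kaiser_retained(eigenvalues, threshold: float = 1.0) -> int:
    """Number of components whose eigenvalue exceeds ``threshold``."""
    return int(np.sum(np.asarray(eigenvalues, dtype=float) > threshold))


class PhylogeneticPCA(BaseEstimator, TransformerMixin):
    """PCA under the evolutionary covariance matrix of a phylogeny.

    Parameters
    ----------
    mode : {"correlation", "covariance"}
        Eigen-decompose the evolutionary correlation matrix (traits
        standardized by their evolutionary standard deviations; default) or
        the evolutionary covariance matrix.
    lam : float, optional
        Optional Pagel-lambda pre-transform of the tree covariance; the
        default ``None`` uses the plain Brownian-motion ``V``.

    Attributes (post-fit)
    ---------------------
    loadings_ : DataFrame, variables x components (eigenvectors)
    eigenvalues_ : ndarray, nonincreasing
    scores_ : DataFrame, species x components, for the training table
    retained_ : list of component names with eigenvalue > 1
    anc_mean_ : Series, GLS-estimated ancestral trait means (raw scale)
    """

    def __init__(self, mode: str = "correlation", lam: float | None = None):
        self.mode = mode
        self.lam = lam

    def fit(self, X: pd.DataFrame, tree: Phylogeny):
        if self.mode not in ("correlation", "covariance"):
            raise ValueError("mode must be 'correlation' or 'covariance'")
        X = pd.DataFrame(X)
        if X.isna().any().any():
            raise ValueError("trait table contains missing values; apply "
                             "listwise deletion before PPCA")
        sp_table, sp_tree = set(X.index), set(tree.tip_labels)
        if sp_table != sp_tree:
            raise ValueError(
                "species mismatch between trait table and tree; only in "
                f"table: {sorted(sp_table - sp_tree)}, only in tree: "
                f"{sorted(sp_tree - sp_table)}"
            )
        labels = list(tree.tip_labels)  # alphabetical
        traits = X.loc[labels]
        self.variables_ = list(traits.columns)
        self.species_ = labels
        M = traits.to_numpy(dtype=float)
        n, p = M.shape
        if n <= p:
            raise ValueError("need more species than variables")
        if self.lam is None:
            cm = tree.covariance()
        else:
            cm = tree.transform("lambda", self.lam)
        L = cm.cholesky()
        ones = np.ones((n, 1))
        Xw = solve_triangular(L, M, lower=True)
        ow = solve_triangular(L, ones, lower=True)
        a = np.linalg.solve(ow.T @ ow, ow.T @ Xw).ravel()
        C = M - a  # centered traits on the raw scale
        Cw = Xw - ow @ a[None, :]
        R = (Cw.T @ Cw) / (n - 1)
        if self.mode == "correlation":
            sd = np.sqrt(np.diag(R))
            R = R / np.outer(sd, sd)
            C = C / sd
            self.evolutionary_sd_ = sd
        eigval, eigvec = np.linalg.eigh(R)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        for j in range(p):
            i = int(np.argmax(np.abs(eigvec[:, j])))
            if eigvec[i, j] < 0:
                eigvec[:, j] = -eigvec[:, j]
        comps = [f"PC{j + 1}" for j in range(p)]
        self.eigenvalues_ = eigval
        self.loadings_ = pd.DataFrame(eigvec, index=self.variables_,
                                      columns=comps)
        self.anc_mean_ = pd.Series(a, index=self.variables_)
        self.scores_ = pd.DataFrame(C @ eigvec, index=labels, columns=comps)
        self.scores_.index.name = "species"
        self.retained_ = [c for c, ev in zip(comps, eigval) if ev > 1.0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Score (possibly new) species on the fitted components."""
        check_is_fitted(self, "loadings_")
        X = pd.DataFrame(X)[self.variables_]
        C = X.to_numpy(dtype=float) - self.anc_mean_.to_numpy()
        if self.mode == "correlation":
            C = C / self.evolutionary_sd_
        return pd.DataFrame(C @ self.loadings_.to_numpy(), index=X.index,
                            columns=list(self.loadings_.columns))

    def table(self) -> pd.DataFrame:
        """Loadings with a trailing eigenvalues row (report layout)."""
        check_is_fitted(self, "loadings_")
        out = self.loadings_.copy()
        out.loc["Eigenvalues"] = self.eigenvalues_
        return out


def phylogenetic_pca(traits: pd.DataFrame, tree: Phylogeny,
                     mode: str = "correlation",
                     lam: float | None = None) -> PhylogeneticPCA:
    """Fit a :class:`PhylogeneticPCA` on a species x variable table."""
    return PhylogeneticPCA(mode=mode, lam=lam).fit(traits, tree)
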
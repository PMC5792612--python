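"""Phylogenetic generalized least squares with profiled covariance transforms.

One fit = one mean structure (an intercept plus predictor term groups)
under one covariance family.  Coefficients and the residual variance are
exact maximum-likelihood GLS quantities at a given covariance matrix ``V``:

    beta  = (X' V^-1 X)^-1 X' V^-1 y
    s2    = e' V^-1 e / n                      (ML, not REML)
    logL  = -(1/2) [ n ln(2 pi) + n ln s2 + ln|V| + n ]

computed by Cholesky whitening, never explicit inversion.  For the lambda /
kappa / delta / OU families the transform parameter is estimated jointly
with the coefficients by profile likelihood: a 5-point grid scan followed by
bounded scalar minimization to 1e-6 on the parameter.  ML (rather than
REML) is used throughout so that AICc is comparable across different mean
structures.

The parameter count ``k`` of a fit is the number of design columns plus one
for the residual variance plus one more when a transform parameter is
estimated; AICc = -2 logL + 2k + 2k(k+1)/(n-k-1).
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import qr as _qr, solve_triangular
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .phylo import FAMILIES, Phylogeny

logger = logging.getLogger(__name__)

# -- model vocabulary ---------------------------------------------------------

#: predictor term groups -> species-table columns
TERM_COLUMNS = {
    "BodySize": ("body_size",),
    "BeakSize": ("beak_size",),
    "BeakMoment": ("beak_size", "log_beak_length"),
    "Habitat": ("habitat_semi_open", "habitat_open"),
    "EnvPC1": ("env_pc1",),
}
MORPHOLOGY_TERMS = ("BodySize", "BeakSize", "BeakMoment")
HABITAT_TERMS = ("Habitat", "EnvPC1")

#: data column -> reported parameter name
DISPLAY_NAMES = {
    "body_size": "Body Size",
    "beak_size": "Beak Size",
    "log_beak_length": "Beak Length",
    "habitat_semi_open": "Habitat (semi-open)",
    "habitat_open": "Habitat (open)",
    "env_pc1": "Environment PC1",
}

#: canonical report ordering of every parameter that can occur
ALL_PARAMETERS = (
    "Intercept",
    "Beak Size",
    "Habitat (semi-open)",
    "Habitat (open)",
    "Beak Length",
    "Beak Size × Habitat (semi-open)",
    "Beak Size × Habitat (open)",
    "Beak Length × Habitat (semi-open)",
    "Beak Length × Habitat (open)",
    "Body Size",
    "Body Size × Habitat (semi-open)",
    "Body Size × Habitat (open)",
    "Environment PC1",
)


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One candidate mean structure under one covariance family.

    ``terms`` holds predictor group names from :data:`TERM_COLUMNS`; the
    intercept is always implied.  To limit collinearity a model may contain
    at most one morphology group and at most one habitat measure, and
    interactions are allowed only between a morphology group and the
    categorical habitat term.
    """

    response: str
    terms: tuple[str, ...] = ()
    interaction: bool = False
    family: str = "lambda"

    def __post_init__(self) -> None:
        unknown = [t for t in self.terms if t not in TERM_COLUMNS]
        if unknown:
            raise ValueError(f"unknown terms {unknown}; expected "
                             f"{sorted(TERM_COLUMNS)}")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms")
        n_morph = sum(t in MORPHOLOGY_TERMS for t in self.terms)
        n_hab = sum(t in HABITAT_TERMS for t in self.terms)
        if n_morph > 1 or n_hab > 1:
            raise ValueError(
                "at most one morphology group and one habitat measure per "
                "model (collinearity constraint)"
            )
        if self.interaction:
            if "EnvPC1" in self.terms or "Habitat" not in self.terms:
                raise ValueError(
                    "interactions are allowed with the categorical habitat "
                    "measure only, never with Environment PC1"
                )
            if n_morph != 1:
                raise ValueError(
                    "an interaction model needs exactly one morphology group"
                )
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def label(self) -> str:
        """Human-readable mean structure, e.g. ``BeakMoment × Habitat``."""
        if not self.terms:
            return "Constant"
        sep = " × " if self.interaction else " + "
        return sep.join(self.terms)

    def data_columns(self) -> list[str]:
        cols: list[str] = []
        for t in self.terms:
            cols.extend(TERM_COLUMNS[t])
        return cols


def design_matrix(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Design matrix for a spec: intercept, main effects, interactions.

    Columns are named with the reported parameter names; a BeakMoment
    interaction expands into both Beak Size x Habitat and Beak Length x
    Habitat product columns.
    """
    X = pd.DataFrame(index=data.index)
    X["Intercept"] = 1.0
    for term in spec.terms:
        for col in TERM_COLUMNS[term]:
            X[DISPLAY_NAMES[col]] = data[col].astype(float)
    if spec.interaction:
        morph = next(t for t in spec.terms if t in MORPHOLOGY_TERMS)
        for mc in TERM_COLUMNS[morph]:
            for hc in TERM_COLUMNS["Habitat"]:
                name = f"{DISPLAY_NAMES[mc]} × {DISPLAY_NAMES[hc]}"
                X[name] = data[mc].astype(float) * data[hc].astype(float)
    return X


# -- core GLS -----------------------------------------------------------------

@dataclasses.dataclass
class GLSFit:
    """Exact ML GLS quantities at a fixed covariance matrix."""

    coefficients: np.ndarray
    sigma2: float
    loglik: float
    degenerate: bool
    names: tuple[str, ...] | None = None


def gls_fit(y, X, V, names=None) -> GLSFit:
    """Maximum-likelihood GLS of ``y`` on ``X`` with error covariance ``V``.

    Solved by whitening with the Cholesky factor of ``V`` and a pivoted QR
    of the whitened design.  A numerically rank-deficient design raises,
    naming the collinear columns.  A perfect fit (``y`` in the column span
    of ``X``) is reported with ``sigma2 = 0`` and a degeneracy flag.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n or V.shape != (n, n):
        raise ValueError("incompatible shapes for y, X, V")
    try:
        L = np.linalg.cholesky(np.asarray(V, dtype=float))
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    Q, R, piv = _qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < p:
        bad = piv[rank:]
        labels = [names[i] if names else f"column {i}" for i in sorted(bad)]
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {labels}")
    beta_p = solve_triangular(R, Q.T @ yw, lower=False)
    beta = np.empty(p)
    beta[piv] = beta_p
    e = yw - Xw @ beta
    rss = float(e @ e)
    sigma2 = rss / n
    scale = float(yw @ yw) / n + 1.0
    degenerate = sigma2 <= 1e-14 * scale
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if degenerate:
        loglik = math.inf
    else:
        loglik = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2)
                         + logdet + n)
    return GLSFit(beta, sigma2, loglik, degenerate,
                  tuple(names) if names else None)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n - k - 1 = {n - k - 1} <= 0")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# -- profile fitting ----------------------------------------------------------

@dataclasses.dataclass
class FitResult:
    """One PGLS fit: coefficients, variance, transform, likelihood, AICc."""

    spec: ModelSpec
    param_names: tuple[str, ...]
    coefficients: np.ndarray
    sigma2: float
    transform_estimate: float | None
    loglik: float
    k: int
    n: int
    aicc: float
    boundary: bool = False
    degenerate: bool = False

    @property
    def coef_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, self.coefficients)))

    def parameter_set(self) -> frozenset[str]:
        """Design columns other than the intercept (for nesting tests)."""
        return frozenset(p for p in self.param_names if p != "Intercept")


def _gls_at(cm, y, X, names) -> GLSFit:
    """GLS at one covariance model, retreating to its ridge on non-PD."""
    try:
        return gls_fit(y, X, cm.matrix, names)
    except ValueError as exc:
        if "positive definite" not in str(exc):
            raise
        L = cm.cholesky()
        return gls_fit(y, X, L @ L.T, names)


def _grid(lo: float, hi: float, m: int, log_scale: bool) -> np.ndarray:
    if log_scale:
        return np.exp(np.linspace(math.log(max(lo, 1e-12)), math.log(hi), m))
    return np.linspace(lo, hi, m)


def _profile_transform(tree: Phylogeny, family: str, y: np.ndarray,
                       X: np.ndarray, names, bounds, grid_points: int,
                       tol: float) -> tuple[GLSFit, float, bool]:
    """Profile the transform parameter; returns (fit, parameter, boundary)."""
    lo, hi = tree.parameter_bounds(family, bounds)

    def neg_loglik(p: float) -> float:
        cm = tree.transform(family, float(np.clip(p, lo, hi)), bounds=bounds)
        return -_gls_at(cm, y, X, names).loglik

    grid = _grid(lo, hi, grid_points, log_scale=(family == "OU"))
    vals = [neg_loglik(p) for p in grid]
    i = int(np.argmin(vals))
    blo = grid[max(i - 1, 0)]
    bhi = grid[min(i + 1, len(grid) - 1)]
    if blo == bhi:  # optimum at a grid edge
        blo, bhi = (lo, grid[1]) if i == 0 else (grid[-2], hi)
    res = optimize.minimize_scalar(
        neg_loglik, bounds=(blo, bhi), method="bounded",
        options={"xatol": tol},
    )
    best_p = float(res.x)
    # the bracket may exclude a better grid edge value
    if vals[i] < res.fun:
        best_p = float(grid[i])
    best_p = float(np.clip(best_p, lo, hi))
    fit = _gls_at(tree.transform(family, best_p, bounds=bounds), y, X, names)
    span = hi - lo
    boundary = (best_p - lo) <= 10 * tol * span or (hi - best_p) <= 10 * tol * span
    return fit, best_p, boundary


def fit_design(y: np.ndarray, X: pd.DataFrame, tree: Phylogeny, family: str,
               spec: ModelSpec | None = None, bounds: dict | None = None,
               grid_points: int = 5, tol: float = 1e-6) -> FitResult:
    """Fit one design matrix under one covariance family (profile ML)."""
    names = tuple(X.columns)
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if family == "BM":
        fit = _gls_at(tree.covariance(), y, Xv, names)
        transform, boundary = None, False
        k = Xv.shape[1] + 1
    else:
        fit, transform, boundary = _profile_transform(
            tree, family, y, Xv, names, bounds, grid_points, tol)
        k = Xv.shape[1] + 2
    if k >= n - 1:
        raise ValueError(f"too few species (n={n}) for k={k} parameters")
    crit = -math.inf if fit.degenerate else aicc(fit.loglik, k, n)
    if spec is None:
        spec = ModelSpec(response="y", terms=(), family=family)
    return FitResult(
        spec=spec, param_names=names, coefficients=fit.coefficients,
        sigma2=fit.sigma2, transform_estimate=transform, loglik=fit.loglik,
        k=k, n=n, aicc=crit, boundary=boundary, degenerate=fit.degenerate,
    )


def fit_pgls(spec: ModelSpec, data: pd.DataFrame, tree: Phylogeny,
             bounds: dict | None = None, grid_points: int = 5,
             tol: float = 1e-6) -> FitResult:
    """Fit one :class:`ModelSpec` on a species table and tree.

    Rows with missing values in the response or any predictor column are
    dropped (listwise deletion) and the tree is pruned to the complete
    cases before fitting.
    """
    cols = [spec.response] + spec.data_columns()
    sub = data[cols].dropna()
    keep = sorted(set(sub.index) & set(tree.tip_labels))
    if len(keep) < len(sub):
        missing = sorted(set(sub.index) - set(tree.tip_labels))
        logger.info("dropping %d species absent from the tree: %s",
                    len(missing), missing[:5])
    sub = sub.loc[keep]
    ptree = tree.subset(keep)
    X = design_matrix(spec, sub)
    return fit_design(sub[spec.response].to_numpy(), X, ptree, spec.family,
                      spec=spec, bounds=bounds, grid_points=grid_points,
                      tol=tol)


class PGLS(RegressorMixin, BaseEstimator):
    """scikit-learn-style phylogenetic GLS regressor.

    Parameters
    ----------
    tree : Phylogeny
        The phylogeny whose covariance structures the residuals.
    family : str
        Covariance family; one of ``BM, lambda, kappa, delta, OU``.
    bounds : dict, optional
        Per-family ``(lo, hi)`` overrides for the transform parameter.

    ``fit(X, y)`` accepts a DataFrame indexed by species label (rows are
    aligned to the tree; the tip sets must match after listwise deletion)
    or a plain array whose rows already follow the tree's alphabetical tip
    order.  An intercept is always added.

    Attributes (post-fit): ``coef_``, ``intercept_``, ``sigma2_``,
    ``transform_``, ``loglik_``, ``k_``, ``n_``, ``aicc_``, ``boundary_``.
    """

    def __init__(self, tree: Phylogeny | None = None, family: str = "lambda",
                 bounds: dict | None = None, grid_points: int = 5,
                 tol: float = 1e-6):
        self.tree = tree
        self.family = family
        self.bounds = bounds
        self.grid_points = grid_points
        self.tol = tol

    def _align(self, X, y):
        if self.tree is None:
            raise ValueError("PGLS requires a tree")
        if isinstance(X, pd.DataFrame):
            df = X.copy()
            yv = pd.Series(np.asarray(y, dtype=float).ravel(), index=df.index)
            df = df.assign(__y=yv).dropna()
            keep = sorted(set(df.index) & set(self.tree.tip_labels))
            df = df.loc[keep]
            tree = self.tree.subset(keep)
            names = tuple(df.columns[:-1])
            return (df.iloc[:, :-1].to_numpy(dtype=float),
                    df["__y"].to_numpy(), tree, names)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = tuple(f"x{i}" for i in range(X.shape[1]))
        return X, np.asarray(y, dtype=float).ravel(), self.tree, names

    def fit(self, X, y):
        Xv, yv, tree, names = self._align(X, y)
        design = pd.DataFrame(
            np.column_stack([np.ones(len(yv)), Xv]),
            columns=("Intercept",) + names,
        )
        res = fit_design(yv, design, tree, self.family, bounds=self.bounds,
                         grid_points=self.grid_points, tol=self.tol)
        self.result_ = res
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.intercept_ = float(res.coefficients[0])
        self.coef_ = res.coefficients[1:].copy()
        self.sigma2_ = res.sigma2
        self.transform_ = res.transform_estimate
        self.loglik_ = res.loglik
        self.k_ = res.k
        self.n_ = res.n
        self.aicc_ = res.aicc
        self.boundary_ = res.boundary
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names_in_)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_
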
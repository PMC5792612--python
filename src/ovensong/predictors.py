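"""Morphology composites, habitat encodings, and the climate principal component.

Morphology enters the models through three natural-log composites per
species: body size (mean of ln mass and ln tarsus length), beak size (mean
of ln beak length, width and depth), and ln beak length on its own.  The
pair (beak size, ln beak length) approximates the beak's moment of inertia
— width x depth x length to an unknown power — and is treated downstream as
a single two-column "beak moment" term.

Habitat is either a three-level category (closed / semi-open / open canopy,
dummy-coded against the closed reference) or a continuous climate axis: the
first component of a correlation-matrix PCA over a redundancy-filtered set
of bioclimatic variables (annual means retained by construction; any other
temperature variable kept only when |r| with Bio1 < 0.90, any precipitation
variable only when |r| with Bio12 < 0.90).  Elevation is carried in the
climate table but never enters the PCA.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

HABITAT_LEVELS = ("closed", "semi_open", "open")

TEMPERATURE_VARS = tuple(f"bio{i}" for i in range(1, 12))
PRECIPITATION_VARS = tuple(f"bio{i}" for i in range(12, 20))
CLIMATE_VARS = TEMPERATURE_VARS + PRECIPITATION_VARS

MORPHOLOGY_COLUMNS = ("mass_g", "tarsus_mm", "beak_length_mm",
                      "beak_width_mm", "beak_depth_mm")


def morphology_composites(morphology: pd.DataFrame) -> pd.DataFrame:
    """Per-species log-scale size composites.

    Returns a frame indexed like the input with columns ``body_size``
    (mean of ln mass and ln tarsus), ``beak_size`` (mean of ln length,
    width, depth) and ``log_beak_length``.  Species with any nonpositive
    raw measurement are dropped with a warning.
    """
    missing = [c for c in MORPHOLOGY_COLUMNS if c not in morphology.columns]
    if missing:
        raise ValueError(f"morphology table missing columns: {missing}")
    raw = morphology[list(MORPHOLOGY_COLUMNS)].astype(float)
    bad = (raw <= 0).any(axis=1) | raw.isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} species with nonpositive or missing "
            f"morphology: {sorted(morphology.index[bad])}", stacklevel=2,
        )
        raw = raw[~bad]
    logs = np.log(raw)
    out = pd.DataFrame(index=raw.index)
    out["body_size"] = logs[["mass_g", "tarsus_mm"]].mean(axis=1)
    out["beak_size"] = logs[
        ["beak_length_mm", "beak_width_mm", "beak_depth_mm"]
    ].mean(axis=1)
    out["log_beak_length"] = logs["beak_length_mm"]
    return out


def encode_habitat(category) -> pd.DataFrame | tuple[int, int]:
    """Dummy-code habitat against the closed-canopy reference.

    closed -> (0, 0); semi_open -> (1, 0); open -> (0, 1).  Accepts a single
    label (returns the tuple) or a Series (returns a two-column frame
    ``habitat_semi_open``, ``habitat_open``).
    """
    if isinstance(category, str):
        if category not in HABITAT_LEVELS:
            raise ValueError(
                f"unknown habitat {category!r}; expected one of {HABITAT_LEVELS}"
            )
        return (int(category == "semi_open"), int(category == "open"))
    cat = pd.Series(category)
    bad = sorted(set(cat.dropna()) - set(HABITAT_LEVELS))
    if bad:
        raise ValueError(
            f"unknown habitat labels {bad}; expected one of {HABITAT_LEVELS}"
        )
    out = pd.DataFrame(index=cat.index)
    out["habitat_semi_open"] = (cat == "semi_open").astype(int)
    out["habitat_open"] = (cat == "open").astype(int)
    return out


def climate_filter(climate: pd.DataFrame, threshold: float = 0.90) -> list[str]:
    """Redundancy filter for the bioclimatic variables.

    Keeps a temperature variable iff ``|r|`` with Bio1 is below
    ``threshold`` and a precipitation variable iff ``|r|`` with Bio12 is
    below it; Bio1 and Bio12 themselves are always retained.  Zero-variance
    and absent variables are excluded (with a warning for the former).
    The returned order follows :data:`CLIMATE_VARS`.
    """
    if len(climate) < 2:
        raise ValueError("need at least 2 species rows to correlate")
    for anchor in ("bio1", "bio12"):
        if anchor not in climate.columns:
            raise ValueError(f"climate table must contain {anchor}")
    retained: list[str] = []
    for group, anchor in ((TEMPERATURE_VARS, "bio1"),
                          (PRECIPITATION_VARS, "bio12")):
        a = climate[anchor].astype(float)
        for var in group:
            if var not in climate.columns:
                continue
            x = climate[var].astype(float)
            if float(x.std(ddof=1)) == 0.0:
                warnings.warn(f"excluding zero-variance variable {var}",
                              stacklevel=2)
                continue
            if var == anchor:
                retained.append(var)
                continue
            r = float(np.corrcoef(x, a)[0, 1])
            if abs(r) < threshold:
                retained.append(var)
    return retained


class EnvironmentPCA(BaseEstimator, TransformerMixin):
    """Correlation-matrix PCA of per-species climate variables.

    Variables are standardized to zero mean and unit variance (the
    temperature and precipitation variables are in incommensurate units) and
    the correlation matrix is eigen-decomposed.  Components with eigenvalue
    greater than one are flagged as retained (Kaiser criterion).  Each
    eigenvector is sign-oriented so its largest-|loading| variable loads
    positively.  ``transform`` returns scores on all components; the first
    column is the Environment PC1 used as a predictor downstream.
    """

    def __init__(self, kaiser_threshold: float = 1.0):
        self.kaiser_threshold = kaiser_threshold

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.shape[1] < 2 or X.shape[0] < 3:
            raise ValueError("need >= 2 variables and >= 3 species")
        self.variables_ = list(X.columns)
        vals = X.to_numpy(dtype=float)
        self.means_ = vals.mean(axis=0)
        self.scales_ = vals.std(axis=0, ddof=1)
        if np.any(self.scales_ == 0):
            zero = [v for v, s in zip(self.variables_, self.scales_) if s == 0]
            raise ValueError(f"zero-variance variables: {zero}")
        Z = (vals - self.means_) / self.scales_
        corr = (Z.T @ Z) / (len(Z) - 1)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        n_zero = int(np.sum(eigval < 1e-12))
        if n_zero:
            logger.info("correlation matrix rank-deficient: %d zero "
                        "eigenvalues", n_zero)
        # sign convention: largest-|loading| variable positive per component
        for j in range(eigvec.shape[1]):
            i = int(np.argmax(np.abs(eigvec[:, j])))
            if eigvec[i, j] < 0:
                eigvec[:, j] = -eigvec[:, j]
        comps = [f"PC{j + 1}" for j in range(len(eigval))]
        self.eigenvalues_ = eigval
        self.loadings_ = pd.DataFrame(eigvec, index=self.variables_,
                                      columns=comps)
        self.variance_fractions_ = eigval / eigval.sum()
        self.retained_ = [c for c, ev in zip(comps, eigval)
                          if ev > self.kaiser_threshold]
        self.n_zero_eigenvalues_ = n_zero
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "loadings_")
        X = pd.DataFrame(X)[self.variables_]
        Z = (X.to_numpy(dtype=float) - self.means_) / self.scales_
        scores = Z @ self.loadings_.to_numpy()
        return pd.DataFrame(scores, index=X.index,
                            columns=list(self.loadings_.columns))


def env_pca(climate: pd.DataFrame, variables: list[str] | None = None,
            threshold: float = 0.90) -> tuple[pd.DataFrame, EnvironmentPCA]:
    """Filter climate variables, run the correlation-matrix PCA, score species.

    Returns ``(scores, fitted EnvironmentPCA)``; ``scores["PC1"]`` is the
    Environment PC1 predictor.
    """
    if variables is None:
        variables = climate_filter(climate, threshold=threshold)
    model = EnvironmentPCA().fit(climate[variables])
    return model.transform(climate[variables]), model
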
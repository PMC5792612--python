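"""Candidate-set enumeration, AICc ranking, pruning, and model averaging.

The candidate set for one response crosses 15 mean structures — the
constant model, each of three morphology groups (body size, beak size,
beak moment), each of two habitat measures (categorical habitat,
Environment PC1), the six morphology + habitat pairs, and the three
morphology x categorical-habitat interaction models — with the five
covariance families, giving 75 fits ranked jointly by AICc.

Akaike weights are ``w_i = exp(-dAICc_i / 2) / sum``; the evidence ratio of
a model is its weight over the total weight of the constant models (one per
family).  Models within two AICc of a higher-ranked model whose parameters
strictly contain the higher-ranked model's parameters are pruned as
uninformative.  Averaging is over the smallest prefix of the weight-sorted
list reaching 95% cumulative weight, with weights renormalized and a
parameter's coefficient treated as zero in models that omit it
(zero-substitution).  A posterior sample of trees is aggregated by
repeating the whole procedure per tree and taking the unweighted mean of
the averaged parameters.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pgls import (ALL_PARAMETERS, FAMILIES, FitResult, HABITAT_TERMS,
                   MORPHOLOGY_TERMS, ModelSpec, fit_pgls)
from .phylo import Phylogeny, TreeSet

logger = logging.getLogger(__name__)


def build_model_set(response: str,
                    morphology: Sequence[str] = MORPHOLOGY_TERMS,
                    habitat: Sequence[str] = HABITAT_TERMS,
                    families: Sequence[str] = FAMILIES,
                    interactions: bool = True) -> list[ModelSpec]:
    """Enumerate the candidate :class:`ModelSpec` list for one response."""
    structures: list[tuple[tuple[str, ...], bool]] = [((), False)]
    structures += [((m,), False) for m in morphology]
    structures += [((h,), False) for h in habitat]
    structures += [((m, h), False) for m in morphology for h in habitat]
    if interactions:
        structures += [((m, "Habitat"), True) for m in morphology
                       if "Habitat" in habitat]
    return [ModelSpec(response=response, terms=t, interaction=ix, family=f)
            for t, ix in structures for f in families]


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalized Akaike weights from AICc values (shift-invariant)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0 or not np.any(np.isfinite(a)):
        raise ValueError("need at least one finite AICc value")
    delta = a - np.nanmin(a[np.isfinite(a)])
    w = np.exp(-0.5 * delta)
    w[~np.isfinite(a)] = 0.0
    return w / w.sum()


@dataclasses.dataclass
class ModelSet:
    """A ranked, weighted candidate set for one response."""

    fits: list[FitResult]           # sorted by AICc ascending
    delta_aicc: np.ndarray
    weights: np.ndarray
    evidence_ratio: np.ndarray
    w_constant: float

    ER_SENTINEL = 1e6

    def __len__(self) -> int:
        return len(self.fits)

    def table(self) -> pd.DataFrame:
        """Ranking table: model, family, AICc, dAICc, weight, ER."""
        rows = []
        for fit, d, w, er in zip(self.fits, self.delta_aicc, self.weights,
                                 self.evidence_ratio):
            rows.append({
                "model": fit.spec.label, "family": fit.spec.family,
                "n": fit.n, "k": fit.k, "loglik": fit.loglik,
                "transform": fit.transform_estimate,
                "aicc": fit.aicc, "delta_aicc": d, "weight": w,
                "evidence_ratio": er if np.isfinite(er) else self.ER_SENTINEL,
                "er_censored": not np.isfinite(er),
            })
        return pd.DataFrame(rows)


def rank_models(fits: Iterable[FitResult]) -> ModelSet:
    """Rank fits by AICc over the pooled candidate set and weight them."""
    fits = sorted(fits, key=lambda f: (f.aicc,))
    a = np.array([f.aicc for f in fits])
    weights = akaike_weights(a)
    finite = a[np.isfinite(a)]
    delta = a - finite.min()
    w_const = float(sum(w for f, w in zip(fits, weights) if not f.spec.terms))
    with np.errstate(divide="ignore", invalid="ignore"):
        er = np.where(w_const > 0, weights / w_const, np.inf)
    return ModelSet(fits=list(fits), delta_aicc=delta, weights=weights,
                    evidence_ratio=er, w_constant=w_const)


def prune_uninformative(modelset: ModelSet,
                        margin: float = 2.0) -> tuple[list[FitResult], list[str]]:
    """Drop models that only add parameters to a higher-ranked model.

    A model is pruned when some model with lower-or-equal AICc has a
    parameter set strictly contained in its own and lies within ``margin``
    AICc units.  The top-ranked model is never pruned.  Returns the
    retained fits (rank order preserved) and a log of pruning decisions.
    """
    retained: list[FitResult] = []
    log: list[str] = []
    fits = modelset.fits
    for i, fit in enumerate(fits):
        pruned = False
        pset = fit.parameter_set()
        for other in fits[:i]:
            if other.aicc > fit.aicc:
                continue
            if (other.parameter_set() < pset
                    and fit.aicc - other.aicc <= margin):
                log.append(
                    f"pruned {fit.spec.label} [{fit.spec.family}] "
                    f"(dAICc {fit.aicc - other.aicc:+.3f} vs nested "
                    f"{other.spec.label} [{other.spec.family}])"
                )
                pruned = True
                break
        if not pruned:
            retained.append(fit)
    return retained, log


def cumulative_weight_set(modelset: ModelSet,
                          threshold: float = 0.95) -> list[int]:
    """Indices (into the ranked fits) of the smallest 95% cumulative set.

    Models are taken in decreasing weight (ties broken by AICc, then rank
    order) until the cumulative weight reaches ``threshold``.
    """
    order = sorted(range(len(modelset)),
                   key=lambda i: (-modelset.weights[i], modelset.fits[i].aicc, i))
    chosen: list[int] = []
    cum = 0.0
    for i in order:
        chosen.append(i)
        cum += modelset.weights[i]
        if cum >= threshold - 1e-12:
            break
    return sorted(chosen)


def parameter_total_weight(fits: Sequence[FitResult], weights,
                           parameter: str) -> float:
    """Sum of the weights of the models whose design includes ``parameter``."""
    weights = np.asarray(weights, dtype=float)
    known = set().union(*(f.param_names for f in fits))
    if parameter not in known:
        warnings.warn(f"parameter {parameter!r} appears in no model",
                      stacklevel=2)
        return 0.0
    return float(sum(w for f, w in zip(fits, weights)
                     if parameter in f.param_names))


def all_parameter_weights(fits: Sequence[FitResult], weights) -> pd.Series:
    """Total weight for every non-intercept parameter, report order."""
    weights = np.asarray(weights, dtype=float)
    out = {}
    for p in ALL_PARAMETERS:
        if p == "Intercept":
            continue
        out[p] = float(sum(w for f, w in zip(fits, weights)
                           if p in f.param_names))
    return pd.Series(out)


@dataclasses.dataclass
class AveragedModel:
    """Zero-substitution weighted-average coefficients over a model subset."""

    parameters: tuple[str, ...]
    averaged_beta: pd.Series
    parameter_total_weight: pd.Series
    modal_family: str
    mean_transform: float
    tree_count: int = 1


def model_average(fits: Sequence[FitResult], weights,
                  parameters: Sequence[str] | None = None) -> AveragedModel:
    """Weighted average of coefficients with zeros substituted when absent.

    ``weights`` are renormalized over the given fits.  ``parameters``
    defaults to :data:`ALL_PARAMETERS`; a parameter present in no model
    averages to exactly zero.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("cannot average an empty model set")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(fits):
        raise ValueError("weights and fits length mismatch")
    w = w / w.sum()
    if parameters is None:
        parameters = ALL_PARAMETERS
    beta = {}
    total = {}
    for p in parameters:
        beta[p] = float(sum(wi * f.coef_dict.get(p, 0.0)
                            for f, wi in zip(fits, w)))
        total[p] = float(sum(wi for f, wi in zip(fits, w)
                             if p in f.param_names))
    fam_weight = Counter()
    for f, wi in zip(fits, w):
        fam_weight[f.spec.family] += wi
    modal = max(fam_weight, key=lambda k: (fam_weight[k], k))
    mean_tr = float(sum(wi * (f.transform_estimate or 0.0)
                        for f, wi in zip(fits, w)))
    return AveragedModel(
        parameters=tuple(parameters),
        averaged_beta=pd.Series(beta),
        parameter_total_weight=pd.Series(total),
        modal_family=modal,
        mean_transform=mean_tr,
    )


def fit_model_set(response: str, data: pd.DataFrame, tree: Phylogeny,
                  families: Sequence[str] = FAMILIES,
                  interactions: bool = True,
                  bounds: dict | None = None,
                  exclude: Sequence[str] = ()) -> list[FitResult]:
    """Fit every candidate model for one response on one tree.

    Listwise deletion is applied over the union of all predictor columns so
    every candidate is fitted to the same species (AICc values are then
    comparable); explicitly excluded species are removed first.
    """
    specs = build_model_set(response, families=families,
                            interactions=interactions)
    cols = sorted({c for s in specs for c in s.data_columns()})
    sub = data.drop(index=[s for s in exclude if s in data.index])
    sub = sub[[response] + cols].dropna()
    keep = sorted(set(sub.index) & set(tree.tip_labels))
    sub = sub.loc[keep]
    ptree = tree.subset(keep)
    return [fit_pgls(s, sub, ptree, bounds=bounds) for s in specs]


def average_across_trees(trees: TreeSet, response: str, data: pd.DataFrame,
                         families: Sequence[str] = FAMILIES,
                         threshold: float = 0.95,
                         interactions: bool = True,
                         bounds: dict | None = None,
                         exclude: Sequence[str] = (),
                         return_per_tree: bool = False):
    """Fit, select and average per posterior tree, then mean across trees.

    For each tree the full candidate set is fitted, the 95% cumulative
    weight subset is model-averaged (weights renormalized), and the
    per-tree averaged coefficients (zero-substituted over the full
    parameter list) are combined by an unweighted mean.  Parameter total
    weights are likewise averaged across trees; the family reported is the
    modal top-model family.
    """
    overlap = set(data.index) & set(trees.tip_labels)
    if not overlap:
        raise ValueError("tree tips and data species do not overlap")
    per_tree: list[AveragedModel] = []
    full_weights: list[pd.Series] = []
    top_families: list[str] = []
    for tree in trees:
        fits = fit_model_set(response, data, tree, families=families,
                             interactions=interactions, bounds=bounds,
                             exclude=exclude)
        ms = rank_models(fits)
        idx = cumulative_weight_set(ms, threshold=threshold)
        avg = model_average([ms.fits[i] for i in idx], ms.weights[idx])
        per_tree.append(avg)
        full_weights.append(all_parameter_weights(ms.fits, ms.weights))
        top_families.append(ms.fits[0].spec.family)
    beta = pd.concat([a.averaged_beta for a in per_tree], axis=1).mean(axis=1)
    totw = pd.concat(full_weights, axis=1).mean(axis=1)
    totw["Intercept"] = 1.0
    modal = Counter(top_families)
    result = AveragedModel(
        parameters=tuple(beta.index),
        averaged_beta=beta,
        parameter_total_weight=totw.reindex(beta.index).fillna(0.0),
        modal_family=max(modal, key=lambda k: (modal[k], k)),
        mean_transform=float(np.mean([a.mean_transform for a in per_tree])),
        tree_count=len(trees),
    )
    if return_per_tree:
        return result, per_tree
    return result
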